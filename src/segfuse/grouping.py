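"""Cross-sample evaluation: recurrence, positional conservation, clustering.

Per-sample candidates sharing a (5' gene, 3' gene) pair across at least two
samples form a *group*. Within a group, each of the four fusion coordinates
is either conserved (identical in every member) or variable; at least two
must be conserved or the group is rejected. The variable coordinates define a
Euclidean distance between members, and complete-linkage hierarchical
clustering of that matrix splits the group into subgroups — or discards
members whose fusion deviates by more than 40% of the group's median fusion
length. Only subgroups covering at least two samples are reported.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import DISCARDED, FusionCandidate, FusionGroup
from .params import Parameters

logger = logging.getLogger("segfuse")

#: One agglomeration step: (height, members_a, members_b) with member indices.
Merge = Tuple[float, Tuple[int, ...], Tuple[int, ...]]


def collect_groups(
    candidates: Union[Iterable[Sequence[FusionCandidate]], Sequence[FusionCandidate]],
    params: Optional[Parameters] = None,
) -> List[FusionGroup]:
    """Group candidates by gene pair; keep pairs seen in enough samples."""
    params = params or Parameters()
    flat: List[FusionCandidate] = []
    for item in candidates:
        if isinstance(item, FusionCandidate):
            flat.append(item)
        else:
            flat.extend(item)
    by_pair: Dict[Tuple[str, str], List[FusionCandidate]] = {}
    for cand in flat:
        by_pair.setdefault(cand.gene_pair, []).append(cand)
    groups: List[FusionGroup] = []
    for pair in sorted(by_pair):
        members = sorted(by_pair[pair], key=lambda c: (c.sample_id, c.coords))
        if len({m.sample_id for m in members}) >= params.group_min_samples:
            groups.append(FusionGroup(gene_pair=pair, members=members))
    return groups


def conserved_positions(group: FusionGroup) -> Tuple[bool, bool, bool, bool]:
    """Per-coordinate mask: True where the position is identical in all members."""
    coords = np.array([m.coords for m in group.members], dtype=np.int64)
    mask = tuple(bool(np.all(coords[:, j] == coords[0, j])) for j in range(4))
    return mask


def position_distance_matrix(
    group: FusionGroup, mask: Sequence[bool]
) -> np.ndarray:
    """Pairwise Euclidean distances over the non-conserved coordinates."""
    coords = np.array([m.coords for m in group.members], dtype=float)
    free = [j for j in range(4) if not mask[j]]
    n = len(group.members)
    if not free:
        return np.zeros((n, n))
    pts = coords[:, free]
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def median_fusion_length(group: FusionGroup) -> float:
    """Median of members' fusion lengths (mean of middle two for even counts)."""
    return float(np.median([m.fusion_len_bp for m in group.members]))


def complete_linkage(matrix: np.ndarray) -> List[Merge]:
    """Agglomerate with complete linkage; deterministic tie-breaking.

    At each step the cluster pair with the smallest maximal inter-member
    distance is merged; ties break toward the pair with the smallest member
    indices. Returns the n-1 merges with their heights.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    clusters: List[Tuple[int, ...]] = [(i,) for i in range(n)]
    merges: List[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(matrix[a, b] for a in clusters[i] for b in clusters[j])
                key = (d, clusters[i][0], clusters[j][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        merges.append((float(d), clusters[i], clusters[j]))
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return merges


def cut_dendrogram(merges: Sequence[Merge], n: int, height: float) -> List[Tuple[int, ...]]:
    """Clusters obtained by applying all merges with height <= ``height``."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for h, a, b in merges:
        if h <= height:
            ra, rb = find(a[0]), find(b[0])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted((tuple(sorted(v)) for v in clusters.values()), key=lambda c: c[0])


def cluster_group(
    group: FusionGroup,
    matrix: np.ndarray,
    params: Optional[Parameters] = None,
    cut_mode: str = "height",
) -> List[object]:
    """Subgroup labels for each member, or DISCARDED.

    ``cut_mode="height"`` cuts the dendrogram at length_fraction x the
    group's median fusion length (the 40% rule). ``cut_mode="min_cluster_size"``
    cuts at the smallest merge height at which every cluster covers at least
    ``group_min_samples`` samples — useful when member lengths are unknown.
    Clusters covering fewer than ``group_min_samples`` samples are discarded;
    the rest are numbered 1..k by ascending minimal member coordinates.
    """
    params = params or Parameters()
    n = len(group.members)
    merges = complete_linkage(matrix)
    if cut_mode == "height":
        cut = params.length_fraction * median_fusion_length(group)
        clusters = cut_dendrogram(merges, n, cut)
    elif cut_mode == "min_cluster_size":
        heights = sorted({0.0} | {m[0] for m in merges})
        clusters = [tuple(range(n))]
        for h in heights:
            trial = cut_dendrogram(merges, n, h)
            if all(
                len({group.members[i].sample_id for i in c}) >= params.group_min_samples
                for c in trial
            ):
                clusters = trial
                break
        else:  # pragma: no cover - full merge always satisfies the rule
            clusters = cut_dendrogram(merges, n, float("inf"))
    else:
        raise ValueError(f"unknown cut_mode {cut_mode!r}")

    labels: List[object] = [DISCARDED] * n
    kept = [
        c
        for c in clusters
        if len({group.members[i].sample_id for i in c}) >= params.group_min_samples
    ]
    kept.sort(key=lambda c: min(group.members[i].coords for i in c))
    for number, cluster in enumerate(kept, start=1):
        for i in cluster:
            labels[i] = number
    return labels


def evaluate_all(
    candidates: Union[Iterable[Sequence[FusionCandidate]], Sequence[FusionCandidate]],
    params: Optional[Parameters] = None,
    cut_mode: str = "height",
) -> List[FusionGroup]:
    """Full cross-sample pipeline: collect, conserve, cluster, label.

    Groups with fewer than two conserved coordinates are rejected. Returned
    groups carry the conservation mask, median fusion length and subgroup
    labels (DISCARDED for members cut away).
    """
    params = params or Parameters()
    groups = collect_groups(candidates, params)
    out: List[FusionGroup] = []
    for group in groups:
        mask = conserved_positions(group)
        if sum(mask) < 2:
            logger.info(
                "group %s-%s rejected: only %d conserved coordinate(s)",
                group.gene_pair[0],
                group.gene_pair[1],
                sum(mask),
            )
            continue
        matrix = position_distance_matrix(group, mask)
        group.conserved_mask = mask
        group.median_len_bp = median_fusion_length(group)
        group.subgroup_labels = cluster_group(group, matrix, params, cut_mode=cut_mode)
        out.append(group)
    return out


def reported_subgroups(group: FusionGroup) -> Dict[int, List[FusionCandidate]]:
    """Members of each reported (non-discarded) subgroup, keyed by label."""
    assert group.subgroup_labels is not None
    subgroups: Dict[int, List[FusionCandidate]] = {}
    for member, label in zip(group.members, group.subgroup_labels):
        if label != DISCARDED:
            subgroups.setdefault(int(label), []).append(member)
    return subgroups


def export_dendrogram(merges: Sequence[Merge], member_ids: Sequence[str], path) -> None:
    """Write merge heights and member labels as TSV (for external plotting)."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("height\tcluster_a\tcluster_b\n")
        for h, a, b in merges:
            ids_a = ",".join(member_ids[i] for i in a)
            ids_b = ",".join(member_ids[i] for i in b)
            out.write(f"{h:.6f}\t{ids_a}\t{ids_b}\n")
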