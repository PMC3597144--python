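"""Segmentation cleaning, breakpoint detection and gene anchoring.

The detection substrate is a cleaned per-sample segmentation: segments
supported by too few probes are indistinguishable from experimental or
algorithmic artifacts and are removed before breakpoints are enumerated.
Genes are then tied to breakpoints either by spanning one (the gene is split
into subsegments) or by lying within a fixed distance of a boundary.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set

from .io import merge_same_cn
from .model import (
    BOTH,
    FIVE_PRIME,
    THREE_PRIME,
    AnchoredGene,
    Breakpoint,
    GeneModel,
    Segment,
    SegmentationProfile,
)
from .params import Parameters

logger = logging.getLogger("segfuse")


def remove_single_probe_segments(
    profile: SegmentationProfile, params: Optional[Parameters] = None
) -> SegmentationProfile:
    """Drop artifact segments supported by too few probes.

    A removed run's interval and probe count are absorbed into the surviving
    left flank (the right flank when there is none on the left); flanks of
    equal copy number that become adjacent are merged. Chromosomes consisting
    solely of artifacts are dropped.
    """
    params = params or Parameters()
    threshold = params.artifact_max_probes
    cleaned: Dict[str, List[Segment]] = {}
    for chrom, segs in profile.segments.items():
        survivors: List[Segment] = []
        # probe counts / intervals pending absorption into the next survivor
        pending_probes = 0
        pending_start: Optional[int] = None
        for seg in segs:
            if seg.n_probes <= threshold:
                pending_probes += seg.n_probes
                if pending_start is None:
                    pending_start = seg.start
                pending_end = seg.end
                if survivors:
                    prev = survivors.pop()
                    survivors.append(
                        Segment(
                            chrom=prev.chrom,
                            start=prev.start,
                            end=pending_end,
                            n_probes=prev.n_probes + pending_probes,
                            total_cn=prev.total_cn,
                        )
                    )
                    pending_probes = 0
                    pending_start = None
            else:
                if pending_probes:
                    # artifacts at the chromosome start: absorb rightward
                    seg = Segment(
                        chrom=seg.chrom,
                        start=pending_start,
                        end=seg.end,
                        n_probes=seg.n_probes + pending_probes,
                        total_cn=seg.total_cn,
                    )
                    pending_probes = 0
                    pending_start = None
                survivors.append(seg)
        if not survivors:
            logger.warning("chromosome %s consists only of artifact segments; dropped", chrom)
            continue
        cleaned[chrom] = merge_same_cn(survivors)
    return SegmentationProfile(sample_id=profile.sample_id, segments=cleaned).validate()


def detect_breakpoints(profile: SegmentationProfile) -> List[Breakpoint]:
    """One breakpoint per adjacent segment pair with differing copy number."""
    out: List[Breakpoint] = []
    for chrom in profile.chromosomes():
        segs = profile.segments[chrom]
        for left, right in zip(segs, segs[1:]):
            if left.total_cn != right.total_cn:
                out.append(Breakpoint(chrom=chrom, left_segment=left, right_segment=right))
    return out


def _role_from_boundaries(gene: GeneModel, bp_left, bp_right) -> Optional[str]:
    """Role of an anchored interval from the boundaries it faces.

    An interval can donate a 5' part only if a boundary sits at its
    transcriptional 3' end, and a 3' part only if one sits at its
    transcriptional 5' end.
    """
    if gene.strand == "+":
        five_ok, three_ok = bp_right is not None, bp_left is not None
    else:
        five_ok, three_ok = bp_left is not None, bp_right is not None
    if five_ok and three_ok:
        return BOTH
    if five_ok:
        return FIVE_PRIME
    if three_ok:
        return THREE_PRIME
    return None


def anchor_genes(
    breakpoints: Sequence[Breakpoint],
    genes: Iterable[GeneModel],
    params: Optional[Parameters] = None,
    known_chromosomes: Optional[Set[str]] = None,
) -> List[AnchoredGene]:
    """Tie genes to breakpoints, assigning 5'/3' roles by transcript direction.

    Spanning genes are split at every interior boundary; the most upstream
    subsegment (in transcript orientation) becomes the 5' part, the most
    downstream the 3' part, and inner subsegments take both roles. A gene that
    does not span a boundary is anchored whole when its nearer end lies within
    ``max_breakpoint_distance_bp`` of one; the donated role then follows from
    strand and which gene end faces the break.
    """
    params = params or Parameters()
    by_chrom: Dict[str, List[Breakpoint]] = {}
    for bp in breakpoints:
        by_chrom.setdefault(bp.chrom, []).append(bp)
    for bps in by_chrom.values():
        bps.sort(key=lambda b: b.boundary_pos)

    anchored: List[AnchoredGene] = []
    for gene in genes:
        if known_chromosomes is not None and gene.chrom not in known_chromosomes:
            logger.warning(
                "gene %s on chromosome %s absent from segmentation; skipped",
                gene.gene_id,
                gene.chrom,
            )
            continue
        bps = by_chrom.get(gene.chrom, [])
        if not bps:
            continue
        interior = [b for b in bps if gene.start <= b.boundary_pos < gene.end]
        if interior:
            anchored.extend(_split_gene(gene, interior, bps, params))
        else:
            whole = _anchor_whole(gene, bps, params)
            if whole is not None:
                anchored.append(whole)
    anchored.sort(key=lambda a: (a.gene.chrom, a.sub_start, a.sub_end, a.gene.gene_id))
    return anchored


def _nearest_outside(gene_start: int, gene_end: int, bps: List[Breakpoint], max_dist: int):
    """Nearest qualifying boundaries left of the gene start / right of its end."""
    left = None
    right = None
    for bp in bps:
        pos = bp.boundary_pos
        if pos < gene_start and gene_start - pos <= max_dist:
            if left is None or pos > left.boundary_pos:
                left = bp
        elif pos >= gene_end and pos - gene_end <= max_dist:
            if right is None or pos < right.boundary_pos:
                right = bp
    return left, right


def _split_gene(
    gene: GeneModel,
    interior: List[Breakpoint],
    all_bps: List[Breakpoint],
    params: Parameters,
) -> List[AnchoredGene]:
    out_left, out_right = _nearest_outside(
        gene.start, gene.end, all_bps, params.max_breakpoint_distance_bp
    )
    edges = [gene.start - 1] + [b.boundary_pos for b in interior] + [gene.end]
    pieces: List[AnchoredGene] = []
    for i in range(len(interior) + 1):
        sub_start, sub_end = edges[i] + 1, edges[i + 1]
        bp_left = interior[i - 1] if i > 0 else out_left
        bp_right = interior[i] if i < len(interior) else out_right
        cn = interior[i - 1].right_segment.total_cn if i > 0 else interior[0].left_segment.total_cn
        role = _role_from_boundaries(gene, bp_left, bp_right)
        if role is None:
            continue
        pieces.append(
            AnchoredGene(
                gene=gene,
                role=role,
                sub_start=sub_start,
                sub_end=sub_end,
                total_cn=cn,
                bp_left=bp_left,
                bp_right=bp_right,
            )
        )
    return pieces


def _anchor_whole(
    gene: GeneModel, bps: List[Breakpoint], params: Parameters
) -> Optional[AnchoredGene]:
    left, right = _nearest_outside(gene.start, gene.end, bps, params.max_breakpoint_distance_bp)
    if left is None and right is None:
        return None
    if right is not None:
        cn = right.left_segment.total_cn
    else:
        cn = left.right_segment.total_cn
    role = _role_from_boundaries(gene, left, right)
    if role is None:
        return None
    return AnchoredGene(
        gene=gene,
        role=role,
        sub_start=gene.start,
        sub_end=gene.end,
        total_cn=cn,
        bp_left=left,
        bp_right=right,
    )
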