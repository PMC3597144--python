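"""Per-sample constraint funnel: from anchored genes to fusion candidates.

An ordered (5', 3') gene pair survives when

* the total copy numbers of the two partners differ by at most the tolerance
  (joined DNA is replicated together),
* the strand orientation at each partner's fusion side preserves transcription
  direction across the junction,
* the combined subsegment length lies within the fusion-length bounds derived
  from the gene collection,
* each partner contributes a full crossover window of probes next to its
  boundary, and
* the two loess-smoothed crossover series correlate with |r| above the cutoff
  (the sign is ignored; inverted dye response is still a consistent trend).

Survivors carry the correlation, the root-mean-square difference of the two
smoothed series (near zero for a consistent crossover) and the span used.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .loess import LoessError, select_loess_span, smooth_loess
from .model import (
    BOTH,
    FIVE_PRIME,
    THREE_PRIME,
    AnchoredGene,
    Breakpoint,
    CrossoverWindow,
    FusionCandidate,
    ProbePanel,
    ProbeRecord,
)
from .params import ConfigurationError, Parameters

logger = logging.getLogger("segfuse")

#: One drop-log entry: (sample, five_gene, three_gene, stage, reason)
DropEntry = Tuple[str, str, str, str, str]


class DegenerateWindowError(ValueError):
    """A smoothed crossover side has zero variance."""


def _same_breakpoint(a: Optional[Breakpoint], b: Optional[Breakpoint]) -> bool:
    return a is not None and b is not None and a == b


def _self_pairing(five: AnchoredGene, three: AnchoredGene) -> bool:
    """A gene (or subsegments of one gene) paired with itself at one break."""
    if five is three:
        return True
    if five.gene.gene_id != three.gene.gene_id:
        return False
    shared = (
        _same_breakpoint(five.bp_left, three.bp_left)
        or _same_breakpoint(five.bp_left, three.bp_right)
        or _same_breakpoint(five.bp_right, three.bp_left)
        or _same_breakpoint(five.bp_right, three.bp_right)
    )
    return shared


def enumerate_pairs(
    anchored: Sequence[AnchoredGene],
) -> List[Tuple[AnchoredGene, AnchoredGene]]:
    """All ordered (5'-capable, 3'-capable) pairs of anchored genes.

    A gene — or two subsegments of one gene — is never paired with itself at
    the same breakpoint; subsegments of one gene at different breakpoints may
    pair (an internal deletion joining the gene's own flanks).
    """
    fives = [a for a in anchored if a.role in (FIVE_PRIME, BOTH)]
    threes = [a for a in anchored if a.role in (THREE_PRIME, BOTH)]
    return [(f, t) for f in fives for t in threes if not _self_pairing(f, t)]


def orientation_ok(strand5: str, side5: str, strand3: str, side3: str) -> bool:
    """Read-through rule on raw strand / fusion-side combinations.

    ``side`` names the gene end facing the junction ("left"/"right" in
    genomic coordinates). The 5' partner must present its transcriptional 3'
    end and the 3' partner its transcriptional 5' end, so transcription runs
    continuously across the junction.
    """
    need5 = "right" if strand5 == "+" else "left"
    need3 = "left" if strand3 == "+" else "right"
    return side5 == need5 and side3 == need3


def filter_cn(five: AnchoredGene, three: AnchoredGene, params: Parameters) -> bool:
    """Keep iff the partners' total copy numbers differ by at most the tolerance."""
    return abs(five.total_cn - three.total_cn) <= params.cn_tolerance


def filter_orientation(five: AnchoredGene, three: AnchoredGene) -> bool:
    """Keep iff each partner faces a boundary at the strand-appropriate end."""
    return five.boundary_for(FIVE_PRIME) is not None and three.boundary_for(THREE_PRIME) is not None


def filter_length(five: AnchoredGene, three: AnchoredGene, params: Parameters) -> bool:
    """Keep iff the summed subsegment length lies within the fusion bounds."""
    if params.min_fusion_len_bp is None or params.max_fusion_len_bp is None:
        raise ConfigurationError(
            "fusion length bounds unset; derive them from the gene collection first"
        )
    fusion_len = five.sub_length + three.sub_length
    return params.min_fusion_len_bp <= fusion_len <= params.max_fusion_len_bp


def nearest_probes(
    probes: ProbePanel, chrom: str, start: int, end: int, boundary_pos: int, k: int
) -> List[ProbeRecord]:
    """The k probes inside [start, end] nearest ``boundary_pos``.

    Ties in distance break toward the lower position. Returned in order of
    increasing distance from the boundary.
    """
    records = probes.in_interval(chrom, start, end)
    records = sorted(records, key=lambda r: (abs(r.pos - boundary_pos), r.pos))
    return records[:k]


def crossover_window(
    five: AnchoredGene,
    three: AnchoredGene,
    probes: ProbePanel,
    params: Parameters,
) -> Optional[CrossoverWindow]:
    """Raw crossover window for a pair, or None when a side has too few probes.

    The 5' series is ordered toward the junction (distance decreasing) and
    the 3' series away from it, forming one continuous virtual track.
    """
    b5 = five.boundary_for(FIVE_PRIME)
    b3 = three.boundary_for(THREE_PRIME)
    if b5 is None or b3 is None:
        return None
    k = params.crossover_probes
    five_recs = nearest_probes(probes, five.gene.chrom, five.sub_start, five.sub_end, b5.boundary_pos, k)
    three_recs = nearest_probes(
        probes, three.gene.chrom, three.sub_start, three.sub_end, b3.boundary_pos, k
    )
    if len(five_recs) < k or len(three_recs) < k:
        return None
    five_vals = [r.intensity for r in reversed(five_recs)]  # far -> near junction
    three_vals = [r.intensity for r in three_recs]  # near -> far
    return CrossoverWindow(five_prime_intensities=five_vals, three_prime_intensities=three_vals)


def smooth_window(window: CrossoverWindow, params: Parameters) -> CrossoverWindow:
    """Select a span on the concatenated track, then smooth each side with it."""
    span = select_loess_span(window.track(), params)
    window.five_prime_smoothed = list(smooth_loess(window.five_prime_intensities, span))
    window.three_prime_smoothed = list(smooth_loess(window.three_prime_intensities, span))
    window.span_used = span
    return window


def crossover_correlation(window: CrossoverWindow) -> float:
    """Pearson correlation between the two smoothed crossover series."""
    a = np.asarray(window.five_prime_smoothed, dtype=float)
    b = np.asarray(window.three_prime_smoothed, dtype=float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateWindowError("degenerate window")
    return float(stats.pearsonr(a, b).statistic)


def crossover_rms(window: CrossoverWindow) -> float:
    """Root mean squared difference between the two smoothed series."""
    a = np.asarray(window.five_prime_smoothed, dtype=float)
    b = np.asarray(window.three_prime_smoothed, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def evaluate_candidates(
    anchored: Sequence[AnchoredGene],
    probes: ProbePanel,
    params: Parameters,
    sample_id: Optional[str] = None,
    drop_log: Optional[List[DropEntry]] = None,
) -> List[FusionCandidate]:
    """Run the full constraint funnel over all ordered anchored-gene pairs.

    Pairs are enumerated permissively into both slots and pruned stage by
    stage (cn -> orientation -> length -> window -> smoothing -> correlation);
    each rejected pair leaves one drop-log entry naming the stage reached.
    """
    sample = sample_id if sample_id is not None else probes.sample_id
    out: List[FusionCandidate] = []
    n_pairs = 0
    capped = False
    for five in anchored:
        for three in anchored:
            if _self_pairing(five, three):
                continue
            n_pairs += 1
            if n_pairs > params.max_pairs_per_sample:
                if not capped:
                    logger.warning(
                        "sample %s: candidate pairs exceed cap %d; remainder skipped",
                        sample,
                        params.max_pairs_per_sample,
                    )
                    capped = True
                break
            pair_ids = (five.gene.gene_id, three.gene.gene_id)

            def drop(stage: str, reason: str) -> None:
                if drop_log is not None:
                    drop_log.append((sample, pair_ids[0], pair_ids[1], stage, reason))

            if not filter_cn(five, three, params):
                drop("cn", f"|CN {five.total_cn} - {three.total_cn}| > {params.cn_tolerance}")
                continue
            if not filter_orientation(five, three):
                drop("orientation", "strand orientation breaks read-through at the junction")
                continue
            if not filter_length(five, three, params):
                drop(
                    "length",
                    f"fusion length {five.sub_length + three.sub_length} outside "
                    f"[{params.min_fusion_len_bp}, {params.max_fusion_len_bp}]",
                )
                continue
            window = crossover_window(five, three, probes, params)
            if window is None:
                drop("window", f"a side has fewer than {params.crossover_probes} probes")
                continue
            try:
                smooth_window(window, params)
            except LoessError as exc:
                drop("window", str(exc))
                continue
            try:
                corr = crossover_correlation(window)
            except DegenerateWindowError:
                drop("correlation", "degenerate window")
                continue
            if abs(corr) <= params.min_abs_correlation:
                drop("correlation", f"|r| = {abs(corr):.4f} <= {params.min_abs_correlation}")
                continue
            out.append(
                FusionCandidate(
                    sample_id=sample,
                    five_gene_id=five.gene.gene_id,
                    three_gene_id=three.gene.gene_id,
                    five_prime=five,
                    three_prime=three,
                    coords=(five.sub_start, five.sub_end, three.sub_start, three.sub_end),
                    cn_pair=(five.total_cn, three.total_cn),
                    correlation=corr,
                    rms=crossover_rms(window),
                    fusion_len_bp=five.sub_length + three.sub_length,
                    span_used=window.span_used,
                )
            )
        if capped:
            break
    out.sort(key=lambda c: (c.gene_pair, c.coords))
    return out


def format_drop_log(entries: Iterable[DropEntry]) -> str:
    """Render drop-log entries as 'sample<TAB>gene5<TAB>gene3<TAB>stage<TAB>reason' lines."""
    return "\n".join("\t".join(e) for e in entries)
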