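"""End-to-end wiring: clean, detect, anchor, filter, group.

Thin orchestration over the stage modules; every step is individually
importable for finer control.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

from .breakpoints import anchor_genes, detect_breakpoints, remove_single_probe_segments
from .constraints import DropEntry, evaluate_candidates
from .grouping import evaluate_all
from .model import (
    AnchoredGene,
    FusionCandidate,
    FusionGroup,
    GeneModel,
    ProbePanel,
    SegmentationProfile,
)
from .params import Parameters
from .simulate import CohortDataset

logger = logging.getLogger("segfuse")


def detect_sample(
    profile: SegmentationProfile,
    panel: ProbePanel,
    genes: Sequence[GeneModel],
    params: Optional[Parameters] = None,
    drop_log: Optional[List[DropEntry]] = None,
) -> Tuple[List[FusionCandidate], List[AnchoredGene]]:
    """Per-sample detection: returns surviving candidates and the anchor set."""
    params = params or Parameters()
    if params.min_fusion_len_bp is None or params.max_fusion_len_bp is None:
        params = params.with_length_bounds_from(genes)
    cleaned = remove_single_probe_segments(profile, params)
    breakpoints = detect_breakpoints(cleaned)
    anchored = anchor_genes(
        breakpoints, genes, params, known_chromosomes=set(profile.segments)
    )
    logger.info(
        "sample %s: %d breakpoints, %d anchored gene intervals",
        profile.sample_id,
        len(breakpoints),
        len(anchored),
    )
    candidates = evaluate_candidates(
        anchored, panel, params, sample_id=profile.sample_id, drop_log=drop_log
    )
    logger.info("sample %s: %d fusion candidates", profile.sample_id, len(candidates))
    return candidates, anchored


def run_cohort(
    dataset: CohortDataset,
    params: Optional[Parameters] = None,
    cut_mode: str = "height",
    drop_log: Optional[List[DropEntry]] = None,
) -> Tuple[List[FusionGroup], Dict[str, List[FusionCandidate]]]:
    """Detect in every sample of a simulated cohort, then group across samples."""
    params = params or Parameters()
    if params.min_fusion_len_bp is None or params.max_fusion_len_bp is None:
        params = params.with_length_bounds_from(dataset.genes)
    per_sample: Dict[str, List[FusionCandidate]] = {}
    for sid in dataset.sample_ids():
        data = dataset.samples[sid]
        candidates, _ = detect_sample(
            data.profile, data.panel, dataset.genes, params, drop_log=drop_log
        )
        per_sample[sid] = candidates
    groups = evaluate_all(list(per_sample.values()), params, cut_mode=cut_mode)
    return groups, per_sample
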