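"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import pytest

import segfuse as sf


def make_segments(chrom: str, runs: Sequence[Tuple[int, int, int, int]]) -> List[sf.Segment]:
    """Runs of (start, end, n_probes, total_cn) on one chromosome."""
    return [
        sf.Segment(chrom=chrom, start=s, end=e, n_probes=n, total_cn=cn)
        for s, e, n, cn in runs
    ]


def make_profile(sample_id: str, runs_by_chrom: Dict[str, Sequence[Tuple[int, int, int, int]]]):
    return sf.SegmentationProfile(
        sample_id=sample_id,
        segments={c: make_segments(c, runs) for c, runs in runs_by_chrom.items()},
    ).validate()


def make_panel(sample_id: str, probes: Sequence[Tuple[str, int, float]]) -> sf.ProbePanel:
    records = [
        sf.ProbeRecord(probe_id=f"p{i}", chrom=c, pos=p, intensity=v)
        for i, (c, p, v) in enumerate(probes)
    ]
    return sf.ProbePanel(sample_id=sample_id, records=records)


def make_gene(gene_id: str, chrom: str, start: int, end: int, strand: str = "+") -> sf.GeneModel:
    return sf.GeneModel(
        gene_id=gene_id, gene_name=gene_id, chrom=chrom, start=start, end=end, strand=strand
    )


def flat_candidate(sample_id: str, coords, pair=("GA", "GB"), cn=(3, 3)) -> sf.FusionCandidate:
    return sf.FusionCandidate(
        sample_id=sample_id,
        five_gene_id=pair[0],
        three_gene_id=pair[1],
        coords=tuple(coords),
        cn_pair=tuple(cn),
        correlation=1.0,
        rms=0.0,
        fusion_len_bp=(coords[1] - coords[0] + 1) + (coords[3] - coords[2] + 1),
    )


def make_breakpoint(
    chrom: str, left_end: int, right_start: int, cn_left: int = 4, cn_right: int = 2
) -> sf.Breakpoint:
    left = sf.Segment(chrom=chrom, start=max(1, left_end - 50_000), end=left_end,
                      n_probes=50, total_cn=cn_left)
    right = sf.Segment(chrom=chrom, start=right_start, end=right_start + 50_000,
                       n_probes=50, total_cn=cn_right)
    return sf.Breakpoint(chrom=chrom, left_segment=left, right_segment=right)


def make_anchor(
    gene: sf.GeneModel,
    role: str,
    total_cn: int,
    bp_left: sf.Breakpoint = None,
    bp_right: sf.Breakpoint = None,
    sub: Tuple[int, int] = None,
) -> sf.AnchoredGene:
    sub = sub or (gene.start, gene.end)
    return sf.AnchoredGene(
        gene=gene, role=role, sub_start=sub[0], sub_end=sub[1], total_cn=total_cn,
        bp_left=bp_left, bp_right=bp_right,
    )


@pytest.fixture(scope="session")
def study_cohort() -> sf.CohortDataset:
    """The reference cohort with the compliant fusion and all five controls."""
    config = sf.plant_noncompliant_controls(sf.default_config(seed=7))
    return sf.simulate_cohort(config)


@pytest.fixture(scope="session")
def study_results(study_cohort):
    """Full pipeline output on the reference cohort, with the drop log."""
    drop_log: list = []
    groups, per_sample = sf.run_cohort(study_cohort, drop_log=drop_log)
    return groups, per_sample, drop_log
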