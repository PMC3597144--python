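"""Synthetic cohorts with planted unbalanced fusions.

The generator emulates what the caller consumes downstream of array
segmentation: per-sample constant-copy-number segments over a regular probe
grid, probe intensities whose spread grows with the copy number, a gene
annotation, and a truth table. A planted fusion is realised as two altered
copy-number intervals — one ending at the 5' gene's junction, one starting at
the 3' gene's junction — plus a shared linear intensity trend across the
junction's crossover probes (two physically joined partners are replicated
together, so their border intensities drift together). Single-probe
copy-number spikes model segmentation artifacts.

Intensity model: a probe in a CN = c segment draws from
N(log2((c + 0.1) / 2), base_sd + sd_per_cn * c) — a smooth monotone
log-ratio location with linearly CN-dependent noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import write_gene_models_bed, write_probes, write_segmentation
from .model import (
    GeneModel,
    ProbePanel,
    ProbeRecord,
    Segment,
    SegmentationProfile,
    ValidationError,
)

BASELINE_CN = 2
#: artifacts are kept away from planted junctions by this margin
ARTIFACT_MARGIN_BP = 20_000


def mean_intensity(cn: float) -> float:
    """Monotone CN-to-intensity location: log2((cn + 0.1) / 2)."""
    return math.log2((cn + 0.1) / 2.0)


@dataclass(frozen=True)
class NoiseModel:
    """Probe-intensity noise: sd = base_sd + sd_per_cn * CN."""

    base_sd: float = 0.02
    sd_per_cn: float = 0.01

    def sd(self, cn) -> np.ndarray:
        return self.base_sd + self.sd_per_cn * np.asarray(cn, dtype=float)


@dataclass(frozen=True)
class PlantedFusion:
    """One planted event: altered CN intervals flanking a gene pair.

    ``seg5`` is the altered interval ending at the 5' junction (its right
    edge), ``seg3`` the interval starting at the 3' junction (left edge).
    ``junction_trend`` is the per-probe intensity increment of the shared
    linear drift across the crossover window (0 disables it).
    """

    name: str
    gene5: GeneModel
    gene3: GeneModel
    seg5: Tuple[int, int]
    seg3: Tuple[int, int]
    cn5: int
    cn3: int
    samples: Tuple[int, ...]
    jitter_bp: float = 0.0
    junction_trend: float = 0.1
    compliant: bool = True
    expected_drop: str = ""


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    fusion_name: str
    gene5_id: str
    gene3_id: str
    five_start: int
    five_end: int
    three_start: int
    three_end: int
    cn5: int
    cn3: int
    compliant: bool
    expected_drop: str


@dataclass
class SimulationConfig:
    seed: int
    chromosomes: Dict[str, int] = field(default_factory=dict)
    probe_spacing_bp: int = 1_000
    n_samples: int = 5
    genes: List[GeneModel] = field(default_factory=list)
    fusions: List[PlantedFusion] = field(default_factory=list)
    constant_regions: Dict[str, List[Tuple[int, int, int]]] = field(default_factory=dict)
    artifact_rate: float = 0.0005
    artifact_cn_shift: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)

    def validate(self) -> "SimulationConfig":
        if self.seed is None:
            raise ValidationError("simulation seed is mandatory")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.probe_spacing_bp < 1:
            raise ValidationError("probe_spacing_bp must be >= 1")
        for fus in self.fusions:
            if fus.cn5 < 0 or fus.cn3 < 0:
                raise ValidationError(f"fusion {fus.name}: CN values must be non-negative")
            if fus.jitter_bp < 0:
                raise ValidationError(f"fusion {fus.name}: jitter must be >= 0")
            for gene in (fus.gene5, fus.gene3):
                if gene.chrom not in self.chromosomes:
                    raise ValidationError(
                        f"fusion {fus.name}: gene {gene.gene_id} on unknown chromosome"
                    )
        # event genes of *different* ids must not overlap on a chromosome
        event_genes: Dict[str, GeneModel] = {}
        for fus in self.fusions:
            for gene in (fus.gene5, fus.gene3):
                event_genes.setdefault(gene.gene_id, gene)
        genes_list = list(event_genes.values())
        for i, a in enumerate(genes_list):
            for b in genes_list[i + 1 :]:
                if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                    raise ValidationError(
                        f"fusion genes {a.gene_id} and {b.gene_id} overlap on {a.chrom}"
                    )
        return self


@dataclass
class SampleData:
    profile: SegmentationProfile
    panel: ProbePanel


@dataclass
class CohortDataset:
    config: SimulationConfig
    genes: List[GeneModel]
    samples: Dict[str, SampleData]
    truth: List[TruthRecord]

    def sample_ids(self) -> List[str]:
        return sorted(self.samples)


def _probe_positions(length: int, spacing: int) -> np.ndarray:
    return np.arange(spacing, length + 1, spacing, dtype=np.int64)


def _boundary_between(left_pos: int, right_pos: int) -> int:
    return (left_pos + right_pos) // 2


def _realized_edges(fus: PlantedFusion, rng: np.random.Generator) -> Tuple[int, int]:
    """Jittered junction edges: seg5 right edge and seg3 left edge."""
    b5 = fus.seg5[1]
    a3 = fus.seg3[0]
    if fus.jitter_bp > 0:
        b5 += int(round(rng.normal(0.0, fus.jitter_bp)))
        a3 += int(round(rng.normal(0.0, fus.jitter_bp)))
    return b5, a3


def simulate_sample(
    config: SimulationConfig, sample_idx: int
) -> Tuple[SegmentationProfile, ProbePanel, List[TruthRecord]]:
    """One sample: CN per probe, segmentation, intensities, truth records."""
    sample_id = f"S{sample_idx + 1:02d}"
    rng = np.random.default_rng([config.seed, sample_idx])

    positions = {
        chrom: _probe_positions(length, config.probe_spacing_bp)
        for chrom, length in sorted(config.chromosomes.items())
    }
    cn = {chrom: np.full(pos.size, BASELINE_CN, dtype=np.int64) for chrom, pos in positions.items()}
    altered: Dict[str, List[Tuple[int, int]]] = {chrom: [] for chrom in positions}

    for chrom, regions in sorted(config.constant_regions.items()):
        for start, end, value in regions:
            mask = (positions[chrom] >= start) & (positions[chrom] <= end)
            cn[chrom][mask] = value
            altered[chrom].append((start, end))

    # realize planted events (jitter draws happen in fixed name order)
    realized: List[Tuple[PlantedFusion, int, int]] = []
    for fus in sorted(config.fusions, key=lambda f: f.name):
        if sample_idx not in fus.samples:
            continue
        b5, a3 = _realized_edges(fus, rng)
        realized.append((fus, b5, a3))
        c5, p5 = fus.gene5.chrom, positions[fus.gene5.chrom]
        mask5 = (p5 >= fus.seg5[0]) & (p5 <= b5)
        cn[c5][mask5] = fus.cn5
        altered[c5].append((fus.seg5[0], b5))
        c3, p3 = fus.gene3.chrom, positions[fus.gene3.chrom]
        mask3 = (p3 >= a3) & (p3 <= fus.seg3[1])
        cn[c3][mask3] = fus.cn3
        altered[c3].append((a3, fus.seg3[1]))

    # single-probe CN spikes on undisturbed baseline territory
    for chrom in sorted(positions):
        pos = positions[chrom]
        eligible = cn[chrom] == BASELINE_CN
        for start, end in altered[chrom]:
            eligible &= ~(
                (pos >= start - ARTIFACT_MARGIN_BP) & (pos <= end + ARTIFACT_MARGIN_BP)
            )
        spikes = eligible & (rng.random(pos.size) < config.artifact_rate)
        cn[chrom][spikes] += config.artifact_cn_shift

    # intensities: CN-dependent location and spread
    intensity = {}
    for chrom in sorted(positions):
        means = np.log2((cn[chrom] + 0.1) / 2.0)
        sds = config.noise.sd(cn[chrom])
        intensity[chrom] = rng.normal(means, sds)

    # shared junction trend across each planted crossover window
    truth: List[TruthRecord] = []
    for fus, b5, a3 in realized:
        c5, c3 = fus.gene5.chrom, fus.gene3.chrom
        p5, p3 = positions[c5], positions[c3]
        in5 = p5[(p5 >= fus.seg5[0]) & (p5 <= b5)]
        after5 = p5[p5 > b5]
        boundary5 = _boundary_between(int(in5[-1]), int(after5[0])) if in5.size and after5.size else b5
        in3 = p3[(p3 >= a3) & (p3 <= fus.seg3[1])]
        before3 = p3[p3 < a3]
        boundary3 = _boundary_between(int(before3[-1]), int(in3[0])) if in3.size and before3.size else a3

        five_start = fus.gene5.start
        five_end = min(fus.gene5.end, boundary5)
        three_start = max(fus.gene3.start, boundary3 + 1)
        three_end = fus.gene3.end
        if fus.junction_trend:
            _apply_trend(
                positions[c5], intensity[c5], five_start, five_end, boundary5, fus.junction_trend, side="five"
            )
            _apply_trend(
                positions[c3], intensity[c3], three_start, three_end, boundary3, fus.junction_trend, side="three"
            )
        truth.append(
            TruthRecord(
                sample_id=sample_id,
                fusion_name=fus.name,
                gene5_id=fus.gene5.gene_id,
                gene3_id=fus.gene3.gene_id,
                five_start=five_start,
                five_end=five_end,
                three_start=three_start,
                three_end=three_end,
                cn5=fus.cn5,
                cn3=fus.cn3,
                compliant=fus.compliant,
                expected_drop=fus.expected_drop,
            )
        )

    profile = SegmentationProfile(
        sample_id=sample_id,
        segments={
            chrom: _segments_from_cn(chrom, positions[chrom], cn[chrom])
            for chrom in sorted(positions)
        },
    ).validate()
    records = [
        ProbeRecord(
            probe_id=f"{chrom}_p{i + 1:06d}",
            chrom=chrom,
            pos=int(positions[chrom][i]),
            intensity=float(intensity[chrom][i]),
        )
        for chrom in sorted(positions)
        for i in range(positions[chrom].size)
    ]
    return profile, ProbePanel(sample_id=sample_id, records=records), truth


def _apply_trend(
    positions: np.ndarray,
    intensity: np.ndarray,
    start: int,
    end: int,
    boundary: int,
    slope: float,
    side: str,
    window: int = 7,
) -> None:
    """Add the shared linear drift to a side's crossover probes.

    Track index t runs 0..13 across the junction: the 5' side occupies
    t = 0..6 approaching the boundary, the 3' side t = 7..13 leaving it.
    """
    idx = np.nonzero((positions >= start) & (positions <= end))[0]
    if idx.size == 0:
        return
    dist = np.abs(positions[idx] - boundary)
    order = idx[np.lexsort((positions[idx], dist))][:window]
    for rank, i in enumerate(order):
        t = (window - 1 - rank) if side == "five" else (window + rank)
        intensity[i] += slope * (t - (window - 0.5))


def _segments_from_cn(chrom: str, positions: np.ndarray, cn: np.ndarray) -> List[Segment]:
    segments: List[Segment] = []
    run_start = 0
    for i in range(1, cn.size + 1):
        if i == cn.size or cn[i] != cn[run_start]:
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(positions[run_start]),
                    end=int(positions[i - 1]),
                    n_probes=i - run_start,
                    total_cn=int(cn[run_start]),
                )
            )
            run_start = i
    return segments


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Deterministic cohort for a validated configuration."""
    config.validate()
    samples: Dict[str, SampleData] = {}
    truth: List[TruthRecord] = []
    for idx in range(config.n_samples):
        profile, panel, records = simulate_sample(config, idx)
        samples[profile.sample_id] = SampleData(profile=profile, panel=panel)
        truth.extend(records)
    return CohortDataset(config=config, genes=list(config.genes), samples=samples, truth=truth)


TRUTH_COLUMNS = [
    "sample",
    "fusion",
    "five_gene",
    "three_gene",
    "five_start",
    "five_end",
    "three_start",
    "three_end",
    "cn_five",
    "cn_three",
    "compliant",
    "expected_drop",
]


def write_dataset(dataset: CohortDataset, outdir) -> None:
    """Write the cohort in the package's TSV/BED formats plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_models_bed(dataset.genes, outdir / "genes.bed")
    with open(outdir / "truth.tsv", "w", encoding="utf-8") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in dataset.truth:
            out.write(
                f"{t.sample_id}\t{t.fusion_name}\t{t.gene5_id}\t{t.gene3_id}"
                f"\t{t.five_start}\t{t.five_end}\t{t.three_start}\t{t.three_end}"
                f"\t{t.cn5}\t{t.cn3}\t{int(t.compliant)}\t{t.expected_drop}\n"
            )
    with open(outdir / "manifest.tsv", "w", encoding="utf-8") as out:
        out.write("sample\tsegments\tprobes\n")
        for sid in dataset.sample_ids():
            write_segmentation(dataset.samples[sid].profile, outdir / f"{sid}.segments.tsv")
            write_probes(dataset.samples[sid].panel, outdir / f"{sid}.probes.tsv")
            out.write(f"{sid}\t{sid}.segments.tsv\t{sid}.probes.tsv\n")


# --------------------------------------------------------------------------
# Default study cohort: one compliant recurrent fusion, optional negative
# controls, each on its own copy-number rung so that cross-event pairings are
# rejected by the CN filter and every control isolates a single constraint.
# --------------------------------------------------------------------------


def _gene(gene_id: str, chrom: str, start: int, end: int, strand: str) -> GeneModel:
    return GeneModel(
        gene_id=gene_id, gene_name=gene_id, chrom=chrom, start=start, end=end, strand=strand
    )


def default_config(seed: int, n_samples: int = 5) -> SimulationConfig:
    """The reference cohort: 5 samples, one compliant fusion in samples 0-2.

    The fusion joins a 60 kb forward-strand gene ending at a CN-4 junction on
    chr1 to a 40 kb forward-strand gene starting at a CN-3 junction on chr2,
    both within the anchoring distance. chr3 carries only background genes,
    including the 1.4 Mb gene that sets the maximal fusion length.
    """
    g5 = _gene("G5CMP", "chr1", 100_001, 160_000, "+")
    g3 = _gene("G3CMP", "chr2", 101_001, 141_000, "+")
    background = [
        _gene("GLONG", "chr3", 100_001, 1_500_000, "+"),
        _gene("GBG1", "chr3", 1_510_001, 1_530_000, "+"),
        _gene("GBG2", "chr3", 1_540_001, 1_560_000, "-"),
        _gene("GBG3", "chr3", 20_001, 60_000, "-"),
    ]
    compliant = PlantedFusion(
        name="FUS_CMP",
        gene5=g5,
        gene3=g3,
        seg5=(61_000, 160_000),
        seg3=(101_000, 200_000),
        cn5=4,
        cn3=3,
        samples=(0, 1, 2),
    )
    return SimulationConfig(
        seed=seed,
        chromosomes={"chr1": 2_600_000, "chr2": 2_600_000, "chr3": 1_600_000},
        n_samples=n_samples,
        genes=[g5, g3] + background,
        fusions=[compliant],
    )


def plant_noncompliant_controls(config: SimulationConfig) -> SimulationConfig:
    """Append five negative controls, each violating exactly one constraint.

    Laid out on the default cohort's chr1/chr2 territory, on copy-number
    rungs >= 2 apart from every other event: a CN gap of 2, a wrong-strand 3'
    partner, a fusion longer than the longest gene, a 3' subsegment of only
    six probes, and a gene 15 kb away from its breakpoint.
    """
    sp = config.probe_spacing_bp
    samples = tuple(sorted({s for f in config.fusions for s in f.samples})) or (0,)

    ori5 = _gene("G5ORI", "chr1", 520_001, 560_000, "+")
    ori3 = _gene("G3ORI", "chr2", 501_001, 541_000, "-")
    len5 = _gene("G5LEN", "chr1", 900_001, 1_660_000, "+")
    len3 = _gene("G3LEN", "chr2", 901_001, 1_661_000, "+")
    win5 = _gene("G5WIN", "chr1", 1_820_001, 1_860_000, "+")
    win3 = _gene("G3WIN", "chr2", 1_801_001, 1_801_000 + 6 * sp + 100, "+")
    cng5 = _gene("G5CNG", "chr1", 2_020_001, 2_060_000, "+")
    cng3 = _gene("G3CNG", "chr2", 2_001_001, 2_041_000, "+")
    dis5 = _gene("G5DIS", "chr1", 2_190_001, 2_245_000, "+")
    dis3 = _gene("G3DIS", "chr2", 2_286_001, 2_326_000, "+")

    controls = [
        PlantedFusion(
            name="CTL_ORIENTATION",
            gene5=ori5,
            gene3=ori3,
            seg5=(461_000, 560_000),
            seg3=(501_000, 600_000),
            cn5=6,
            cn3=7,
            samples=samples,
            compliant=False,
            expected_drop="orientation",
        ),
        PlantedFusion(
            name="CTL_LENGTH",
            gene5=len5,
            gene3=len3,
            seg5=(861_000, 1_660_000),
            seg3=(901_000, 1_700_000),
            cn5=9,
            cn3=10,
            samples=samples,
            compliant=False,
            expected_drop="length",
        ),
        PlantedFusion(
            name="CTL_WINDOW",
            gene5=win5,
            gene3=win3,
            seg5=(1_761_000, 1_860_000),
            seg3=(1_801_000, 1_900_000),
            cn5=12,
            cn3=13,
            samples=samples,
            compliant=False,
            expected_drop="window",
        ),
        PlantedFusion(
            name="CTL_CN",
            gene5=cng5,
            gene3=cng3,
            seg5=(1_961_000, 2_060_000),
            seg3=(2_001_000, 2_100_000),
            cn5=16,
            cn3=18,
            samples=samples,
            compliant=False,
            expected_drop="cn",
        ),
        PlantedFusion(
            name="CTL_DISTANCE",
            gene5=dis5,
            gene3=dis3,
            seg5=(2_161_000, 2_260_000),
            seg3=(2_271_000, 2_340_000),
            cn5=3,
            cn3=3,
            samples=samples,
            compliant=False,
            expected_drop="distance",
        ),
    ]
    new_genes = config.genes + [
        ori5, ori3, len5, len3, win5, win3, cng5, cng3, dis5, dis3
    ]
    return replace(config, genes=new_genes, fusions=config.fusions + controls)


def noise_check_config(
    seed: int,
    cn_states: Sequence[int] = (1, 2, 4, 8, 13),
    probes_per_state: int = 10_000,
    noise: Optional[NoiseModel] = None,
) -> SimulationConfig:
    """One-sample cohort with large constant-CN blocks for noise validation."""
    spacing = 1_000
    length = (len(cn_states) * probes_per_state + 1) * spacing
    regions = []
    for i, state in enumerate(cn_states):
        start = (i * probes_per_state) * spacing + 1
        end = ((i + 1) * probes_per_state) * spacing
        regions.append((start, end, int(state)))
    return SimulationConfig(
        seed=seed,
        chromosomes={"chr1": length},
        n_samples=1,
        genes=[],
        fusions=[],
        constant_regions={"chr1": regions},
        artifact_rate=0.0,
        noise=noise or NoiseModel(),
    )
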