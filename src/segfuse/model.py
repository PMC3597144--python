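"""Domain types for copy-number based fusion calling.

Coordinates are 1-based and inclusive throughout the package; BED input is
converted at the boundary. A breakpoint is the boundary between two adjacent
segments of differing total copy number; its position is the floor midpoint
between the left segment's end and the right segment's start, since the true
break lies somewhere between the flanking probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
BOTH = "both"

#: Subgroup label for members cut away by the clustering rules.
DISCARDED = "DISCARDED"


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number run of probes on a chromosome."""

    chrom: str
    start: int
    end: int
    n_probes: int
    total_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start > end"
            )
        if self.n_probes < 1:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end} has no probes")
        if self.total_cn < 0:
            raise ValidationError("total_cn must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentationProfile:
    """Per-sample segmentation: ordered constant-CN segments per chromosome."""

    sample_id: str
    segments: Dict[str, List[Segment]] = field(default_factory=dict)

    def validate(self) -> "SegmentationProfile":
        for chrom, segs in self.segments.items():
            if not segs:
                raise ValidationError(f"chromosome {chrom} retained with no segments")
            prev = None
            for seg in segs:
                if seg.chrom != chrom:
                    raise ValidationError(f"segment {seg} filed under chromosome {chrom}")
                if prev is not None and seg.start <= prev.end:
                    raise ValidationError(
                        f"overlapping/unsorted segments on {chrom}: "
                        f"{prev.start}-{prev.end} then {seg.start}-{seg.end}"
                    )
                prev = seg
        return self

    def chromosomes(self) -> List[str]:
        return sorted(self.segments)

    def n_segments(self) -> int:
        return sum(len(s) for s in self.segments.values())


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    pos: int
    intensity: float


class ProbePanel:
    """Position-sorted probe intensities for one sample.

    Stores per-chromosome sorted position arrays for fast window queries.
    """

    def __init__(self, sample_id: str, records: Sequence[ProbeRecord]):
        import numpy as np

        self.sample_id = sample_id
        by_chrom: Dict[str, List[ProbeRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._records: Dict[str, List[ProbeRecord]] = {}
        self._pos: Dict[str, "np.ndarray"] = {}
        self._intensity: Dict[str, "np.ndarray"] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            seen = set()
            for r in recs:
                if r.pos in seen:
                    raise ValidationError(
                        f"duplicate probe position {chrom}:{r.pos} in sample {sample_id}"
                    )
                seen.add(r.pos)
            self._records[chrom] = recs
            self._pos[chrom] = np.array([r.pos for r in recs], dtype=np.int64)
            self._intensity[chrom] = np.array([r.intensity for r in recs], dtype=float)

    def chromosomes(self) -> List[str]:
        return sorted(self._records)

    def records(self, chrom: Optional[str] = None) -> List[ProbeRecord]:
        if chrom is not None:
            return list(self._records.get(chrom, []))
        return [r for c in self.chromosomes() for r in self._records[c]]

    def __len__(self) -> int:
        return sum(len(r) for r in self._records.values())

    def in_interval(self, chrom: str, start: int, end: int) -> List[ProbeRecord]:
        """Probes with start <= pos <= end, in position order."""
        import numpy as np

        pos = self._pos.get(chrom)
        if pos is None:
            return []
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return self._records[chrom][lo:hi]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Breakpoint:
    """Boundary between two adjacent segments of differing total copy number."""

    chrom: str
    left_segment: Segment
    right_segment: Segment

    def __post_init__(self) -> None:
        if self.left_segment.end >= self.right_segment.start:
            raise ValidationError("breakpoint flanks must be ordered and disjoint")
        if self.left_segment.total_cn == self.right_segment.total_cn:
            raise ValidationError("breakpoint flanks must differ in copy number")

    @property
    def boundary_pos(self) -> int:
        return (self.left_segment.end + self.right_segment.start) // 2


@dataclass(frozen=True)
class AnchoredGene:
    """A gene (or gene subsegment) tied to one or two flanking breakpoints.

    ``sub_start``/``sub_end`` delimit the anchored interval: the whole gene
    body for genes merely near a breakpoint, or one inter-breakpoint piece for
    genes split by breakpoints. ``bp_left``/``bp_right`` are the boundaries
    flanking the interval (either may be absent). The role follows transcript
    orientation: an interval whose transcriptional 3' end faces a boundary can
    donate a 5' fusion part, and vice versa; inner subsegments of a gene split
    by two or more breakpoints face boundaries on both sides and take both
    roles.
    """

    gene: GeneModel
    role: str
    sub_start: int
    sub_end: int
    total_cn: int
    bp_left: Optional[Breakpoint] = None
    bp_right: Optional[Breakpoint] = None

    def __post_init__(self) -> None:
        if self.role not in (FIVE_PRIME, THREE_PRIME, BOTH):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.sub_start > self.sub_end:
            raise ValidationError("anchored interval has start > end")
        if self.bp_left is None and self.bp_right is None:
            raise ValidationError("anchored gene must face at least one breakpoint")

    @property
    def sub_length(self) -> int:
        return self.sub_end - self.sub_start + 1

    def boundary_for(self, role: str) -> Optional[Breakpoint]:
        """The boundary this interval would fuse at when playing ``role``.

        A 5' partner fuses at its transcriptional 3' end (genomic right on the
        forward strand), a 3' partner at its transcriptional 5' end.
        """
        if role == FIVE_PRIME:
            side = "right" if self.gene.strand == "+" else "left"
        elif role == THREE_PRIME:
            side = "left" if self.gene.strand == "+" else "right"
        else:
            raise ValueError("boundary_for expects a concrete role")
        return self.bp_right if side == "right" else self.bp_left


@dataclass
class FusionCandidate:
    """An ordered (5'-gene, 3'-gene) pair surviving all per-sample constraints.

    ``five_prime``/``three_prime`` hold the anchored intervals when the
    candidate comes straight from detection; candidates re-loaded from a
    report carry only the flat fields.
    """

    sample_id: str
    five_gene_id: str
    three_gene_id: str
    coords: Tuple[int, int, int, int]
    cn_pair: Tuple[int, int]
    correlation: float
    rms: float
    fusion_len_bp: int
    span_used: Optional[int] = None
    five_prime: Optional[AnchoredGene] = None
    three_prime: Optional[AnchoredGene] = None

    @property
    def gene_pair(self) -> Tuple[str, str]:
        return (self.five_gene_id, self.three_gene_id)


@dataclass
class FusionGroup:
    """The same gene pair recurring across samples, with clustering labels."""

    gene_pair: Tuple[str, str]
    members: List[FusionCandidate]
    conserved_mask: Optional[Tuple[bool, bool, bool, bool]] = None
    subgroup_labels: Optional[List[object]] = None
    median_len_bp: Optional[float] = None

    def sample_ids(self) -> List[str]:
        return [m.sample_id for m in self.members]


@dataclass
class CrossoverWindow:
    """Probe intensities flanking a hypothesized fusion junction.

    The 5' series runs toward the junction and the 3' series away from it, so
    their concatenation forms one continuous virtual track across the break.
    """

    five_prime_intensities: List[float]
    three_prime_intensities: List[float]
    five_prime_smoothed: Optional[List[float]] = None
    three_prime_smoothed: Optional[List[float]] = None
    span_used: Optional[int] = None

    def track(self) -> List[float]:
        return list(self.five_prime_intensities) + list(self.three_prime_intensities)
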