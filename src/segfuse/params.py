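"""Tunable parameters of the fusion caller.

Every numeric rule of the method lives here: the gene-to-breakpoint distance
cap, the copy-number tolerance between fusion partners, the size of the
crossover probe window, the correlation cutoff, the loess span grid, and the
cross-sample grouping rules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional


class ConfigurationError(ValueError):
    """Raised when parameters are missing or inconsistent."""


@dataclass
class Parameters:
    """Rule set applied by the detection and grouping stages.

    Attributes
    ----------
    max_breakpoint_distance_bp:
        A gene that does not span a breakpoint is anchored to one only if the
        nearer gene end lies within this many base pairs of the boundary.
    cn_tolerance:
        Maximum allowed difference between the total copy numbers of the two
        fusion partners (joined DNA is replicated together).
    crossover_probes:
        Number of probes taken from each partner subsegment to describe the
        crossover (junction) region; sides with fewer probes are ignored.
    min_abs_correlation:
        Strict lower bound on |Pearson r| between the two smoothed crossover
        series (negative correlations pass on magnitude).
    span_grid_lo / span_grid_hi / span_grid_step:
        Loess span grid, in percent of the data points, scanned for the
        minimal-AICc span.
    group_min_samples:
        Minimum number of distinct samples required for a gene pair to form a
        group, and for a subgroup to be reported.
    length_fraction:
        Dendrogram cut height as a fraction of the group's median fusion
        length (the "40% of the median sequence length" rule).
    min_fusion_len_bp / max_fusion_len_bp:
        Acceptable fusion length bounds; by default derived from the shortest
        and longest gene in the gene collection.
    artifact_max_probes:
        Segments supported by at most this many probes are treated as
        segmentation artifacts and removed.
    max_pairs_per_sample:
        Guard against combinatorial blow-up during pair enumeration.
    """

    max_breakpoint_distance_bp: int = 10_000
    cn_tolerance: int = 1
    crossover_probes: int = 7
    min_abs_correlation: float = 0.9
    span_grid_lo: int = 2
    span_grid_hi: int = 95
    span_grid_step: int = 1
    group_min_samples: int = 2
    length_fraction: float = 0.40
    min_fusion_len_bp: Optional[int] = None
    max_fusion_len_bp: Optional[int] = None
    artifact_max_probes: int = 1
    max_pairs_per_sample: int = 1_000_000

    def __post_init__(self) -> None:
        positive = {
            "max_breakpoint_distance_bp": self.max_breakpoint_distance_bp,
            "cn_tolerance": self.cn_tolerance,
            "crossover_probes": self.crossover_probes,
            "span_grid_lo": self.span_grid_lo,
            "span_grid_hi": self.span_grid_hi,
            "span_grid_step": self.span_grid_step,
            "group_min_samples": self.group_min_samples,
            "artifact_max_probes": self.artifact_max_probes,
            "max_pairs_per_sample": self.max_pairs_per_sample,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if not (0.0 < self.min_abs_correlation <= 1.0):
            raise ConfigurationError(
                f"min_abs_correlation must be in (0, 1], got {self.min_abs_correlation}"
            )
        if self.span_grid_lo >= self.span_grid_hi:
            raise ConfigurationError("span_grid_lo must be < span_grid_hi")
        if not (0.0 < self.length_fraction < 1.0):
            raise ConfigurationError(
                f"length_fraction must be in (0, 1), got {self.length_fraction}"
            )
        for name in ("min_fusion_len_bp", "max_fusion_len_bp"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")

    def with_length_bounds_from(self, genes) -> "Parameters":
        """Return a copy with fusion-length bounds taken from a gene collection.

        The shortest and longest gene set the minimal and maximal accepted
        fusion length. Explicit bounds already present are kept.
        """
        if not genes:
            raise ConfigurationError("cannot derive length bounds from an empty gene collection")
        lengths = [g.end - g.start + 1 for g in genes]
        lo = self.min_fusion_len_bp if self.min_fusion_len_bp is not None else min(lengths)
        hi = self.max_fusion_len_bp if self.max_fusion_len_bp is not None else max(lengths)
        return replace(self, min_fusion_len_bp=lo, max_fusion_len_bp=hi)

    def span_grid(self) -> range:
        """The loess span grid, in percent."""
        return range(self.span_grid_lo, self.span_grid_hi + 1, self.span_grid_step)
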