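# Methods

## Model and assumptions

`segfuse` calls fusion genes at the DNA level from segmented SNP-array copy
number. The underlying model is simple: an unbalanced rearrangement changes
dosage, so each of its ends appears as a boundary between two constant-CN
segments; a fusion joins the 5′ portion of one gene (up to such a boundary)
to the 3′ portion of another (from such a boundary onward). Three
assumptions follow and shape the filters:

* **Joint replication.** The two joined partners sit on the same derivative
  chromosome, so their total CNs may differ by at most the tolerance
  (default ±1 — segmentation HMMs return the most likely, not the true,
  CN sequence).
* **Read-through orientation.** Transcription must run continuously across
  the junction: the 5′ partner presents its transcriptional 3′ end
  (genomic right end on +, left end on −) and the 3′ partner its
  transcriptional 5′ end.
* **Co-amplified junction.** Probe intensities just left and right of a real
  junction drift together. Raw intensities cannot be compared directly
  because their variance grows with CN, so both 7-probe flanks are
  loess-smoothed and compared by Pearson correlation (|r| > 0.9, sign
  ignored) and summarised by the RMS of the smoothed difference.

Balanced rearrangements produce no dosage change and are invisible to this
method by construction.

## Coordinates and conventions

All coordinates are 1-based inclusive; BED input is converted at the
boundary. Segment coordinates are probe positions. A breakpoint's position
is the floor midpoint between the left segment's end and the right
segment's start — the true break lies somewhere between the flanking
probes, and a fixed convention makes distance rules deterministic. The
10 kb gene-to-boundary rule is inclusive (a gene exactly 10 000 bp away
anchors); a gene overlapping the boundary counts as spanning.

Artifact removal: segments with ≤ `artifact_max_probes` probes (default 1)
are removed; the removed run's interval *and probe count* are absorbed into
the surviving left flank (right flank at a chromosome start), so probe mass
is conserved and `n_probes` keeps meaning "probes inside the interval".
Chromosomes consisting only of artifacts are dropped.

Pair enumeration inside the pipeline is permissive: every anchored end is
tried in both the 5′ and the 3′ slot and the orientation filter prunes
wrong-slot pairings. Because roles are strand-derived, the surviving set is
identical to strict role-based enumeration (property-tested); the permissive
route keeps the orientation constraint a live, observable stage in the drop
log rather than an implicit consequence of role assignment. A gene (or two
subsegments of one gene) is never paired with itself at the same breakpoint;
subsegments of one gene at *different* breakpoints may pair (internal
deletion). A per-sample cap (default 10⁶ pairs) guards combinatorial
blow-up.

## Loess and span selection

Smoothing is local quadratic regression under tricube weights on
nearest-neighbour windows of k = ⌈span/100 · n⌉ points (indices, not
genomic distances: the two sides of a translocation share no coordinate
system, and array probes are near-uniformly spaced). Numerical choices:

* the tricube scale is set 10⁻⁷ beyond the farthest window point so that
  point keeps a positive weight and the design stays full-rank;
* windows with k < 3 points fall back to degree k − 1;
* the smoother row is computed via a pseudo-inverse, giving both the fitted
  value and the hat diagonal for the operator trace.

The span is selected per candidate on the concatenated 14-point crossover
track by minimising AICc = n ln(RSS/n) + n(n + tr L)/(n − tr L − 2) over an
integer percentage grid (default 2–95 step 1); grid values with a < 2-point
window or no residual degrees of freedom (n − tr L − 2 ≤ 0) are skipped, and
ties resolve toward the smaller span. The same span then smooths each
7-point side separately, which reconciles per-candidate span selection with
per-side smoothed series. RSS is floored at (10⁻⁸ × data scale)² per point
so exact-fit series tie deterministically instead of comparing rounding
noise; a consequence worth knowing is that for exactly polynomial data the
trace penalty picks the smallest span whose window spans all points, not the
smallest feasible span. Whether correlation should use smoothed or raw
values is ambiguous in principle; smoothed values are used, matching the
motivation for smoothing at all.

## Grouping and clustering

Groups are gene pairs recurring in ≥ 2 distinct samples. Coordinate
conservation is exact integer equality — no tolerance — and at least two of
the four coordinates must be conserved. Distances between members are
Euclidean over the non-conserved coordinates only. Complete-linkage
agglomeration is implemented directly (scipy's implementation serves as an
independent oracle in the tests) so that tie-breaking is fully specified:
merge the pair with the smallest linkage distance, ties toward the smallest
member index. Two cut modes exist:

* `height` (default): cut the dendrogram at `length_fraction` × the group's
  median fusion length — the 40 %-of-median rule. The median is computed over
  *all* initial members, including ones later discarded, since the threshold
  must exist before anything is discarded by it. "Fusion length" is the sum
  of the two subsegment lengths; the rule could also be read as a per-member
  discard criterion, but a global cut height is the reading consistent with
  a horizontal dendrogram line and is the default.
* `min_cluster_size`: the smallest merge height at which every cluster
  covers ≥ `group_min_samples` samples. This mode needs no member lengths
  and is what the published five-cell-line worked example uses, where one
  discarded line's coordinates are unavailable so the 40 % arithmetic cannot
  be reproduced.

Clusters covering fewer than `group_min_samples` samples are labelled
DISCARDED; the rest are numbered by ascending minimal member coordinates.

## The simulator

The generator emulates the post-segmentation world only: a regular probe
grid (default 1 kb spacing), per-sample constant-CN segments, and
intensities drawn from N(log₂((c + 0.1)/2), base_sd + sd_per_cn · c) for a
probe in a CN = c segment — a smooth monotone log-ratio location with noise
that grows linearly with CN (defaults base_sd = 0.02, sd_per_cn = 0.01). A
planted fusion is realised as two altered intervals whose junction edges sit
next to the partner genes, plus a shared linear intensity drift (default
0.1 per probe) across the 14 crossover probes — the observable signature of
joint replication. Optional per-sample jitter of the junction edges models
intron-to-intron variability of real breaks. Single-probe CN spikes
(default rate 5 × 10⁻⁴ per baseline probe, kept 20 kb away from planted
junctions) model segmentation artifacts.

The reference cohort (`default_config`) has 5 samples, three chromosomes
(2.6 / 2.6 / 1.6 Mb), 16 genes and one compliant fusion planted in samples
1–3: a 60 kb gene at a CN-4 boundary fused to a 40 kb gene at a CN-3
boundary. `plant_noncompliant_controls` adds five events that each violate
exactly one constraint (CN gap 2; minus-strand 3′ partner presenting its
wrong end; combined length above the longest gene; a 6-probe 3′ subsegment;
a gene 15 kb from its boundary). Each event sits on its own copy-number rung
≥ 2 apart from every other event, a one-factor-at-a-time layout that makes
cross-event pairings fail the CN filter so every control exercises exactly
the constraint it was built to violate. Scale was chosen so the full
cohort simulates and analyses in seconds; the noise-calibration
configuration uses 10 000 probes per CN state, where the sd estimate has
< 1 % sampling error against its 5 % check band.

What the simulator does **not** emulate — and hence what passing tests do
not show about real arrays: raw CEL-level normalisation, allele-specific
signal, wavy genomic background, probe-density variation, segmentation
errors beyond single-probe spikes, and real intron-level breakpoint
scatter. Recovery results on simulated cohorts demonstrate the pipeline's
internal correctness, not its sensitivity on a given array platform.

## Degenerate inputs and edge cases

Empty candidate lists produce header-only reports; a crossover side with
fewer than 7 probes drops the pair ("window"); a zero-variance smoothed side
drops it ("degenerate window"); fusion-length bounds must exist (derived
from the gene collection or set explicitly) or a configuration error is
raised; series shorter than 4 points refuse span selection. Genes on
chromosomes absent from a profile are skipped with a warning.

## Known limitations

Only unbalanced events are visible. The 10 kb rule is enforced per gene
(each partner within 10 kb of its boundary), which admits up to ~20 kb of
non-coding sequence between the partners; a combined bound would be
stricter. Exact-equality conservation assumes identical segmentation
coordinates across samples — real cohorts may need a tolerance. The
correlation filter presumes at least a mild intensity trend at the
junction; a perfectly flat co-amplified junction is indistinguishable from
a degenerate window.
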