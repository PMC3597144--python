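"""Simulate a five-sample cohort with one planted fusion and five controls.

Writes segmentation, probe, gene and truth files under ./example_cohort and
prints what was planted. The compliant fusion joins G5CMP (chr1, CN 4) to
G3CMP (chr2, CN 3) in samples S01-S03; each control violates exactly one
detection constraint.
"""

import segfuse as sf

config = sf.plant_noncompliant_controls(sf.default_config(seed=7))
dataset = sf.simulate_cohort(config)
sf.write_dataset(dataset, "example_cohort")

print(f"samples : {', '.join(dataset.sample_ids())}")
print(f"genes   : {len(dataset.genes)} (shortest {min(g.length for g in dataset.genes):,} bp, "
      f"longest {max(g.length for g in dataset.genes):,} bp)")
print("planted events (sample S01):")
for t in dataset.truth:
    if t.sample_id != "S01":
        continue
    kind = "compliant" if t.compliant else f"control ({t.expected_drop})"
    print(f"  {t.gene5_id} -> {t.gene3_id}  CN ({t.cn5},{t.cn3})  "
          f"5' {t.five_start:,}-{t.five_end:,}  3' {t.three_start:,}-{t.three_end:,}  [{kind}]")
print("files written to ./example_cohort (segments/probes per sample, genes.bed, truth.tsv)")
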