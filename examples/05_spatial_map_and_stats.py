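"""Map which channels carry surprise, and compare segments across replicates.

Part 1: per-channel decoding on one dataset shows the channels with the
largest (absolute) loadings decode best.  Part 2: a small replicate study
(4 subject-like datasets) feeds the repeated-measures ANOVA + post-hoc
comparison of early/middle/late segment powers.
"""

import numpy as np

import megsurprise as ms

spec = ms.SyntheticEpochSpec(n_trials=150, n_channels=6,
                             times_ms=np.linspace(-200, 600, 30))
seq = ms.generate_oddball(T=150, p_deviant=1 / 3, seed=7)
tensor = ms.simulate_epochs(seq, spec)

table, _ = ms.spatial_map(tensor, seq, ["shannon"], w_grid=(16.0,), seed=0)
print("per-channel decoding power (entire time course per channel):")
for _, row in table.sort_values("r2", ascending=False).iterrows():
    print(f"  {row['channel']}: R^2 = {row['r2']:.3f}")

datasets = ms.replicate_datasets(4, spec, base_seed=7)
study = ms.segment_study(datasets, "shannon", w_grid=(16.0,), seed=0,
                         n_permutations=5, chance_segments=("baseline", "middle"))
print(f"\nboundaries from the replicate-averaged curve: "
      f"t1 = {study.boundaries.t1_ms:.0f} ms, t2 = {study.boundaries.t2_ms:.0f} ms")
print("mean segment R^2 over 4 replicates:")
print(study.r2_table.mean().round(3).to_string())
print(f"\nANOVA over early/middle/late: F = {study.between_segments.anova_f:.2f}, "
      f"p = {study.between_segments.anova_p:.2e}")
for c in study.between_segments.comparisons:
    flag = "significant" if c.significant else "n.s."
    print(f"  {c.label}: t = {c.statistic:.2f}, p = {c.p_value:.4f} ({flag} at "
          f"{c.corrected_threshold:.4f})")
print("\nThe middle segment (containing the encoding bump) dominates; the "
      "Bonferroni threshold 0.05/3 = 0.0167 guards the three post-hoc pairs.")
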