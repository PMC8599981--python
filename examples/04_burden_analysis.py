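"""Case/control burden analysis with an injected duplication excess.

Simulates 200 cases / 200 controls where each case carries on average 16
extra private duplications, then runs the full 96-cell burden grid
(2 CNV sets x 4 features x 3 event classes x 4 groups) with permutation
p-values.
"""

from cnvburden import (
    RareFilterParameters,
    SimulationConfig,
    bonferroni_threshold,
    rare_cnvs,
    results_to_frame,
    run_burden_grid,
    simulate_cohort,
    simulate_mask,
)

cfg = SimulationConfig(seed=33, n_samples=400, n_cases=200, burden_effect=16.0)
cohort, phenotypes = simulate_cohort(cfg)
rare = rare_cnvs(cohort, simulate_mask(cfg), RareFilterParameters())

grid = run_burden_grid(cohort, rare, phenotypes, n_permutations=4_000, seed=5)
threshold = bonferroni_threshold(0.05, len(grid))
frame = results_to_frame(grid)

print(f"{len(grid)} analyses; Bonferroni threshold 0.05/{len(grid)} = {threshold:.6f}")
sig = frame[frame["significant"]]
print(f"{len(sig)} cells significant:")
cols = ["cnv_set", "feature", "event_class", "group",
        "mean_case", "mean_control", "p_value"]
print(sig[cols].round(3).to_string(index=False))

dup_all = frame.query(
    "cnv_set == 'all' and feature == 'event_count' and event_class == 'Dup' and group == 'ALL'"
).iloc[0]
print(f"\nduplication event count, all samples: cases {dup_all.mean_case:.1f} "
      f"vs controls {dup_all.mean_control:.1f} (p = {dup_all.p_value:.2e})")

# The injected effect surfaces exactly where it was planted: duplication
# event-count (and total-length) cells reject far below the Bonferroni
# threshold, while deletion-specific cells stay null. The minimum
# reportable p is 1/(permutations+1), so more permutations sharpen small
# p-values.
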