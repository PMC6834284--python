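"""Screen expression features for survival association.

Simulates a 300-patient cohort with three features carrying a planted
hazard-ratio-3 effect at a 50/50 split among 60 null features, then runs
the calibrated minimum-p-value screen. The planted features should surface
at the top with q-values below the 0.1 FDR threshold, while null features
should not.
"""

from neep import run_neep
from neep.synthetic import simulate_cohort, simulate_expression

base = simulate_cohort(300, event_rate_target=0.5, seed=1)
matrix, truth = simulate_expression(base, n_null=60,
                                    planted=[(3.0, 0.5)] * 3, seed=2)
cohort = truth.cohort  # survival reflects the planted hazard effect

results = run_neep(matrix, cohort, n_sims=20_000, seed=3)

cols = ["feature_id", "k_star", "min_p", "neep_p", "q_value",
        "significant", "hazard_ratio"]
print(results[cols].head(6).to_string(index=False))
print(f"\nsignificant at FDR 0.1: {int(results.significant.sum())} "
      f"(planted: {len(truth.planted_features)})")
# Each row gives the optimal low-group size (k_star), the raw minimum
# logrank p over the sweep, its calibrated (valid) p-value, the BH q-value
# and the O/E hazard ratio of high over low expression at that split.
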