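"""Interval-adjusted progression and gated paired statistics on a simulated
cohort.

Simulates 31 subjects scanned twice about 360 days apart with a -10%
follow-up effect on one metric, computes the interval-adjusted progression,
runs the Shapiro-gated paired comparison (t-test or Wilcoxon) with BH
q-values, and prints the Spearman correlation of two progression variables.
"""

from lungqct import CohortMetricSpec, CohortSimConfig, simulate_cohort, spearman_matrix
from lungqct.stats import compare_all, progression_table

config = CohortSimConfig(
    metrics={
        "TBV": CohortMetricSpec(138.3, 61.9, effect_relative=-0.10, noise_sd=8.0),
        "Dh_Trachea": CohortMetricSpec(18.0, 2.0, noise_sd=0.5),
    },
    seed=7,
)
cohort = simulate_cohort(config)

prog = progression_table(cohort)
print(f"cohort average scan interval: {prog.attrs['average_interval_days']:.2f} days")
print(f"mean progression TBV        : {prog['TBV'].mean():+.4f}  (simulated effect -0.10)")
print(f"mean progression Dh_Trachea : {prog['Dh_Trachea'].mean():+.4f}  (no effect)")
print()
tests = compare_all(cohort)
print(tests[["test_used", "p_value", "q_value"]].round(4).to_string())
print()
corr = spearman_matrix(prog)
print(f"Spearman rho(TBV, Dh_Trachea) = {corr.loc['TBV', 'Dh_Trachea']:+.3f}")
print()
print("The vessel-volume decline is detected (small p and q); the stable")
print("airway metric is not. Progression is the fractional change rescaled by")
print("average/individual interval, so unequal follow-up times are comparable.")
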