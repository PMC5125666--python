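"""The inferential chain: mixed ANOVA, regression, commonality analysis.

Simulates three listener groups, runs the group x coherence mixed ANOVA
on arcsine-transformed order-correct scores, then regresses the
combined older groups' coherent-sequence scores on their covariates and
partitions the model R-squared into unique and shared components.
"""

import pandas as pd

import fest

battery = fest.load_battery()
sessions = []
for group, n, seed in (("YNH", 15, 1), ("MON", 19, 2), ("MOI", 11, 3)):
    sessions += fest.simulate_cohort(fest.default_cohort(group, n, seed=seed), battery)
frame = fest.session_scores_frame(sessions, battery)

aov = fest.mixed_anova(frame, dv="oc_asin")
print("mixed ANOVA on arcsine-OC (group x coherence):")
print(aov.table.round(4).to_string())
# partial eta-squared = SS_effect / (SS_effect + SS_error)

older = [s for s in sessions if s.group in ("MON", "MOI")]
cov = pd.DataFrame({s.listener_id: s.covariates for s in older}).T
y = (
    frame[frame["condition"] == "coherent"]
    .set_index("listener_id")["oc_asin"]
    .reindex(cov.index)
)
reg = fest.fit_regression(y, cov)
print(f"\nregression of coherent-sequence OC on covariates (n={reg.n}):")
print(f"  R2 = {reg.r2:.3f}, adjusted R2 = {reg.adj_r2:.3f}")
print(reg.coefficients[["beta", "p", "r2_bivariate", "r2_semipartial"]].round(3).to_string())

com = fest.commonality_partition(y, cov)
print("\ncommonality partition — unique components (% of R2):")
for p in cov.columns:
    print(f"  {p:<10} {com.pct_of_effect[frozenset([p])]:6.1f}%")
total_unique = sum(com.pct_of_effect[frozenset([p])] for p in cov.columns)
print(f"  sum of uniques: {total_unique:.1f}% (remainder is shared across predictors)")
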