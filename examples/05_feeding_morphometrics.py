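"""Feeding-experiment morphometrics: published summaries and raw tables.

First reproduces the two-group t-tests computable from published
(mean, SD, n) queen summaries; then runs one-way ANOVA + Tukey HSD on a
generated per-bee table with planted treatment effects.
"""

from jellynet import (
    MorphoSummary, SimConfig, anova_oneway, gen_morpho, percent_effect,
    ttest_from_summary, tukey_hsd,
)

published = {
    "birth_weight (g)": ((0.2355, 0.02, 57), (0.2252, 0.0309, 64)),
    "body_length (mm)": ((18.0737, 1.038, 57), (17.5825, 1.2879, 64)),
    "wing_area (mm^2)": ((20.4017, 1.0491, 57), (19.9734, 1.0253, 64)),
}
for trait, ((m1, s1, n1), (m2, s2, n2)) in published.items():
    ctrl = MorphoSummary("control", trait, m1, s1, n1)
    trt = MorphoSummary("treated", trait, m2, s2, n2)
    res = ttest_from_summary(ctrl, trt)
    print(f"{trait}: t={res.statistic:.3f}, df={res.df}, p={res.p:.4f}, "
          f"effect {percent_effect(trt, ctrl):+.1%}")

cfg = SimConfig(seed=1)
raw, summaries, truth = gen_morpho(cfg)
groups = ["untreated", "control", "treated"]
samples = [raw[raw["group"] == g]["birth_weight"].to_numpy() for g in groups]
an = anova_oneway(samples, groups)
print(f"\nsimulated birth weight: F{an.df}={an.statistic:.2f}, p={an.p:.2e}")
for pair in tukey_hsd(samples, groups):
    print(f"  Tukey {pair.groups[0]} vs {pair.groups[1]}: "
          f"q={pair.statistic:.2f}, p={pair.p:.4f}")
# The summary-statistics t-tests are exactly the tests computable from a
# published table; the ANOVA/Tukey pass shows the raw-data route on a
# generated cohort with a planted ~8% weight reduction in the treated group.
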