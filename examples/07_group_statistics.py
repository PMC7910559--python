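"""Compare measurement groups the way electrophysiology papers report them.

Two conditions: Welch's unequal-variance t-test.  Three or more: one-way
ANOVA with Tukey's HSD post hoc correction and the star convention
(* p<0.05, ** p<0.01, *** p<0.001).
"""

import numpy as np

from hvkit.stats import GroupSummary, anova_tukey, welch_t

rng = np.random.default_rng(0)
# activation time constants (ms) for three constructs, 6 patches each
groups = {
    "SlHv1": rng.normal(300.0, 40.0, 6),
    "AoHv1": rng.normal(50.0, 8.0, 6),
    "ChL1-2": rng.normal(60.0, 10.0, 6),
}

for name, values in groups.items():
    g = GroupSummary.from_values(name, values)
    print(f"{name:8s} tau_on = {g.mean:6.1f} ± {g.sem:4.1f} ms (n = {g.n})")

res = welch_t(groups["SlHv1"], groups["AoHv1"])
print(f"\nWelch SlHv1 vs AoHv1: t = {res.t:.2f}, df = {res.df:.1f}, p = {res.p:.2e}")

aov = anova_tukey(groups)
print(f"\nANOVA: F = {aov.F:.1f}, p = {aov.p:.2e}")
print(aov.pairwise.to_string(index=False))
print("\nTukey keeps the family-wise error controlled across all pairs;")
print("only the SlHv1 contrasts are significant here.")
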