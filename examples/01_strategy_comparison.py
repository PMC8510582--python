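"""Compare selection strategies across prevalence and PRS strength.

For each disease prevalence K and PRS accuracy r2 (liability scale), this
prints the relative and absolute risk reduction when one of five embryos
is implanted either by excluding the population top-2% of PRS (HRE) or by
picking the lowest-PRS embryo (LRP).
"""

from embryoscreen import ScreeningScenario, Strategy, risk_reduction

print(f"{'K':>5} {'r2':>5} {'HRE RRR':>8} {'LRP RRR':>8} {'LRP ARR':>8}")
for K in (0.01, 0.05, 0.2):
    for r2 in (0.05, 0.1, 0.3):
        hre = risk_reduction(ScreeningScenario(K, r2, 5, Strategy.HRE, q=0.02))
        lrp = risk_reduction(ScreeningScenario(K, r2, 5, Strategy.LRP))
        print(
            f"{K:5.2f} {r2:5.2f} {hre.rrr:8.1%} {lrp.rrr:8.1%} {lrp.arr:8.2%}"
        )

print(
    "\nLowest-risk prioritization reduces relative risk several-fold more "
    "than top-2% exclusion;\nfor rare diseases even a large relative "
    "reduction is a small absolute one."
)
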