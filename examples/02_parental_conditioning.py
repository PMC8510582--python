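"""Risk reduction when the parents' PRSs or disease status are known.

The couple's mean PRS c shifts every embryo's score; parental disease
status is a weaker, indirect signal about c.  Both kinds of conditioning
are shown for a disease with prevalence 5%, PRS r2 = 0.1 and (for status
conditioning) heritability h2 = 40%.
"""

from embryoscreen import (
    CoupleContext,
    ScreeningScenario,
    percentile_to_c,
    risk_given_c,
    risk_given_parental_status,
)

scenario = ScreeningScenario(K=0.05, r2_ps=0.1, n=5)

print("Parental PRS percentiles (LRP, n=5):")
for p1, p2 in ((0.5, 0.5), (0.98, 0.25), (0.75, 0.75), (0.98, 0.98)):
    c = percentile_to_c(p1, p2, scenario.r2_ps)
    res = risk_given_c(scenario, c)
    print(
        f"  parents at {p1:.0%}/{p2:.0%}: baseline {res.p_baseline:.1%}, "
        f"selected {res.p_disease:.1%}, RRR {res.rrr:.1%}"
    )

print("\nParental disease status (h2 = 40%):")
for s1, s2 in (("unaffected", "unaffected"), ("affected", "unaffected"),
               ("affected", "affected")):
    ctx = CoupleContext(h2=0.4, status_parent1=s1, status_parent2=s2)
    res = risk_given_parental_status(scenario, ctx)
    print(
        f"  {s1}/{s2}: baseline {res.p_baseline:.1%}, "
        f"selected {res.p_disease:.1%}, RRR {res.rrr:.1%}"
    )

print(
    "\nWith one affected parent the child's baseline risk roughly doubles; "
    "selecting the\nlowest-PRS embryo of five nearly restores it to the "
    "population prevalence."
)
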