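"""Selecting against one disease can raise the risk of another.

Two diseases with genetically correlated scores (correlation rho < 0) are
simulated in 200,000 couples with five embryos each.  Implanting the
embryo with the lowest PRS for the target disease lowers its risk but
raises the risk of the negatively correlated disease.
"""

from embryoscreen import PleiotropyScenario, simulate_pleiotropy

print(f"{'rho':>6} {'target RRR':>11} {'correlated risk increase':>25}")
for rho in (-0.05, -0.1, -0.2, -0.3):
    res = simulate_pleiotropy(
        PleiotropyScenario(
            rho=rho, K1=0.05, K2=0.05, r2_1=0.1, r2_2=0.1,
            n=5, n_couples=200_000, seed=2024,
        )
    )
    print(
        f"{rho:6.2f} {res.rrr_target:11.1%} {res.rri_correlated:25.1%}"
        f"  (+/- {res.se_rri_correlated:.1%})"
    )

print(
    "\nThe target-disease reduction is unchanged by rho (same seed, same "
    "selections), while\nthe correlated disease's risk rises, approaching "
    "a sixth of the target benefit at rho = -0.3."
)
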