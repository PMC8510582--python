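"""Validate the liability-threshold predictions with simulated genomes.

A synthetic phased case-control cohort is generated under a liability
threshold model; virtual couples produce Mendelian embryos with map-based
Poisson recombination; embryos are scored and their risks predicted by an
ascertainment-corrected logistic model fitted on the 'parents'.  The
empirical risk reduction is compared with the analytic theory at the
cohort's own liability-scale r2.
"""

from embryoscreen.genome import generate_synthetic_cohort, run_genome_pipeline

cohort, gmap, model = generate_synthetic_cohort(
    n_cases=150, n_controls=100, n_variants=600, n_chromosomes=10,
    target_r2_liab=0.07, K=0.01, seed=42,
)
print(f"cohort: {cohort.n_samples} samples, {cohort.n_variants} variants")

res = run_genome_pipeline(
    cohort, gmap, model, K=0.01, n_couples=400, n_embryos=5, q=0.02, seed=42,
)
print(f"liability-scale r2 of the score: {res.r2_liability:.3f}")
print(f"empirical LRP RRR: {res.rrr_lrp.rrr:.1%} (theory {res.theory_rrr_lrp:.1%})")
print(f"empirical HRE top-2% RRR: {res.rrr_hre.rrr:.1%}")
print(
    f"embryo/parent score variance ratio: "
    f"{res.diagnostics.variance_ratio:.3f} (expected 0.5), "
    f"slope vs mid-parental score {res.diagnostics.slope:.3g}"
)
print(
    "\nMendelian segregation halves the parental score variance within "
    "couples, and the\nempirical risk reduction tracks the analytic curve."
)
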