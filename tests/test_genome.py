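"""Genome simulator: meiosis, scoring, risk models, pipeline, file IO."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from embryoscreen.genome import (
    GeneticMap,
    ScoreModel,
    calibrate_score_percentiles,
    compute_prs,
    embryo_variance_diagnostics,
    empirical_rrr,
    fit_logistic_risk,
    generate_synthetic_cohort,
    io as gio,
    mate_virtual_couples,
    observed_to_liability_r2,
    simulate_offspring,
)
from embryoscreen.core import Strategy


def _toy_variants(n, chrom="chr1", spacing=1_000_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [(i + 1) * spacing for i in range(n)],
            "id": [f"{chrom}:{(i + 1) * spacing}" for i in range(n)],
            "ref": "A",
            "alt": "G",
        }
    )


class TestGenerator:
    def test_fixed_seed_is_byte_identical(self):
        a = generate_synthetic_cohort(20, 20, 40, 4, seed=7, K=0.1)
        b = generate_synthetic_cohort(20, 20, 40, 4, seed=7, K=0.1)
        assert np.array_equal(a[0].haplotypes, b[0].haplotypes)
        assert a[2].table.equals(b[2].table)

    def test_requested_sizes_and_labels(self, small_cohort):
        cohort, gmap, model = small_cohort
        assert cohort.n_samples == 60
        assert int(cohort.is_case.sum()) == 30
        assert cohort.n_variants == 60 == len(model)
        assert set(cohort.variants["chrom"]) == set(gmap.chromosomes)

    def test_zero_weights_give_constant_score(self):
        cohort, _, model = generate_synthetic_cohort(
            15, 15, 30, 3, target_r2_liab=0.0, K=0.2, seed=2
        )
        scores = compute_prs(cohort.haplotypes, cohort.variants, model)
        assert np.allclose(scores, 0.0)

    def test_lee_conversion_recovers_target_r2(self):
        """Round trip on a cohort large enough to pin the correlation."""
        cohort, _, model = generate_synthetic_cohort(
            1500, 1500, n_variants=300, n_chromosomes=6,
            target_r2_liab=0.1, K=0.2, seed=9,
        )
        scores = compute_prs(cohort.haplotypes, cohort.variants, model)
        r2_obs = np.corrcoef(scores, cohort.is_case.astype(float))[0, 1] ** 2
        r2_liab = observed_to_liability_r2(r2_obs, 0.2, cohort.is_case.mean())
        assert r2_liab == pytest.approx(0.1, rel=0.20)


class TestMeiosis:
    def test_mendelian_consistency_everywhere(self, small_cohort):
        cohort, gmap, _ = small_cohort
        p1 = cohort.sample_haplotypes(0)
        p2 = cohort.sample_haplotypes(35)
        embryos = simulate_offspring(p1, p2, cohort.variants, gmap, 8, seed=1)
        for parent, hap in ((p1, embryos[:, 0, :]), (p2, embryos[:, 1, :])):
            ok = (hap == parent[0]) | (hap == parent[1])
            assert ok.all()

    def test_zero_length_chromosome_transmits_intact_strand(self):
        variants = _toy_variants(12)
        gmap = GeneticMap({"chr1": (np.array([1, 13_000_000]), np.array([0.0, 0.0]))})
        parent = np.vstack([np.zeros(12, dtype=np.uint8), np.ones(12, dtype=np.uint8)])
        embryos = simulate_offspring(parent, parent, variants, gmap, 50, seed=3)
        for g in embryos.reshape(-1, 12):
            assert g.min() == g.max()  # all-0 or all-1: no recombination

    def test_crossover_count_is_poisson_with_map_length_mean(self):
        """10^4 meioses on a 1-Morgan chromosome: mean switches ~ 1.0."""
        n_var = 120
        variants = _toy_variants(n_var)
        # map span ends exactly at the first/last variant so that every
        # crossover falls between observable markers
        span = (1_000_000, n_var * 1_000_000)
        gmap = GeneticMap.linear(
            {"chr1": span}, cm_per_mb=100.0 / ((span[1] - span[0]) / 1e6)
        )
        assert gmap.length_morgan("chr1") == pytest.approx(1.0)
        parent = np.vstack(
            [np.zeros(n_var, dtype=np.uint8), np.ones(n_var, dtype=np.uint8)]
        )
        n_meioses = 10_000
        embryos = simulate_offspring(parent, parent, variants, gmap, n_meioses, seed=11)
        gametes = embryos[:, 0, :]
        switches = (np.diff(gametes.astype(int), axis=1) != 0).sum(axis=1)
        # observable switches slightly undercount double crossovers in a gap
        assert switches.mean() == pytest.approx(1.0, abs=3.0 / math.sqrt(n_meioses) + 0.01)

    def test_variant_outside_map_range_raises(self):
        variants = _toy_variants(3)
        gmap = GeneticMap({"chr1": (np.array([1, 2_000_000]), np.array([0.0, 2.0]))})
        parent = np.zeros((2, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="outside the genetic map"):
            simulate_offspring(parent, parent, variants, gmap, 1, seed=0)

    def test_map_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            GeneticMap({"chr1": (np.array([1, 2, 3]), np.array([0.0, 2.0, 1.0]))})


class TestScoring:
    def test_hand_computed_toy_table(self):
        variants = _toy_variants(3)
        model = ScoreModel(
            pd.DataFrame(
                {
                    "id": variants["id"],
                    "effect_allele": ["G", "A", "G"],
                    "weight": [0.5, -1.0, 2.0],
                }
            )
        )
        hap = np.array(
            [  # sample 1: dosages alt = (2, 1, 0); sample 2: (0, 2, 1)
                [[1, 1, 0], [1, 0, 0]],
                [[0, 1, 1], [0, 1, 0]],
            ],
            dtype=np.uint8,
        )
        scores = compute_prs(hap, variants, model)
        # effect dosage: s1 = (2, 2-1=1, 0) -> 0.5*2 - 1.0*1 + 2.0*0 = 0.0
        #                s2 = (0, 2-2=0, 1) -> 0.5*0 - 1.0*0 + 2.0*1 = 2.0
        assert scores == pytest.approx([0.0, 2.0])
        avg = compute_prs(hap, variants, model, dialect="average")
        assert avg == pytest.approx(scores / 6.0)

    def test_heterozygote_single_variant(self):
        variants = _toy_variants(1)
        model = ScoreModel(
            pd.DataFrame({"id": variants["id"], "effect_allele": ["G"], "weight": [0.7]})
        )
        hap = np.array([[[1], [0]]], dtype=np.uint8)
        assert compute_prs(hap, variants, model) == pytest.approx([0.7])

    def test_unmatched_variants_warn_then_error(self):
        variants = _toy_variants(2)
        model = ScoreModel(
            pd.DataFrame(
                {
                    "id": [variants["id"][0], "rs_missing"],
                    "effect_allele": ["G", "G"],
                    "weight": [1.0, 1.0],
                }
            )
        )
        hap = np.zeros((1, 2, 2), dtype=np.uint8)
        with pytest.warns(UserWarning, match="not found"):
            compute_prs(hap, variants, model)
        all_missing = ScoreModel(
            pd.DataFrame(
                {"id": ["nope1", "nope2"], "effect_allele": ["G", "G"], "weight": [1.0, 1.0]}
            )
        )
        with pytest.raises(ValueError, match="no score variants"):
            compute_prs(hap, variants, all_missing)

    def test_mismatched_effect_allele_raises(self):
        variants = _toy_variants(1)
        model = ScoreModel(
            pd.DataFrame({"id": variants["id"], "effect_allele": ["T"], "weight": [1.0]})
        )
        with pytest.raises(ValueError, match="neither ref nor alt"):
            compute_prs(np.zeros((1, 2, 1), dtype=np.uint8), variants, model)


class TestLogisticRisk:
    def test_no_ascertainment_means_no_adjustment(self, rng):
        scores = rng.normal(size=400)
        statuses = rng.random(400) < 1.0 / (1.0 + np.exp(-scores))
        P = statuses.mean()
        model = fit_logistic_risk(scores, statuses, K=float(P))
        assert model.intercept_adjusted == pytest.approx(model.intercept_sample)

    def test_shuffled_labels_predict_prevalence(self, rng):
        scores = rng.normal(size=2000)
        statuses = np.zeros(2000, dtype=bool)
        statuses[:1000] = True
        rng.shuffle(statuses)
        model = fit_logistic_risk(scores, statuses, K=0.01)
        preds = model.predict(rng.normal(size=500))
        assert np.mean(preds) == pytest.approx(0.01, rel=0.25)

    def test_population_weighted_mean_risk_matches_prevalence(self, validation_cohort):
        cohort, _, model = validation_cohort
        scores = compute_prs(cohort.haplotypes, cohort.variants, model)
        risk = fit_logistic_risk(scores, cohort.is_case, K=0.01)
        preds = risk.predict(scores)
        w = np.where(cohort.is_case, 0.01 / cohort.is_case.sum(),
                     0.99 / (~cohort.is_case).sum())
        assert float(np.sum(w * preds)) == pytest.approx(0.01, rel=0.25)

    def test_perfect_separation_raises(self):
        scores = np.concatenate([np.zeros(20), np.ones(20)])
        statuses = scores > 0.5
        with pytest.raises(ValueError, match="separation"):
            fit_logistic_risk(scores, statuses, K=0.1)


class TestPercentileCalibration:
    def test_toy_weighted_moments_by_hand(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        statuses = np.array([True, True, False, False])
        K = 0.1
        mean, var = calibrate_score_percentiles(scores, statuses, K)
        # case weight 0.05 each, control weight 0.45 each
        w = np.array([0.05, 0.05, 0.45, 0.45])
        mu = float(np.sum(w * scores))
        v = float(np.sum(w * (scores - mu) ** 2))
        assert mean == pytest.approx(mu) and var == pytest.approx(v)

    def test_equal_class_distributions_make_weighting_moot(self, rng):
        scores = np.tile(rng.normal(size=50), 2)
        statuses = np.repeat([True, False], 50)
        m1, v1 = calibrate_score_percentiles(scores, statuses, 0.01)
        m2, v2 = calibrate_score_percentiles(scores, statuses, 0.5)
        assert m1 == pytest.approx(m2) and v1 == pytest.approx(v2, rel=1e-6)

    def test_zero_variance_scores_raise(self):
        with pytest.raises(ValueError, match="variance"):
            calibrate_score_percentiles(
                np.ones(10), np.repeat([True, False], 5), 0.1
            )


class TestLiabilityConversion:
    def test_zero_maps_to_zero(self):
        assert observed_to_liability_r2(0.0, 0.01, 0.5) == 0.0

    def test_monotone_in_observed_r2(self):
        vals = [
            observed_to_liability_r2(r, 0.01, 0.4) for r in (0.01, 0.05, 0.1, 0.2)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_unascertained_sample_reduces_to_classical_factor(self):
        K = 0.1
        t = norm.isf(K)
        z = norm.pdf(t)
        r2o = 0.05
        expected = r2o * K * (1 - K) / z**2
        assert observed_to_liability_r2(r2o, K, K) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ValueError):
            observed_to_liability_r2(0.5, 1.5, 0.5)


class TestCouples:
    def test_composition_matches_prevalence(self, validation_cohort):
        cohort = validation_cohort[0]
        K = 0.01
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            couples = mate_virtual_couples(cohort, 5000, K, seed=3)
        assert len(couples) == 5000
        assert len(set(map(lambda ab: (min(ab), max(ab)), couples))) == 5000
        status = cohort.is_case
        both_control = sum(
            1 for a, b in couples if not status[a] and not status[b]
        )
        assert both_control / 5000 == pytest.approx((1 - K) ** 2, abs=1e-3)

    def test_zero_prevalence_gives_all_control_couples(self, small_cohort):
        cohort = small_cohort[0]
        couples = mate_virtual_couples(cohort, 20, 0.0, seed=1)
        assert all(
            not cohort.is_case[a] and not cohort.is_case[b] for a, b in couples
        )

    def test_no_self_pairing(self, small_cohort):
        cohort = small_cohort[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            couples = mate_virtual_couples(cohort, 200, 0.5, seed=2)
        assert all(a != b for a, b in couples)

    def test_insufficient_cases_error_names_the_requirement(self, small_cohort):
        cohort = small_cohort[0]
        starved = type(cohort)(
            cohort.samples,
            np.r_[np.ones(1, bool), np.zeros(cohort.n_samples - 1, bool)],
            cohort.variants,
            cohort.haplotypes,
        )
        with pytest.raises(ValueError, match="cases"):
            mate_virtual_couples(starved, 10, 0.5, seed=1)


class TestEmpiricalRrr:
    def test_single_embryo_gives_exactly_zero(self, validation_cohort):
        cohort, _, model = validation_cohort
        scores = compute_prs(cohort.haplotypes, cohort.variants, model)
        risk = fit_logistic_risk(scores, cohort.is_case, K=0.01)
        embryo_scores = np.random.default_rng(5).normal(size=(100, 3))
        res = empirical_rrr(embryo_scores, risk, Strategy.LRP, 1, seed=1)
        assert res.rrr == 0.0

    def test_hre_requires_percentile_reference(self, validation_cohort):
        cohort, _, model = validation_cohort
        scores = compute_prs(cohort.haplotypes, cohort.variants, model)
        risk = fit_logistic_risk(scores, cohort.is_case, K=0.01)
        with pytest.raises(ValueError, match="percentile_ref"):
            empirical_rrr(np.zeros((10, 5)), risk, Strategy.HRE, 5, seed=1)


class TestVarianceDiagnostics:
    def test_identical_homozygote_parents_have_zero_variance(self, small_cohort):
        cohort, gmap, model = small_cohort
        parent = np.zeros((2, cohort.n_variants), dtype=np.uint8)
        embryos = simulate_offspring(parent, parent, cohort.variants, gmap, 6, seed=9)
        scores = compute_prs(embryos, cohort.variants, model)
        diag = embryo_variance_diagnostics(
            np.zeros(1), scores[None, :], parental_variance=1.0
        )
        assert diag.pooled_embryo_variance == pytest.approx(0.0, abs=1e-20)

    def test_halving_and_flatness(self, validation_pipeline):
        diag = validation_pipeline.diagnostics
        assert diag.variance_ratio == pytest.approx(0.5, abs=0.05)
        # slope in units of variance per score-SD should be negligible
        scale = diag.parental_variance / math.sqrt(diag.parental_variance)
        assert abs(diag.slope) * scale < 0.1 * diag.pooled_embryo_variance


class TestFileRoundTrips:
    def test_vcf_and_status(self, small_cohort, tmp_path):
        cohort, gmap, model = small_cohort
        paths = gio.write_cohort_bundle(cohort, gmap, model, str(tmp_path))
        back = gio.read_cohort(paths["vcf"], paths["status"])
        assert back.samples == cohort.samples
        assert np.array_equal(back.is_case, cohort.is_case)
        assert np.array_equal(back.haplotypes, cohort.haplotypes)
        pd.testing.assert_frame_equal(
            back.variants.astype({"pos": int}), cohort.variants.astype({"pos": int})
        )

    def test_unphased_genotypes_rejected(self, small_cohort, tmp_path):
        cohort, gmap, model = small_cohort
        paths = gio.write_cohort_bundle(cohort, gmap, model, str(tmp_path))
        text = open(paths["vcf"]).read().replace("0|1", "0/1", 1)
        if "0/1" not in text:  # ensure the edit took place
            text = text.replace("1|0", "1/0", 1)
        bad = tmp_path / "bad.vcf"
        bad.write_text(text)
        with pytest.raises(ValueError, match="unphased"):
            gio.read_cohort(str(bad), paths["status"])

    def test_map_round_trip(self, small_cohort, tmp_path):
        _, gmap, _ = small_cohort
        path = tmp_path / "map.tsv"
        gio.write_genetic_map(gmap, str(path))
        back = gio.read_genetic_map(str(path))
        for chrom in gmap.chromosomes:
            assert back.length_morgan(chrom) == pytest.approx(
                gmap.length_morgan(chrom)
            )

    def test_score_round_trip(self, small_cohort, tmp_path):
        cohort, _, model = small_cohort
        path = tmp_path / "weights.txt"
        gio.write_score_file(model, str(path))
        back = gio.read_score_file(str(path))
        scores_a = compute_prs(cohort.haplotypes, cohort.variants, model)
        scores_b = compute_prs(cohort.haplotypes, cohort.variants, back)
        assert scores_a == pytest.approx(scores_b, rel=1e-9)
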