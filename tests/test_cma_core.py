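"""Corrected meta-analysis core: correlation estimation, GLS combination,
genomic control and power inflation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cma.datatypes import (
    CohortCorrelation,
    HarmonizedSet,
    InflationConfig,
    MetaResult,
    SimulationConfig,
    PhenotypeTable,
)
from cma.errors import InvalidConfigError, ValidationError
from cma import assoc, cma_core, gwas_io, splitter, synthetic_data

from conftest import make_sumstats, null_pheno


def harmonized_pair(beta1, se1, beta2, se2, n1=100, n2=100):
    ids = [f"v{i}" for i in range(len(beta1))]
    c1 = make_sumstats("c1", n1, ids, beta1, se1)
    c2 = make_sumstats("c2", n2, ids, beta2, se2)
    return HarmonizedSet(cohorts=[c1, c2])


def corr_for(harm, r):
    k = len(harm.cohorts)
    n = np.array([c.n_samples for c in harm.cohorts], dtype=float)
    R = np.full((k, k), float(r))
    np.fill_diagonal(R, 1.0)
    return CohortCorrelation(
        labels=harm.labels, r=R, r_raw=R, n12=R * np.sqrt(np.outer(n, n)),
        n=n, n_variants_used=len(harm.variant_ids),
    )


class TestEstimateCorrelation:
    def test_duplicated_cohort_gives_r1_n12_n(self):
        rng = np.random.default_rng(0)
        ids = [f"v{i}" for i in range(300)]
        beta = rng.normal(0, 0.1, 300)
        se = rng.uniform(0.05, 0.2, 300)
        c1 = make_sumstats("c1", 250, ids, beta, se)
        c2 = make_sumstats("c2", 250, ids, beta, se)
        harm = HarmonizedSet(cohorts=[c1, c2])
        corr = cma_core.estimate_correlation(harm)
        assert corr.r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert corr.n12[0, 1] == pytest.approx(250.0, abs=1e-9)

    def test_n12_algebra_at_half_correlation(self):
        # z2 built orthogonally so the Pearson correlation is exactly 0.5;
        # with n1=100, n2=400: n12 = 0.5 * sqrt(100*400) = 100.
        rng = np.random.default_rng(1)
        m = 400
        z1 = rng.normal(size=m)
        u = rng.normal(size=m)
        z1c = (z1 - z1.mean()) / z1.std()
        u -= u.mean()
        u -= z1c * (u @ z1c) / (z1c @ z1c)
        u /= u.std()
        z2 = 0.5 * z1c + np.sqrt(0.75) * u
        se = np.ones(m)
        c1 = make_sumstats("c1", 100, [f"v{i}" for i in range(m)], z1c * se, se)
        c2 = make_sumstats("c2", 400, [f"v{i}" for i in range(m)], z2 * se, se)
        corr = cma_core.estimate_correlation(HarmonizedSet(cohorts=[c1, c2]))
        assert corr.r[0, 1] == pytest.approx(0.5, abs=1e-9)
        assert corr.n12[0, 1] == pytest.approx(100.0, abs=1e-6)

    def test_negative_estimates_clamped_raw_kept(self):
        rng = np.random.default_rng(2)
        m = 200
        z1 = rng.normal(size=m)
        z2 = -0.3 * z1 + rng.normal(size=m)
        se = np.ones(m)
        c1 = make_sumstats("c1", 100, [f"v{i}" for i in range(m)], z1 * se, se)
        c2 = make_sumstats("c2", 100, [f"v{i}" for i in range(m)], z2 * se, se)
        corr = cma_core.estimate_correlation(HarmonizedSet(cohorts=[c1, c2]))
        assert corr.r_raw[0, 1] < 0
        assert corr.r[0, 1] == 0.0
        assert corr.n12[0, 1] == 0.0

    def test_too_few_variants_errors(self):
        harm = harmonized_pair([0.1] * 50, [0.1] * 50, [0.1] * 50, [0.1] * 50)
        with pytest.raises(ValidationError, match="floor"):
            cma_core.estimate_correlation(harm, min_variants=100)

    def test_degenerate_constant_z_errors(self):
        m = 150
        harm = harmonized_pair([0.1] * m, [0.1] * m, list(np.random.default_rng(3).normal(size=m)), [0.1] * m)
        with pytest.raises(ValidationError, match="degenerate z"):
            cma_core.estimate_correlation(harm, min_variants=100, warn_below=0)

    def test_null_like_selection_uses_small_z_only(self):
        rng = np.random.default_rng(4)
        m = 3000
        z1 = rng.normal(size=m)
        z2 = rng.normal(size=m)
        big = rng.choice(m, 200, replace=False)
        z1[big] = 8 + rng.normal(size=200)  # shared strong signal
        z2[big] = 8 + rng.normal(size=200)
        se = np.ones(m)
        ids = [f"v{i}" for i in range(m)]
        harm = HarmonizedSet(cohorts=[
            make_sumstats("c1", 100, ids, z1 * se, se),
            make_sumstats("c2", 100, ids, z2 * se, se),
        ])
        corr_all = cma_core.estimate_correlation(harm, "all")
        corr_null = cma_core.estimate_correlation(harm, "null_like")
        assert corr_all.r[0, 1] > 0.5
        assert corr_null.r[0, 1] < 0.1


class TestCombine:
    def test_inverse_variance_closed_form(self):
        harm = harmonized_pair([0.2], [0.1], [0.1], [0.1])
        meta = cma_core.combine(harm, corr_for(harm, 0.0), method="MA")
        assert meta.table.loc[0, "beta"] == pytest.approx(0.15, abs=1e-12)
        assert meta.table.loc[0, "se"] == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)

    def test_equicorrelated_closed_form(self):
        harm = harmonized_pair([0.2], [0.1], [0.1], [0.1])
        meta = cma_core.combine(harm, corr_for(harm, 0.5), method="CMA")
        assert meta.table.loc[0, "beta"] == pytest.approx(0.15, abs=1e-12)
        assert meta.table.loc[0, "se"] == pytest.approx(0.1 * np.sqrt(0.75), rel=1e-12)

    def test_full_overlap_no_double_counting(self):
        harm = harmonized_pair([0.2], [0.1], [0.2], [0.1])
        meta = cma_core.combine(harm, corr_for(harm, 1.0), method="CMA")
        assert meta.table.loc[0, "beta"] == pytest.approx(0.2, abs=1e-12)
        assert meta.table.loc[0, "se"] == pytest.approx(0.1, rel=1e-12)
        assert meta.table.loc[0, "n_eff"] == pytest.approx(100.0)

    def test_opposite_signs_negative_offdiagonal(self):
        harm = harmonized_pair([0.2], [0.1], [-0.2], [0.1])
        meta = cma_core.combine(harm, corr_for(harm, 0.5), method="CMA")
        assert meta.table.loc[0, "beta"] == pytest.approx(0.0, abs=1e-12)
        assert meta.table.loc[0, "se"] == pytest.approx(0.1 * np.sqrt(0.25), rel=1e-12)

    def test_zero_r_cma_equals_ma_equals_textbook(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = rng.integers(2, 9)
            beta = rng.normal(0, 0.2, k)
            se = rng.uniform(0.02, 0.3, k)
            ids = ["v0"]
            cohorts = [make_sumstats(f"c{j}", 100, ids, [beta[j]], [se[j]]) for j in range(k)]
            harm = HarmonizedSet(cohorts=cohorts)
            cma = cma_core.combine(harm, corr_for(harm, 0.0), "CMA").table
            ma = cma_core.combine(harm, corr_for(harm, 0.0), "MA").table
            w = 1 / se**2
            beta_ref = float(np.sum(w * beta) / w.sum())
            se_ref = float(w.sum() ** -0.5)
            for t in (cma, ma):
                np.testing.assert_allclose(t.loc[0, "beta"], beta_ref, rtol=1e-12, atol=1e-15)
                np.testing.assert_allclose(t.loc[0, "se"], se_ref, rtol=1e-12)

    def test_se_monotone_in_r_for_same_signs(self):
        ses = []
        for r in np.linspace(0, 0.95, 12):
            harm = harmonized_pair([0.2], [0.1], [0.1], [0.1])
            ses.append(cma_core.combine(harm, corr_for(harm, r), "CMA").table.loc[0, "se"])
        assert (np.diff(ses) >= -1e-15).all()

    def test_partial_variant_uses_cohort_subset(self):
        ids = ["v0", "v1"]
        c1 = make_sumstats("c1", 100, ids, [0.2, 0.3], [0.1, 0.1])
        c2 = make_sumstats("c2", 100, ["v0"], [0.1], [0.1])
        harm = gwas_io.harmonize([c1, c2], allow_partial=True)
        meta = cma_core.combine(harm, corr_for(harm, 0.0), "CMA")
        t = meta.table.set_index("id")
        assert t.loc["v1", "n_cohorts"] == 1
        assert t.loc["v1", "beta"] == pytest.approx(0.3)
        assert t.loc["v0", "n_cohorts"] == 2

    def test_ridge_escalation_and_failure(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        assert cma_core._solve_pd(bad, np.ones(2), np.ones(2)) is None
        nearly = np.array([[1.0, 1.0 + 1e-12], [1.0 + 1e-12, 1.0]])
        assert cma_core._solve_pd(nearly, np.ones(2), np.ones(2)) is not None

    def test_k1_passthrough_bitwise(self):
        rng = np.random.default_rng(6)
        ids = [f"v{i}" for i in range(30)]
        ss = make_sumstats("c1", 500, ids, rng.normal(0, 0.1, 30), rng.uniform(0.05, 0.2, 30))
        meta = cma_core.sumstats_to_meta(ss)
        assert (meta.table["beta"].to_numpy() == ss.records["beta"].to_numpy()).all()
        assert (meta.table["se"].to_numpy() == ss.records["se"].to_numpy()).all()
        assert (meta.table["z"].to_numpy() == ss.records["z"].to_numpy()).all()
        assert (meta.table["p"].to_numpy() == ss.records["p"].to_numpy()).all()


class TestInflate:
    def _meta(self, T, beta_sign=None):
        m = len(T)
        T = np.asarray(T, float)
        z = np.sqrt(T) * (beta_sign if beta_sign is not None else 1.0)
        table = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(m)],
                "chrom": 1, "pos": np.arange(1, m + 1), "a1": "A", "a2": "G",
                "freq": 0.3, "n_eff": 100.0, "n_cohorts": 2,
                "beta": z * 0.1, "se": 0.1, "z": z, "T": T,
                "p": np.clip(stats.chi2.sf(T, 1), 5e-324, 1.0),
            }
        )
        return MetaResult(table=table, stage="raw")

    def test_genomic_control_two_step_example(self):
        T_adj, lam = cma_core.genomic_control(np.array([0.5, 1.0, 4.0]), "median_unit")
        assert lam == 1.0
        factor = max(1.0, 0.95 + 0.3)
        np.testing.assert_allclose(T_adj * factor, [0.625, 1.25, 5.0], rtol=1e-12)

    def test_median_exactly_one_after_gc(self):
        rng = np.random.default_rng(7)
        T = rng.chisquare(1, 1001) * 1.37
        T_adj, _ = cma_core.genomic_control(T, "median_unit")
        assert np.median(T_adj) == 1.0

    def test_classical_lambda_convention(self):
        rng = np.random.default_rng(8)
        T = rng.chisquare(1, 500)
        _, lam = cma_core.genomic_control(T, "classical")
        assert lam == pytest.approx(np.median(T) / stats.chi2.ppf(0.5, 1), rel=1e-12)

    @pytest.mark.parametrize(
        "h2,trait,expected",
        [
            (0.3, "quantitative", 1.25),
            (0.05, "quantitative", 1.0),   # Max boundary: 0.95 + 0.05 = 1
            (0.10, "binary", 1.0),         # 0.85 + 0.10 = 0.95 -> Max(1, .) = 1
            (0.2, "binary", 1.05),
        ],
    )
    def test_inflation_factor_formula(self, h2, trait, expected):
        meta = self._meta(np.linspace(0.2, 4.0, 15))
        out = cma_core.inflate(meta, InflationConfig(h2_prior=h2, trait_type=trait))
        assert out.inflation_factor == pytest.approx(expected, abs=1e-12)
        lam = np.median(meta.table["T"])
        np.testing.assert_allclose(
            out.table["T"], meta.table["T"] / lam * expected, rtol=1e-12
        )

    def test_effects_untouched_scores_recomputed(self):
        rng = np.random.default_rng(9)
        T = rng.chisquare(1, 40)
        sign = np.where(rng.random(40) < 0.5, -1.0, 1.0)
        meta = self._meta(T, sign)
        out = cma_core.inflate(meta, InflationConfig(h2_prior=0.3))
        np.testing.assert_array_equal(out.table["beta"], meta.table["beta"])
        np.testing.assert_array_equal(out.table["se"], meta.table["se"])
        np.testing.assert_allclose(out.table["T"], out.table["z"] ** 2, rtol=1e-12)
        np.testing.assert_allclose(
            out.table["p"], stats.chi2.sf(out.table["T"], 1), rtol=1e-12
        )
        assert np.all(np.sign(out.table["z"]) == np.sign(meta.table["beta"]))
        assert "se_t" in out.table.columns
        assert out.stage == "inflated"

    def test_requires_raw_stage_and_enough_variants(self):
        meta = self._meta(np.linspace(0.5, 2, 15))
        out = cma_core.inflate(meta, InflationConfig(h2_prior=0.2))
        with pytest.raises(ValidationError, match="raw"):
            cma_core.inflate(out, InflationConfig(h2_prior=0.2))
        small = self._meta([0.5, 1.0, 4.0])
        with pytest.raises(ValidationError, match="10 variants"):
            cma_core.inflate(small, InflationConfig(h2_prior=0.2))

    def test_bad_h2_rejected(self):
        with pytest.raises(InvalidConfigError):
            InflationConfig(h2_prior=1.4).validate()


class TestIncrementalCombination:
    def test_pseudo_cohort_consistency(self):
        config = SimulationConfig(
            n_unrelated=1500, n_sib_pairs=750, n_variants=1500, n_causal=150,
            h2=0.2, seed=42, mac_min_causal=50,
        )
        geno, _, y, _ = synthetic_data.simulate_cohort(config)
        pheno = null_pheno(geno, y)
        asg = splitter.split_cohort(geno.sample_ids, 3, 9)
        sss = [
            assoc.run_gwas(geno.subset_samples(asg.ids_for(i)), pheno.subset(asg.ids_for(i)), f"c{i}")
            for i in (1, 2, 3)
        ]
        harm3 = gwas_io.harmonize(sss)
        meta3 = cma_core.combine(harm3, cma_core.estimate_correlation(harm3), "CMA")

        harm_ab = gwas_io.harmonize(sss[:2])
        meta_ab = cma_core.combine(harm_ab, cma_core.estimate_correlation(harm_ab), "CMA")
        pseudo = cma_core.as_pseudo_cohort(meta_ab, "AB")
        harm_inc = gwas_io.harmonize([pseudo, sss[2]])
        meta_inc = cma_core.combine(harm_inc, cma_core.estimate_correlation(harm_inc), "CMA")

        a = meta3.table.set_index("id")
        b = meta_inc.table.set_index("id")
        common = a.index.intersection(b.index)
        rel_se = np.abs(b.loc[common, "se"] - a.loc[common, "se"]) / a.loc[common, "se"]
        # approximate identity: the bulk of variants agree to ~2%
        assert np.median(rel_se) < 0.02
        assert np.corrcoef(a.loc[common, "beta"], b.loc[common, "beta"])[0, 1] > 0.99

    def test_effective_n_subtracts_overlap(self):
        harm = harmonized_pair([0.2], [0.1], [0.1], [0.1], n1=100, n2=400)
        meta = cma_core.combine(harm, corr_for(harm, 0.5), "CMA")
        assert meta.table.loc[0, "n_eff"] == pytest.approx(500 - 0.5 * np.sqrt(100 * 400))
        pseudo = cma_core.as_pseudo_cohort(meta, "AB")
        assert pseudo.records.loc[0, "n"] == 400


def test_allele_flip_invariance_through_combination():
    """Flipping both cohorts' allele orientation at a variant leaves the
    combined result unchanged."""
    rng = np.random.default_rng(10)
    m = 150
    ids = [f"v{i}" for i in range(m)]
    beta1, beta2 = rng.normal(0, 0.1, m), rng.normal(0, 0.1, m)
    se = rng.uniform(0.05, 0.2, m)
    c1 = make_sumstats("c1", 100, ids, beta1, se)
    c2 = make_sumstats("c2", 100, ids, beta2, se)
    flip1 = make_sumstats("c1", 100, ids, -beta1, se, a1="G", a2="A", freq=0.7)
    flip2 = make_sumstats("c2", 100, ids, -beta2, se, a1="G", a2="A", freq=0.7)

    h = gwas_io.harmonize([c1, c2])
    hf = gwas_io.harmonize([flip1, flip2])
    r = cma_core.estimate_correlation(h, min_variants=50, warn_below=0)
    rf = cma_core.estimate_correlation(hf, min_variants=50, warn_below=0)
    np.testing.assert_allclose(rf.r, r.r, atol=1e-12)
    t = cma_core.combine(h, r, "CMA").table
    tf = cma_core.combine(hf, rf, "CMA").table
    np.testing.assert_allclose(tf["beta"].to_numpy(), -t["beta"].to_numpy(), atol=1e-12)
    np.testing.assert_allclose(tf["se"].to_numpy(), t["se"].to_numpy(), rtol=1e-12)
    np.testing.assert_allclose(tf["p"].to_numpy(), t["p"].to_numpy(), rtol=1e-9)
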