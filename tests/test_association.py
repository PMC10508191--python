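"""QC filters, GRM relatedness pruning, residualization, the inverse
normal transformation, joint regression (cross-checked against
statsmodels OLS), effective-test multiplicity, and conditional refits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invassoc.association import (
    MultiplicityResult,
    PhenotypeTable,
    compute_grm,
    conditional_adjustment,
    dc_coding,
    effective_tests,
    joint_inversion_regression,
    preresidualize,
    rank_int,
    relatedness_filter,
    significance_tiers,
    snp_sample_qc,
)


def hwe_dosages(rng, n, m, maf=None):
    p = rng.uniform(0.1, 0.5, m) if maf is None else np.full(m, maf)
    return (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)


def make_pheno(n, n_pheno=2, seed=0, y=None):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    if y is None:
        y = rng.standard_normal((n, n_pheno))
    pheno = pd.DataFrame(y, index=ids, columns=[f"p{j}" for j in range(y.shape[1])])
    covars = pd.DataFrame(
        {
            "age": rng.normal(50, 5, n),
            "sex": rng.integers(0, 2, n),
            "site": rng.integers(0, 3, n),
            "quality": rng.standard_normal(n),
        },
        index=ids,
    )
    glob = pd.DataFrame({"global": rng.standard_normal(n)}, index=ids)
    return PhenotypeTable(
        phenotypes=pheno,
        covariates=covars,
        global_measures=glob,
        global_map={c: "global" for c in pheno.columns},
    )


class TestSnpSampleQc:
    def test_clean_matrix_untouched(self):
        G = hwe_dosages(np.random.default_rng(0), 500, 20)
        out, report = snp_sample_qc(G)
        assert out.shape == G.shape
        assert report.n_individuals_removed == 0
        assert report.n_snps_missingness == report.n_snps_hwe == report.n_snps_maf == 0

    def test_low_maf_snp_removed(self):
        rng = np.random.default_rng(1)
        G = hwe_dosages(rng, 1000, 5)
        G[:, 2] = 0.0
        G[:5, 2] = 1.0  # MAF 0.0025
        out, report = snp_sample_qc(G)
        assert report.n_snps_maf == 1
        assert out.shape[1] == 4

    def test_hwe_violation_removed(self):
        rng = np.random.default_rng(2)
        G = hwe_dosages(rng, 1000, 4)
        G[:, 1] = np.repeat([0.0, 2.0], 500)  # no heterozygotes: chi2 = n
        out, report = snp_sample_qc(G)
        assert report.n_snps_hwe == 1

    def test_missing_individuals_dropped_first(self):
        rng = np.random.default_rng(3)
        G = hwe_dosages(rng, 100, 20)
        G[0, :5] = np.nan  # 25% missing
        out, report = snp_sample_qc(G)
        assert report.n_individuals_removed == 1
        assert out.shape[0] == 99

    def test_everything_removed_is_error(self):
        G = np.zeros((100, 2))
        with pytest.raises(ValueError):
            snp_sample_qc(G)


class TestGrm:
    def test_duplicated_individual_off_diagonal_near_one(self):
        rng = np.random.default_rng(4)
        M = 5000
        G = hwe_dosages(rng, 50, M)
        G[1] = G[0]
        A = compute_grm(G)
        assert abs(A[0, 1] - 1.0) < 3 * np.sqrt(2 / M)

    def test_unrelated_pair_near_zero_and_diagonal_near_one(self):
        rng = np.random.default_rng(5)
        M = 10000
        A = compute_grm(hwe_dosages(rng, 30, M))
        off = A[~np.eye(30, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert abs(np.mean(np.diag(A)) - 1.0) < 0.05

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            compute_grm(np.zeros((10, 3)))


class TestRelatednessFilter:
    def test_unrelated_all_retained(self):
        A = np.eye(4)
        retained, removed = relatedness_filter(A)
        assert retained == [0, 1, 2, 3] and removed == []

    def test_one_related_pair_loses_one_member(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 0.5
        retained, removed = relatedness_filter(A)
        assert len(removed) == 1 and removed[0] in (0, 1)

    def test_related_triangle_loses_two(self):
        A = np.eye(5)
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            A[i, j] = A[j, i] = 0.3
        retained, removed = relatedness_filter(A)
        assert len(removed) == 2
        assert len(set(retained) & {0, 1, 2}) == 1


class TestPreresidualize:
    def test_phenotype_linear_in_age_fully_removed(self):
        table = make_pheno(200, seed=6)
        table.phenotypes["p0"] = 2.0 * table.covariates["age"] + 1.0
        resid = preresidualize(table)
        assert np.abs(resid["p0"]).max() < 1e-8

    def test_residuals_orthogonal_to_covariates(self):
        table = make_pheno(300, seed=7)
        resid = preresidualize(table)
        for c in ("age", "quality"):
            r = np.corrcoef(resid["p0"], table.covariates[c].astype(float))[0, 1]
            assert abs(r) < 1e-10

    def test_global_measure_regressed_out_when_requested(self):
        table = make_pheno(500, seed=8)
        g = table.global_measures["global"].to_numpy()
        table.phenotypes["p0"] = 2.0 * g + np.random.default_rng(8).standard_normal(500)
        resid = preresidualize(table, adjust_global=True)
        slope = np.polyfit(g, resid["p0"], 1)[0]
        assert abs(slope) < 1e-8

    def test_collinear_covariates_rejected_by_name(self):
        table = make_pheno(100, seed=9)
        table.covariates["age_copy"] = table.covariates["age"]
        with pytest.raises(ValueError, match="age_copy"):
            preresidualize(table)


class TestRankInt:
    def test_three_values_closed_form(self):
        out = rank_int(np.array([1.0, 2.0, 3.0]))
        expected_low = stats.norm.ppf((1 - 3 / 8) / 3.25)
        assert out[0] == pytest.approx(expected_low)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[2] == pytest.approx(-expected_low)

    def test_mean_zero_for_tie_free_input(self):
        rng = np.random.default_rng(10)
        out = rank_int(rng.standard_normal(101))
        assert abs(out.mean()) < 1e-6

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(11)
        v = rng.standard_normal(50)
        assert np.allclose(rank_int(v), rank_int(np.exp(v)))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_int(np.ones(10))


class TestDcCoding:
    def test_male_codings(self):
        g = np.array([0.0, 1.0, 1.0])
        sex = np.array([1, 1, 0])
        assert dc_coding(g, sex, "full_dc").tolist() == [0.0, 2.0, 1.0]
        assert dc_coding(g, sex, "no_dc").tolist() == [0.0, 1.0, 1.0]

    def test_female_unchanged_under_both_modes(self):
        g = np.array([2.0, 1.0])
        sex = np.array([0, 0])
        for mode in ("full_dc", "no_dc"):
            assert dc_coding(g, sex, mode).tolist() == [2.0, 1.0]

    def test_diploid_male_value_rejected(self):
        with pytest.raises(ValueError):
            dc_coding(np.array([2.0]), np.array([1]), "full_dc")

    def test_full_dc_data_better_fit_by_full_dc_coding(self):
        # generated under full DC, the matched coding should give the
        # larger median |t| for the X-linked locus
        rng = np.random.default_rng(12)
        t_full, t_none = [], []
        for _ in range(100):
            n = 400
            sex = rng.integers(0, 2, n)
            hemi = rng.random(n) < 0.2
            dip = (rng.random(n) < 0.2).astype(float) + (rng.random(n) < 0.2)
            g = np.where(sex == 1, hemi.astype(float), dip)
            d_true = dc_coding(g, sex, "full_dc")
            y = 0.2 * d_true + rng.standard_normal(n)
            for mode, store in (("full_dc", t_full), ("no_dc", t_none)):
                d = dc_coding(g, sex, mode)
                res = joint_inversion_regression(
                    pd.DataFrame({"y": y}), pd.DataFrame({"x": d})
                )
                store.append(abs(res[0].t))
        assert np.median(t_full) > np.median(t_none)


class TestJointRegression:
    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        n, m = 300, 3
        D = pd.DataFrame(hwe_dosages(rng, n, m), columns=[f"i{j}" for j in range(m)])
        y = rng.standard_normal(n)
        res = joint_inversion_regression(pd.DataFrame({"y": y}), D)
        X = sm.add_constant(D.to_numpy())
        fit = sm.OLS(y, X).fit()
        for j, r in enumerate(res):
            assert r.beta == pytest.approx(fit.params[j + 1], abs=1e-10)
            assert r.se == pytest.approx(fit.bse[j + 1], abs=1e-10)
            assert r.p == pytest.approx(fit.pvalues[j + 1], abs=1e-10)

    def test_incremental_r2_analytic_for_orthogonal_predictor(self):
        rng = np.random.default_rng(14)
        n = 10000
        d = hwe_dosages(rng, n, 1)[:, 0]
        y = 0.2 * d + rng.standard_normal(n)
        res = joint_inversion_regression(pd.DataFrame({"y": y}), pd.DataFrame({"d": d}))
        expected = res[0].beta ** 2 * np.var(d) / np.var(y)
        assert res[0].incremental_r2 == pytest.approx(expected, abs=1e-3)

    def test_collinear_dosages_rejected(self):
        rng = np.random.default_rng(15)
        d = hwe_dosages(rng, 100, 1)[:, 0]
        D = pd.DataFrame({"a": d, "b": d})
        with pytest.raises(ValueError, match="a.*b"):
            joint_inversion_regression(pd.DataFrame({"y": d + 1.0}), D)

    def test_incremental_r2_sums_below_model_r2_for_orthogonal_predictors(self):
        rng = np.random.default_rng(16)
        n, m = 2000, 4
        raw = hwe_dosages(rng, n, m)
        # orthogonalize the centered columns so unique contributions add up
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        D = pd.DataFrame(Q, columns=[f"i{j}" for j in range(m)])
        y = Q @ np.array([1.0, 2.0, 0.0, -1.0]) + rng.standard_normal(n)
        res = joint_inversion_regression(pd.DataFrame({"y": y}), D)
        X = np.column_stack([np.ones(n), Q])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        r2_full = 1 - ((y - X @ coef) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert sum(r.incremental_r2 for r in res) <= r2_full + 1e-9


class TestEffectiveTests:
    def test_identity_counts_every_phenotype(self):
        assert effective_tests(np.eye(7)).t_e == pytest.approx(7.0)

    def test_perfect_correlation_counts_one(self):
        assert effective_tests(np.ones((3, 3))).t_e == pytest.approx(1.0)

    def test_equicorrelated_li_ji_value(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        assert effective_tests(C).t_e == pytest.approx(2.0, abs=1e-9)

    def test_t_e_decreases_with_equicorrelation(self):
        vals = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            C = np.full((6, 6), rho)
            np.fill_diagonal(C, 1.0)
            t_e = effective_tests(C).t_e
            assert 1.0 <= t_e <= 6.0
            vals.append(t_e)
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_nyholt_variant(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        lam = np.array([2.0, 0.5, 0.5])
        expected = 1 + 2 * (1 - np.var(lam, ddof=1) / 3)
        assert effective_tests(C, method="nyholt").t_e == pytest.approx(expected)

    def test_non_psd_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            effective_tests(C)


class TestSignificanceTiers:
    MULT = MultiplicityResult(t_e=22.0, eigenvalues=np.ones(22), alpha=0.05)

    def test_genome_wide(self):
        assert significance_tiers(1e-9, self.MULT) == "genome_wide"

    def test_bonferroni_at_reported_effective_tests(self):
        # 1e-3 < 0.05/22 = 2.27e-3
        assert significance_tiers(1e-3, self.MULT) == "bonferroni"

    def test_nominal_and_none(self):
        assert significance_tiers(0.03, self.MULT) == "nominal"
        assert significance_tiers(0.5, self.MULT) == "none"

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_tiers(0.0, self.MULT)


class TestConditionalAdjustment:
    def test_tag_snp_absorbs_inversion_signal(self):
        # a SNP in r^2 ~ 0.98 with the inversion absorbs a signal
        # generated through the inversion: after conditioning, the median
        # inversion p across replicates is indistinguishable from noise
        # while the unconditional p is astronomically small
        rng = np.random.default_rng(17)
        n = 5000
        cond_ps, uncond_ps = [], []
        for _ in range(15):
            d = hwe_dosages(rng, n, 1, maf=0.2)[:, 0]
            snp = d.copy()
            swap = rng.random(n) < 0.004
            snp[swap] = rng.integers(0, 3, swap.sum())
            y = 0.3 * d + rng.standard_normal(n)
            selected, res = conditional_adjustment(
                y, d, pd.DataFrame({"snp": snp}), select_p=5e-8
            )
            assert selected == ["snp"]
            cond_ps.append(res.p)
            uncond_ps.append(
                joint_inversion_regression(
                    pd.DataFrame({"y": y}), pd.DataFrame({"d": d})
                )[0].p
            )
        assert np.median(uncond_ps) < 5e-8
        assert np.median(cond_ps) > 0.05

    def test_no_selection_reduces_to_unconditional(self):
        rng = np.random.default_rng(18)
        n = 1000
        d = hwe_dosages(rng, n, 1)[:, 0]
        snps = pd.DataFrame(hwe_dosages(rng, n, 3), columns=list("abc"))
        y = 0.2 * d + rng.standard_normal(n)
        selected, res = conditional_adjustment(y, d, snps, select_p=1e-300)
        assert selected == []
        uncond = joint_inversion_regression(
            pd.DataFrame({"y": y}), pd.DataFrame({"d": d})
        )[0]
        assert res.beta == pytest.approx(uncond.beta, abs=1e-12)
        assert res.p == pytest.approx(uncond.p, abs=1e-12)

    def test_independent_snp_leaves_inversion_effect(self):
        rng = np.random.default_rng(19)
        n = 5000
        d = hwe_dosages(rng, n, 1, maf=0.2)[:, 0]
        snp = hwe_dosages(rng, n, 1, maf=0.3)[:, 0]
        y = 0.2 * d + 0.3 * snp + rng.standard_normal(n)
        selected, res = conditional_adjustment(y, d, pd.DataFrame({"snp": snp}))
        uncond = joint_inversion_regression(
            pd.DataFrame({"y": y}), pd.DataFrame({"d": d})
        )[0]
        assert selected == ["snp"]
        assert abs(res.beta - uncond.beta) < 2 * uncond.se


def test_pipeline_equivariant_to_phenotype_shift():
    from invassoc.pipeline import RunConfig, associate_cohort

    rng = np.random.default_rng(20)
    n = 500
    table = make_pheno(n, seed=21)
    D = pd.DataFrame(
        {"inv00": hwe_dosages(rng, n, 1, maf=0.2)[:, 0]}, index=table.sample_ids
    )
    cfg = RunConfig()
    res_a, _ = associate_cohort(D, table, cfg)
    shifted = make_pheno(n, seed=21)
    shifted.phenotypes += 100.0
    res_b, _ = associate_cohort(D, shifted, cfg)
    for a, b in zip(res_a, res_b):
        assert a.beta == pytest.approx(b.beta, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-10)
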