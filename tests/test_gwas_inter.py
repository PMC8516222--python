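import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hsgwas.errors import DomainError
from hsgwas.geno_qc import Grm
from hsgwas.gwas_inter import (
    CHI2_1DF_MEDIAN,
    GlsScanner,
    assemble_v,
    classify_hits,
    count_independent,
    gls_augmented,
    gls_scan,
    inflation_factor,
    snp_columns,
    thresholds,
)
from hsgwas.varcomp import MixedModelSpec, VarianceComponents

from conftest import make_genotypes


def _spec_and_vc(n=100, seed=0, p_cov=3, s2=(0.4, None, 0.6), exposed_frac=0.5):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n))
    g_values = a @ a.T / n + np.eye(n) * 0.05  # random PSD "GRM"
    ids = np.array([f"a{i}" for i in range(n)])
    exposed = rng.random(n) < exposed_frac
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p_cov - 1))])
    y = rng.standard_normal(n)
    spec = MixedModelSpec(y=y, X=X, grm=Grm(ids, g_values), exposed_mask=exposed)
    s2g, s2ghs, s2e = s2
    vc = VarianceComponents(sigma2_g=s2g, sigma2_ghs=s2ghs, sigma2_e=s2e)
    return spec, vc


class TestSnpColumns:
    def test_centering(self):
        x_snp, x_inter = snp_columns(np.array([0.0, 1.0, 2.0]), 0.5,
                                     np.array([True, False, True]))
        np.testing.assert_allclose(x_snp, [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(x_inter, [-1.0, 0.0, 1.0])

    def test_unexposed_zeroed(self):
        x_snp, x_inter = snp_columns(np.array([0.0, 1.0, 2.0]), 0.5,
                                     np.array([False, False, False]))
        np.testing.assert_allclose(x_inter, 0.0)

    def test_everyone_exposed_aliases_main(self):
        x_snp, x_inter = snp_columns(np.array([2.0, 1.0, 0.0]), 0.4,
                                     np.array([True, True, True]))
        np.testing.assert_allclose(x_inter, x_snp)


class TestGlsAugmented:
    def test_identity_v_equals_ols(self):
        spec, _ = _spec_and_vc(n=80, seed=1)
        vc = VarianceComponents(sigma2_g=0.0, sigma2_ghs=0.0, sigma2_e=1.0)
        rng = np.random.default_rng(2)
        doses = rng.binomial(2, 0.4, size=80).astype(float)
        x_snp, x_inter = snp_columns(doses, doses.mean() / 2, spec.exposed_mask)
        fit = gls_augmented(spec, vc, x_snp, x_inter)
        # OLS oracle on the augmented design
        X1 = np.column_stack([spec.X, x_snp, x_inter])
        beta, *_ = np.linalg.lstsq(X1, spec.y, rcond=None)
        cov = np.linalg.inv(X1.T @ X1)
        assert fit["beta_main"] == pytest.approx(beta[-2], rel=1e-8)
        assert fit["beta_inter"] == pytest.approx(beta[-1], rel=1e-8)
        assert fit["se_main"] == pytest.approx(np.sqrt(cov[-2, -2]), rel=1e-8)

    def test_matches_dense_oracle_random_v(self):
        spec, vc = _spec_and_vc(n=120, seed=3, s2=(0.5, 0.2, 0.8))
        rng = np.random.default_rng(4)
        doses = rng.binomial(2, 0.3, size=120).astype(float)
        x_snp, x_inter = snp_columns(doses, doses.mean() / 2, spec.exposed_mask)
        fit = gls_augmented(spec, vc, x_snp, x_inter)
        V = assemble_v(spec, vc)
        X1 = np.column_stack([spec.X, x_snp, x_inter])
        Vi = np.linalg.inv(V)
        cov = np.linalg.inv(X1.T @ Vi @ X1)
        beta = cov @ X1.T @ Vi @ spec.y
        assert fit["beta_main"] == pytest.approx(beta[-2], rel=1e-8)
        assert fit["beta_inter"] == pytest.approx(beta[-1], rel=1e-8)
        assert fit["se_inter"] == pytest.approx(np.sqrt(cov[-1, -1]), rel=1e-8)
        assert fit["cov_main_inter"] == pytest.approx(cov[-2, -1], rel=1e-6)

    def test_nobody_exposed_drops_interaction(self):
        spec, vc = _spec_and_vc(n=60, seed=5, exposed_frac=0.0)
        rng = np.random.default_rng(6)
        doses = rng.binomial(2, 0.4, size=60).astype(float)
        x_snp, x_inter = snp_columns(doses, doses.mean() / 2, spec.exposed_mask)
        fit = gls_augmented(spec, vc, x_snp, x_inter)
        assert fit["status"] == "interaction-dropped"
        assert np.isfinite(fit["beta_main"])
        assert np.isnan(fit["beta_inter"])

    def test_everyone_exposed_drops_interaction(self):
        spec, vc = _spec_and_vc(n=60, seed=7, exposed_frac=1.1)
        rng = np.random.default_rng(8)
        doses = rng.binomial(2, 0.4, size=60).astype(float)
        x_snp, x_inter = snp_columns(doses, doses.mean() / 2, spec.exposed_mask)
        assert np.allclose(x_inter, x_snp)
        fit = gls_augmented(spec, vc, x_snp, x_inter)
        assert fit["status"] == "interaction-dropped"

    def test_monomorphic_skipped(self):
        spec, vc = _spec_and_vc(n=40, seed=9)
        fit = gls_augmented(spec, vc, np.zeros(40), None)
        assert fit["status"] == "skipped"

    def test_chi2_is_beta_over_se_squared(self):
        spec, vc = _spec_and_vc(n=90, seed=10, s2=(0.3, 0.1, 0.7))
        rng = np.random.default_rng(11)
        doses = rng.binomial(2, 0.25, size=90).astype(float)
        x_snp, x_inter = snp_columns(doses, doses.mean() / 2, spec.exposed_mask)
        fit = gls_augmented(spec, vc, x_snp, x_inter)
        assert fit["chi2_main"] == pytest.approx((fit["beta_main"] / fit["se_main"]) ** 2)
        assert fit["p_main"] == pytest.approx(stats.chi2.sf(fit["chi2_main"], 1))


class TestAlleleFlipInvariance:
    def test_main_chi2_invariant_under_flip(self):
        spec, vc = _spec_and_vc(n=100, seed=12, s2=(0.4, 0.1, 0.6))
        rng = np.random.default_rng(13)
        doses = rng.binomial(2, 0.3, size=100).astype(float)
        p = doses.mean() / 2
        x1 = snp_columns(doses, p, spec.exposed_mask)
        x2 = snp_columns(2.0 - doses, 1.0 - p, spec.exposed_mask)
        f1 = gls_augmented(spec, vc, *x1)
        f2 = gls_augmented(spec, vc, *x2)
        assert f1["chi2_main"] == pytest.approx(f2["chi2_main"], rel=1e-10)
        assert f1["chi2_inter"] == pytest.approx(f2["chi2_inter"], rel=1e-10)
        assert f1["beta_main"] == pytest.approx(-f2["beta_main"], rel=1e-10)


class TestWhsReducesToNhs:
    def test_zero_interaction_variance_same_fits(self):
        spec, _ = _spec_and_vc(n=80, seed=14)
        vc_whs = VarianceComponents(sigma2_g=0.4, sigma2_ghs=0.0, sigma2_e=0.6)
        vc_nhs = VarianceComponents(sigma2_g=0.4, sigma2_ghs=None, sigma2_e=0.6)
        rng = np.random.default_rng(15)
        doses = rng.binomial(2, 0.35, size=80).astype(float)
        x = snp_columns(doses, doses.mean() / 2, spec.exposed_mask)
        f1 = gls_augmented(spec, vc_whs, *x)
        f2 = gls_augmented(spec, vc_nhs, *x)
        for key in ("beta_main", "beta_inter", "se_main", "se_inter"):
            assert f1[key] == pytest.approx(f2[key], abs=1e-10)


class TestInflationFactor:
    def test_reference_median_gives_one(self):
        assert inflation_factor([CHI2_1DF_MEDIAN] * 5) == pytest.approx(1.0)

    def test_doubled_median_gives_two(self):
        assert inflation_factor([2 * CHI2_1DF_MEDIAN] * 5) == pytest.approx(2.0)

    def test_monte_carlo_null(self):
        rng = np.random.default_rng(16)
        chi2 = rng.chisquare(1, size=400_000)  # median SE ~ 0.004 on this scale
        assert inflation_factor(chi2) == pytest.approx(1.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            inflation_factor([])

    def test_reference_constant(self):
        assert CHI2_1DF_MEDIAN == pytest.approx(0.4549364, abs=5e-8)


class TestThresholds:
    def test_study_counts(self):
        ts = thresholds(41_139, 3_873)
        assert ts.p_bonf == pytest.approx(1.22e-6, rel=5e-3)
        assert ts.neglog_bonf == pytest.approx(5.92, abs=5e-3)
        assert ts.neglog_sugg == pytest.approx(4.89, abs=5e-3)

    def test_single_snp(self):
        ts = thresholds(1, 1)
        assert ts.p_bonf == pytest.approx(0.05)

    def test_zero_rejected(self):
        with pytest.raises(DomainError):
            thresholds(0, 1)


class TestCountIndependent:
    def test_orthogonal_columns_all_kept(self):
        # indicator columns: pairwise r^2 = (1/(n-1))^2, far below 0.15
        n, m = 500, 400
        doses = np.zeros((n, m))
        doses[np.arange(m), np.arange(m)] = 2.0
        g = make_genotypes(doses)
        assert count_independent(g) == 400

    def test_identical_columns_one_per_window(self):
        n, m = 50, 1000
        rng = np.random.default_rng(17)
        col = rng.binomial(2, 0.5, size=n).astype(float)
        doses = np.tile(col[:, None], (1, m))
        g = make_genotypes(doses)
        assert count_independent(g, window=500) == 2

    def test_single_marker(self):
        g = make_genotypes(np.array([[0.0], [1.0], [2.0]]))
        assert count_independent(g) == 1

    def test_split_across_chromosomes(self):
        n = 50
        rng = np.random.default_rng(18)
        col = rng.binomial(2, 0.5, size=n).astype(float)
        doses = np.tile(col[:, None], (1, 600))
        g = make_genotypes(doses, chrom=[1] * 300 + [2] * 300)
        # one survivor per chromosome (each fits in a single window)
        assert count_independent(g, window=500) == 2


class TestGlsScan:
    def test_scan_matches_per_snp_fits(self, rng):
        spec, vc = _spec_and_vc(n=80, seed=19, s2=(0.4, 0.1, 0.6))
        m = 25
        doses = rng.binomial(2, rng.uniform(0.2, 0.5, size=m), size=(80, m)).astype(float)
        g = make_genotypes(doses)
        scan = gls_scan(spec, vc, g, trait="y", week=1)
        assert len(scan.fits) == m
        p_hat = doses.mean(axis=0) / 2
        for j in [0, 7, 24]:
            x = snp_columns(doses[:, j], p_hat[j], spec.exposed_mask)
            ref = gls_augmented(spec, vc, *x)
            assert scan.fits.loc[j, "beta_main"] == pytest.approx(ref["beta_main"], rel=1e-9)
            assert scan.fits.loc[j, "p_inter"] == pytest.approx(ref["p_inter"], rel=1e-9)

    def test_scan_survives_bad_markers(self, rng):
        spec, vc = _spec_and_vc(n=60, seed=20)
        doses = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
        doses[:, 2] = 2.0  # monomorphic
        g = make_genotypes(doses)
        scan = gls_scan(spec, vc, g)
        assert scan.fits.loc[2, "status"] == "skipped"
        assert (scan.fits.drop(index=2)["status"] == "ok").all()

    def test_injected_interaction_is_top_hit(self):
        rng = np.random.default_rng(21)
        n, m = 400, 200
        p = rng.uniform(0.2, 0.5, size=m)
        doses = rng.binomial(2, p, size=(n, m)).astype(float)
        exposed = rng.random(n) < 0.5
        ids = np.array([f"a{i}" for i in range(n)])
        g_values = np.eye(n)  # keep the oracle simple: independent animals
        x_causal = doses[:, 42] - doses[:, 42].mean()
        y = 0.8 * x_causal * exposed + rng.standard_normal(n)
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), grm=Grm(ids, g_values),
                              exposed_mask=exposed)
        vc = VarianceComponents(sigma2_g=1e-6, sigma2_ghs=1e-6, sigma2_e=1.0)
        scan = gls_scan(spec, vc, make_genotypes(doses))
        assert scan.fits["chi2_inter"].idxmax() == 42


class TestClassifyHits:
    def _scan_with_p(self, p_values):
        fits = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(len(p_values))],
            "p_main": p_values, "p_inter": np.nan,
        })
        from hsgwas.gwas_inter import ScanResult

        ts = thresholds(1000, 100)
        return ScanResult("y", 1, "GWA_wHS", fits, 1.0, 1.0, ts)

    def test_boundary_is_significant(self):
        ts = thresholds(1000, 100)
        scan = self._scan_with_p([ts.p_bonf])
        assert classify_hits(scan).loc[0, "label_main"] == "significant"

    def test_between_thresholds_is_suggestive(self):
        ts = thresholds(1000, 100)
        scan = self._scan_with_p([0.5 * (ts.p_bonf + ts.p_sugg)])
        assert classify_hits(scan).loc[0, "label_main"] == "suggestive"

    def test_above_suggestive_is_none(self):
        scan = self._scan_with_p([0.5])
        labeled = classify_hits(scan)
        assert labeled.loc[0, "label_main"] == "none"
        assert labeled.loc[0, "label_inter"] == "none"

    def test_empty_scan(self):
        scan = self._scan_with_p([])
        assert len(classify_hits(scan)) == 0
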