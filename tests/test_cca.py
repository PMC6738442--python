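"""CCA core: oracle equivalence, permutation inference, structure
loadings, subdomain importance, congruence, and recovery properties."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla

from ccamode import (
    cca_analysis,
    factor_congruence,
    fit_cca,
    generate_cohort,
    pca_reduce,
    permutation_fwe,
    structure_loadings,
    subdomain_importance,
)
from ccamode.preprocess import preprocess_tables

from conftest import make_table, small_config


def brute_force_rc(X, Y):
    """Canonical correlations as square roots of the eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx — the textbook generalized eigenproblem, solved
    directly (independent of the QR-SVD implementation)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc
    Syy = Yc.T @ Yc
    Sxy = Xc.T @ Yc
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    eig = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    k = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eig[:k], 0, 1))


class TestPCAReduce:
    def test_full_rank_cumulative_variance_one(self):
        tab = make_table(np.random.default_rng(0).normal(size=(12, 5)))
        red = pca_reduce(tab, d=5)
        assert red.cumulative_variance[-1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_of_covariance(self):
        """4x3 worked matrix: PCA basis equals the eigenvectors of the
        covariance matrix up to sign, scores reproduce the data."""
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 0.0], [3.0, 5.0, 1.5], [0.0, 2.0, 1.0]])
        tab = make_table(X)
        red = pca_reduce(tab, d=3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert red.variance_explained == pytest.approx(evals / evals.sum(), abs=1e-10)
        for j in range(3):
            dot = abs(np.dot(red.basis[:, j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(red.scores @ red.basis.T, Xc, atol=1e-10)

    def test_study_scale_dimensions(self):
        tab = make_table(np.random.default_rng(1).normal(size=(193, 60)))
        red = pca_reduce(tab, d=30)
        assert red.scores.shape == (193, 30)
        assert (np.diff(red.variance_explained) <= 1e-12).all()

    def test_d_too_large_rejected(self):
        tab = make_table(np.random.default_rng(2).normal(size=(8, 4)))
        with pytest.raises(ValueError):
            pca_reduce(tab, d=5)

    def test_incomplete_table_rejected(self):
        vals = np.random.default_rng(3).normal(size=(10, 4))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca_reduce(make_table(vals), d=2)


class TestFitCCA:
    def test_identical_sets_all_ones(self):
        X = np.random.default_rng(4).normal(size=(25, 4))
        res = fit_cca(X, X.copy())
        assert np.allclose(res.rc, 1.0, atol=1e-10)

    def test_bivariate_reduction_to_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 1))
        y = 0.6 * x + rng.normal(size=(40, 1))
        res = fit_cca(x, y)
        assert res.rc[0] == pytest.approx(abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-12)

    def test_oracle_equivalence_100_instances(self):
        """QR-SVD canonical correlations match the brute-force generalized
        eigenproblem on 100 random 20-subject instances to 1e-8."""
        rng = np.random.default_rng(6)
        worst = 0.0
        for _ in range(100):
            X = rng.normal(size=(20, 3))
            Y = rng.normal(size=(20, 4))
            got = fit_cca(X, Y).rc
            want = brute_force_rc(X, Y)
            worst = max(worst, float(np.max(np.abs(got - want))))
        assert worst < 1e-8

    def test_variates_unit_variance_and_cross_orthogonal(self):
        rng = np.random.default_rng(7)
        X, Y = rng.normal(size=(60, 5)), rng.normal(size=(60, 6))
        res = fit_cca(X, Y)
        for M in (res.U, res.V):
            assert np.allclose(M.var(axis=0, ddof=1), 1.0, atol=1e-8)
        k = res.n_modes
        for i in range(k):
            for j in range(k):
                c = np.corrcoef(res.U[:, i], res.V[:, j])[0, 1]
                if i == j:
                    assert c == pytest.approx(res.rc[i], abs=1e-8)
                else:
                    assert abs(c) < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        X, Y = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        a = fit_cca(X, Y)
        b = fit_cca(X.copy(), Y.copy())
        assert np.array_equal(a.A, b.A) and np.array_equal(a.B, b.B)
        for i in range(a.n_modes):
            assert a.A[np.argmax(np.abs(a.A[:, i])), i] > 0

    def test_rank_deficiency_reduced_with_warning(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # dependent column
        Y = rng.normal(size=(30, 3))
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = fit_cca(X, Y)
        assert res.n_modes == 3


class TestPermutationFWE:
    def test_boundary_p_value(self):
        """Signal far above every null max hits the +1 convention floor."""
        rng = np.random.default_rng(10)
        z = rng.normal(size=(80, 2))
        X = np.column_stack([z[:, 0], rng.normal(size=80)])
        Y = np.column_stack([z[:, 0] + 0.01 * rng.normal(size=80), rng.normal(size=80)])
        p, null_max = permutation_fwe(X, Y, n_perm=200, seed=1)
        assert p[0] == pytest.approx(1 / 201)

    def test_p_values_non_decreasing(self):
        rng = np.random.default_rng(11)
        X, Y = rng.normal(size=(50, 4)), rng.normal(size=(50, 4))
        p, _ = permutation_fwe(X, Y, n_perm=300, seed=2)
        assert (np.diff(p) >= 0).all()

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(12)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_fwe(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)), n_perm=50, seed=0)

    def test_exchangeability_exact(self):
        """Reordering subjects of both matrices identically (with the
        canonical-order hook) leaves rc and p_fwe bit-identical."""
        rng = np.random.default_rng(13)
        X, Y = rng.normal(size=(40, 3)), rng.normal(size=(40, 3))
        ids = np.array([f"S{i:03d}" for i in range(40)])
        perm = rng.permutation(40)
        order1 = np.argsort(ids)
        order2 = np.argsort(ids[perm])
        p1, _ = permutation_fwe(X, Y, n_perm=200, seed=5, order=order1)
        p2, _ = permutation_fwe(X[perm], Y[perm], n_perm=200, seed=5, order=order2)
        assert np.allclose(fit_cca(X, Y).rc, fit_cca(X[perm], Y[perm]).rc, atol=1e-12)
        assert np.array_equal(p1, p2)


class TestStructureLoadings:
    def test_variable_identical_to_variate(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=30)
        tab = make_table(v.reshape(-1, 1))
        out = structure_loadings(tab, v)
        assert out["loading"].iloc[0] == pytest.approx(1.0)
        assert out["reported"].iloc[0]

    def test_loading_squared_r2(self):
        rng = np.random.default_rng(15)
        v = rng.normal(size=200)
        x = 0.434 * v + math.sqrt(1 - 0.434**2) * rng.normal(size=200)
        tab = make_table(x.reshape(-1, 1))
        out = structure_loadings(tab, v)
        assert out["r2"].iloc[0] == pytest.approx(out["loading"].iloc[0] ** 2)

    def test_against_direct_correlation_oracle(self):
        """Loadings equal column-by-column correlations computed through an
        independent covariance routine, to 1e-12."""
        rng = np.random.default_rng(16)
        X = rng.normal(size=(50, 10))
        v = rng.normal(size=50)
        tab = make_table(X)
        out = structure_loadings(tab, v, apply_polarity=False)
        Xc = X - X.mean(axis=0)
        vc = v - v.mean()
        cov = Xc.T @ vc / (len(v) - 1)
        expect = cov / (Xc.std(axis=0, ddof=1) * vc.std(ddof=1))
        assert out["loading"].to_numpy() == pytest.approx(expect, abs=1e-12)

    def test_polarity_inversion_applied(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=40)
        tab = make_table((-v).reshape(-1, 1), polarity=[-1])
        out = structure_loadings(tab, v)
        assert out["loading"].iloc[0] == pytest.approx(1.0)

    def test_report_filter_threshold(self):
        rng = np.random.default_rng(18)
        v = rng.normal(size=500)
        weak = 0.05 * v + rng.normal(size=500)
        tab = make_table(weak.reshape(-1, 1))
        out = structure_loadings(tab, v)
        assert not out["reported"].iloc[0]


class TestSubdomainImportance:
    def _loadings(self, loadings, subdomains):
        return pd.DataFrame(
            {
                "variable": [f"v{i}" for i in range(len(loadings))],
                "subdomain": subdomains,
                "loading": loadings,
                "r2": np.array(loadings) ** 2,
            }
        )

    def test_single_member_subdomain(self):
        out = subdomain_importance(self._loadings([0.5], ["a"]))
        assert out["positive_r2_mean"].iloc[0] == pytest.approx(0.25)
        assert out["negative_r2_mean"].iloc[0] == 0.0

    def test_mixed_sign_aggregation_by_enumeration(self):
        """{+0.6, -0.3, 0.0} in one 3-member subdomain: positive bar
        0.36/3, negative bar 0.09/3, zero loads neither."""
        out = subdomain_importance(self._loadings([0.6, -0.3, 0.0], ["a"] * 3))
        assert out["positive_r2_mean"].iloc[0] == pytest.approx(0.36 / 3)
        assert out["negative_r2_mean"].iloc[0] == pytest.approx(0.09 / 3)

    def test_all_zero_loadings(self):
        out = subdomain_importance(self._loadings([0.0, 0.0], ["a", "a"]))
        assert out["positive_r2_mean"].iloc[0] == 0.0
        assert out["negative_r2_mean"].iloc[0] == 0.0

    def test_all_positive_bar_equals_plain_mean(self):
        lo = [0.4, 0.2, 0.6]
        out = subdomain_importance(self._loadings(lo, ["a"] * 3))
        assert out["positive_r2_mean"].iloc[0] == pytest.approx(np.mean(np.square(lo)))


class TestFactorCongruence:
    def test_scale_invariance(self):
        a = np.array([0.3, -0.2, 0.7])
        assert factor_congruence(a, 2 * a) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert factor_congruence(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_arithmetic(self):
        a = np.array([1.0, 0.0, 1.0])
        b = np.array([1.0, 1.0, 0.0])
        assert factor_congruence(a, b) == pytest.approx(0.5)

    def test_missing_loadings_dropped_pairwise(self):
        a = np.array([1.0, np.nan, 1.0])
        b = np.array([1.0, 5.0, 1.0])
        assert factor_congruence(a, b) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            factor_congruence(np.zeros(3), np.ones(3))


class TestModeRecoverySmall:
    """End-to-end recovery on a reduced cohort (fast); the full study-scale
    version lives in the acceptance suite."""

    def _run(self, seed):
        cfg = small_config(
            seed=seed, n_subjects=193, n_idp=40, n_nonidp=20, rc=0.75,
            missing_rate_nonidp=0.0,
        )
        b = generate_cohort(cfg)
        xp, _ = preprocess_tables(b.idp_table, b.confounds)
        yp, _ = preprocess_tables(b.nonidp_table, b.confounds)
        an = cca_analysis(xp, yp, d=15, n_perm=499, seed=seed)
        return b, an

    def test_planted_mode_detected_and_loadings_recovered(self):
        ps, loads = [], []
        for seed in range(5):
            b, an = self._run(600 + seed)
            ps.append(an.cca.p_fwe[0])
            est = an.loadings_nonidp["loading"].to_numpy() * b.nonidp_table.polarity
            truth = b.latent_truth.loadings_nonidp[:, 0]
            loads.append(abs(np.corrcoef(est, truth)[0, 1]))
        assert np.median(ps) <= 0.01
        assert np.median(loads) >= 0.8

    def test_sample_size_consistency(self):
        """At n = 5000 the estimated first canonical correlation is within
        0.02 of the planted population value."""
        cfg = small_config(
            seed=77, n_subjects=5000, n_idp=40, n_nonidp=20, rc=0.75,
            missing_rate_nonidp=0.0, confound_effects=(0.0, 0.0, 0.0, 0.0),
        )
        b = generate_cohort(cfg)
        res = fit_cca(
            pca_reduce(b.idp_table, 15).scores, pca_reduce(b.nonidp_table, 15).scores
        )
        assert abs(res.rc[0] - 0.75) < 0.02

    def test_subgroup_congruence(self):
        """Two independent halves from the same generating model give
        congruent mode-1 loadings (median over seeds ≥ 0.6)."""
        phis = []
        for seed in range(7):
            cfg = small_config(
                seed=700 + seed, n_subjects=200, n_idp=40, n_nonidp=20, rc=0.75,
                missing_rate_nonidp=0.0,
            )
            b = generate_cohort(cfg)
            xp, _ = preprocess_tables(b.idp_table, b.confounds)
            yp, _ = preprocess_tables(b.nonidp_table, b.confounds)
            sub = []
            for rows in (slice(0, 100), slice(100, 200)):
                ids = xp.subject_ids[rows]
                an = cca_analysis(
                    xp.select_subjects(ids), yp.select_subjects(ids),
                    d=10, n_perm=0 or 100, seed=seed,
                )
                sub.append(an.loadings_nonidp["loading"].to_numpy())
            phis.append(abs(factor_congruence(sub[0], sub[1])))
        assert np.median(phis) >= 0.6
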