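"""Wild-type reference model: T2/SPE statistics and control limits."""

import numpy as np
import pytest
from scipy import stats

from morphoscreen.outliers import (
    Limits,
    empirical_limits,
    fit_reference,
    flag,
    score,
    score_many,
    theoretical_limits,
)


def brute_force_t2_spe(wt, x, k):
    """Independent oracle: explicit covariance eigendecomposition and
    residual reconstruction (no SVD shortcut)."""
    mean = wt.mean(0)
    sd = wt.std(0, ddof=1)
    Z = (wt - mean) / sd
    C = Z.T @ Z / (len(wt) - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    xs = (x - mean) / sd
    t = xs @ vecs[:, :k]
    t2 = np.sum(t**2 / vals[:k])
    xhat = t @ vecs[:, :k].T
    spe = np.sum((xs - xhat) ** 2)
    return t2, spe


def _wt_sample(rng, n=100, p=8, k_dom=3):
    V = np.linalg.qr(rng.normal(size=(p, k_dom)))[0]
    return rng.normal(size=(n, k_dom)) * [3.0, 2.0, 1.5] @ V.T + 0.3 * rng.normal(size=(n, p))


class TestScore:
    def test_training_mean_scores_zero(self):
        rng = np.random.default_rng(0)
        wt = _wt_sample(rng)
        model = fit_reference(wt)
        t2, spe = score(model, wt.mean(axis=0))
        assert t2 < 1e-20 and spe < 1e-20

    def test_on_plane_point_has_no_spe(self):
        rng = np.random.default_rng(1)
        wt = _wt_sample(rng, n=200)
        model = fit_reference(wt, k_rule=5)
        # move far from the origin strictly inside the retained subspace
        x = model.mean + model.scale * (model.loadings @ (10.0 * np.sqrt(model.eigenvalues[:5])))
        t2, spe = score(model, x)
        assert spe < 1e-18
        assert t2 > model.eigenvalues[:5].size * 10

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        wt = rng.normal(size=(10, 5))
        model = fit_reference(wt, k_rule=2, min_profiles=10)
        for x in rng.normal(size=(6, 5)):
            t2, spe = score(model, x)
            t2_o, spe_o = brute_force_t2_spe(wt, x, 2)
            assert abs(t2 - t2_o) < 1e-10
            assert abs(spe - spe_o) < 1e-10

    def test_sign_flipped_loadings_give_identical_scores(self):
        rng = np.random.default_rng(3)
        wt = _wt_sample(rng)
        model = fit_reference(wt)
        import copy

        flipped = copy.deepcopy(model)
        flipped.loadings = -flipped.loadings
        X = rng.normal(size=(20, wt.shape[1]))
        assert np.allclose(score_many(model, X), score_many(flipped, X))

    def test_wrong_length_rejected(self):
        rng = np.random.default_rng(4)
        model = fit_reference(_wt_sample(rng))
        with pytest.raises(ValueError, match="length"):
            score(model, np.zeros(5))

    def test_spe_non_increasing_in_k(self):
        rng = np.random.default_rng(5)
        wt = _wt_sample(rng, n=150)
        x = rng.normal(size=8)
        spes = [score(fit_reference(wt, k_rule=k), x)[1] for k in range(1, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(spes, spes[1:]))


class TestFitReference:
    def test_planar_data_retains_two_components(self):
        rng = np.random.default_rng(6)
        V = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        wt = rng.normal(size=(200, 2)) * [3.0, 2.0] @ V.T + 0.01 * rng.normal(size=(200, 10))
        model = fit_reference(wt)
        assert model.k == 2

    def test_reference_cohort_size_accepted(self):
        rng = np.random.default_rng(7)
        wt = _wt_sample(rng, n=276, p=18)
        model = fit_reference(wt)
        assert model.n == 276

    def test_too_few_profiles_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match=">= 30"):
            fit_reference(rng.normal(size=(10, 18)))


class TestEmpiricalLimits:
    def test_interpolates_between_top_order_statistics(self):
        rng = np.random.default_rng(9)
        t2 = np.sort(rng.exponential(size=100))
        lim = empirical_limits(t2, t2, percentiles=(99,))
        assert t2[-2] <= lim.t2[99] <= t2[-1]

    def test_all_equal_scores(self):
        lim = empirical_limits(np.full(50, 3.3), np.full(50, 1.1))
        assert lim.t2[99] == 3.3 and lim.spe[99] == 1.1

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="99"):
            empirical_limits(np.arange(20.0), np.arange(20.0), percentiles=(99,))


class TestTheoreticalLimits:
    def test_t2_limit_approaches_chi2_for_large_n(self):
        rng = np.random.default_rng(10)
        wt = _wt_sample(rng, n=5000)
        model = fit_reference(wt, k_rule=1)
        lim = theoretical_limits(model, alpha=0.01)
        assert abs(lim.t2[99.0] - stats.chi2.ppf(0.99, 1)) < 0.05

    def test_spe_weighted_chi2_matches_monte_carlo(self):
        # Gaussian residuals with known eigenvalues: the g*chi2_h quantile
        # approximates the simulated 99th percentile within 10%
        rng = np.random.default_rng(11)
        lam = np.array([0.5, 0.3, 0.1, 0.05])
        resid = rng.normal(size=(50_000, 4)) * np.sqrt(lam)
        spe = np.sum(resid**2, axis=1)
        th1, th2 = lam.sum(), np.sum(lam**2)
        g, h = th2 / th1, th1**2 / th2
        q_theory = g * stats.chi2.ppf(0.99, h)
        q_mc = np.percentile(spe, 99)
        assert abs(q_mc - q_theory) / q_theory < 0.10

    def test_median_limits_at_alpha_half(self):
        rng = np.random.default_rng(12)
        wt = _wt_sample(rng, n=2000, p=8)
        model = fit_reference(wt, k_rule=3)
        lim = theoretical_limits(model, alpha=0.5)
        t2, spe = score_many(model, wt)
        assert abs(np.median(t2) - lim.t2[50.0]) / lim.t2[50.0] < 0.15
        assert abs(np.median(spe) - lim.spe[50.0]) / lim.spe[50.0] < 0.15


class TestFlag:
    def test_score_exactly_at_limit_not_flagged(self):
        lim = Limits(t2={99.0: 2.0}, spe={99.0: 1.0})
        out = flag(np.array([2.0, 2.1]), np.array([1.0, 0.5]), lim)
        assert list(out["flag"]) == ["none", "t2_only"]
        assert list(out["hit"]) == [False, True]

    def test_categories_consistent(self):
        lim = Limits(t2={99.0: 1.0}, spe={99.0: 1.0})
        out = flag(np.array([2.0, 0.5, 2.0, 0.5]), np.array([2.0, 2.0, 0.5, 0.5]), lim)
        assert list(out["flag"]) == ["both", "spe_only", "t2_only", "none"]

    def test_slow_lysis_breaks_correlation_fast_lysis_preserves_it(self):
        """Time-correlation breakers show up in SPE, extreme-but-correlated
        strains in T2 (the interpretation of the two statistics)."""
        from morphoscreen.profiling import batch_correct, build_profiles, summaries_from_counts
        from morphoscreen.synth import simulate_screen

        _, truth = simulate_screen(
            400, 400, 1,
            effect_spec={"slow_lysis": 30, "fast_lysis": 30},
            rng=5, sigma_plate=0.0,
        )
        profs = build_profiles(summaries_from_counts(truth.wells))
        profs = profs.merge(truth.strains[["strain_id", "archetype"]], on="strain_id")
        corr = batch_correct(profs)
        wt = corr[corr.archetype == "wt"]
        model = fit_reference(wt)
        lim = empirical_limits(*score_many(model, wt))
        mut = corr[corr.archetype != "wt"]
        res = flag(*score_many(model, mut), lim, strain_ids=mut["strain_id"].to_numpy())
        res = res.merge(truth.strains, on="strain_id")
        slow = res[res.archetype == "slow_lysis"]
        fast = res[res.archetype == "fast_lysis"]
        # slow lysis: SPE exceedance dominates; fast lysis: mostly T2
        assert (slow.spe > slow.spe_limit).mean() > (slow.t2 > slow.t2_limit).mean() or \
            (slow.flag.isin(["spe_only", "both"])).mean() > 0.5
        assert (fast.flag.isin(["t2_only", "both"])).mean() > (fast.flag == "spe_only").mean()
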