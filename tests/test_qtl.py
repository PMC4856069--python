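"""Mapping statistics: Pillai reductions, scans, thresholds, search, intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shapemapper.genoprob import calc_genoprob, dosage
from shapemapper.qtl import (
    bayes_interval,
    build_design,
    effect_summaries,
    expected_h2,
    fit_covariates,
    forward_backward_search,
    perm_threshold,
    pillai_f,
    plane_decomposition,
    scan,
)
from shapemapper.synthetic import MapSpec, simulate_backcross


def make_covariates(n, rng):
    return pd.DataFrame(
        {
            "logCS": rng.standard_normal(n) * 0.1,
            "sex": rng.integers(0, 2, n),
            "cross_direction": rng.integers(1, 3, n),
        }
    )


@pytest.fixture(scope="module")
def null_setup():
    rng = np.random.default_rng(77)
    cross = simulate_backcross(MapSpec([("1", 80.0), ("2", 80.0)], 10.0), 150, seed=9)
    probs = calc_genoprob(cross, step=0.0)
    covars = make_covariates(150, rng)
    Y = rng.standard_normal((150, 5))
    return Y, covars, probs


class TestPillai:
    def test_q1_reduces_to_univariate_f(self, null_setup):
        """Pillai scan on one phenotype equals the classic F-scan (1e-10)."""
        Y, covars, probs = null_setup
        y1 = Y[:, :1]
        prof = scan(y1, covars, probs)
        X = build_design(covars)
        for chrom in prof.positions:
            for j, pos in enumerate(prof.positions[chrom]):
                x = dosage(probs, chrom, pos)
                Xf = np.column_stack([X, x])
                coef, *_ = np.linalg.lstsq(Xf, y1, rcond=None)
                rss1 = float(((y1 - Xf @ coef) ** 2).sum())
                coef0, *_ = np.linalg.lstsq(X, y1, rcond=None)
                rss0 = float(((y1 - X @ coef0) ** 2).sum())
                df_e = len(y1) - Xf.shape[1]
                F = (rss0 - rss1) / (rss1 / df_e)
                p = stats.f.sf(F, 1, df_e)
                lod = -np.log10(p)
                assert prof.lod[chrom][j] == pytest.approx(lod, abs=1e-10)

    def test_f_approx_formula(self):
        F, df1, df2, p = pillai_f(0.3, q=4, df_h=1, df_e=100)
        assert df1 == 4 and df2 == 97
        assert F == pytest.approx((97 / 4) * 0.3 / 0.7)

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError):
            pillai_f(0.5, q=50, df_h=1, df_e=40)


class TestFitCovariates:
    def test_q1_pillai_equals_univariate(self, rng):
        n = 120
        covars = make_covariates(n, rng)
        y = (
            0.5 * covars["logCS"].to_numpy()
            + 0.3 * covars["sex"].to_numpy()
            + rng.standard_normal(n)
        )[:, None]
        fit = fit_covariates(y, covars)
        import statsmodels.api as sm

        X = build_design(covars)
        for j, term in enumerate(fit.terms, start=1):
            ols = sm.OLS(y, X).fit()
            t = ols.tvalues[j]
            p_uni = ols.pvalues[j]
            assert fit.p[term] == pytest.approx(p_uni, abs=1e-10)

    def test_planted_size_effect_pct_ss(self, rng):
        """A planted allometric effect's %SS is recovered."""
        n, q = 2000, 8
        covars = make_covariates(n, rng)
        direction = rng.standard_normal(q)
        direction /= np.linalg.norm(direction)
        noise = rng.standard_normal((n, q))
        x = covars["logCS"].to_numpy()
        # scale so the size term explains ~5% of total variance
        target = 0.05
        amp = np.sqrt(target / (1 - target) * q / np.var(x))
        Y = np.outer(x, amp * direction) + noise
        fit = fit_covariates(Y, covars)
        assert fit.pct_ss["logCS"] == pytest.approx(5.0, abs=1.5)
        assert fit.p["logCS"] < 1e-10

    def test_interactions_flag_adds_terms(self, rng):
        covars = make_covariates(200, rng)
        Y = rng.standard_normal((200, 4))
        fit = fit_covariates(Y, covars, interactions=True)
        assert "logCS:sex" in fit.terms
        assert all(p > 1e-4 for t, p in fit.p.items() if ":" in t)

    def test_aliased_design_rejected(self, rng):
        covars = make_covariates(50, rng)
        covars["cross_direction"] = covars["sex"] + 1  # perfectly aliased
        with pytest.raises(ValueError):
            fit_covariates(rng.standard_normal((50, 3)), covars)


class TestScan:
    def test_planted_qtl_found_near_truth(self, small_cross):
        from shapemapper.morpho import gpa, pca_reduce

        res = gpa(small_cross.phenotypes)
        pca = pca_reduce(res, 0.99)
        probs = calc_genoprob(small_cross, step=1.0)
        prof = scan(pca.scores, small_cross.covariates, probs)
        chrom, pos, lod = prof.max()
        truth = {(q.chrom, q.pos) for q in small_cross.sim_truth.qtls}
        assert any(c == chrom and abs(p - pos) <= 5.0 for c, p in truth)
        assert lod > 5.0

    def test_fixed_qtl_window_masked(self, null_setup):
        Y, covars, probs = null_setup
        prof = scan(Y, covars, probs, fixed_positions=[("1", 40.0)], window=10.0)
        grid = prof.positions["1"]
        masked = np.abs(grid - 40.0) < 10.0
        assert np.all(np.isnan(prof.lod["1"][masked]))
        assert np.all(np.isfinite(prof.lod["1"][~masked]))
        assert np.all(np.isfinite(prof.lod["2"]))

    def test_too_small_n_reports(self, null_setup):
        _, covars, probs = null_setup
        rng = np.random.default_rng(0)
        Y_wide = rng.standard_normal((150, 148))
        with pytest.raises(ValueError, match="pca_reduce"):
            scan(Y_wide, covars, probs)


class TestPermThreshold:
    def test_alpha_one_gives_minimum(self, null_setup):
        Y, covars, probs = null_setup
        t_min = perm_threshold(Y, covars, probs, n_perm=30, alpha=1.0, seed=3)
        t_05 = perm_threshold(Y, covars, probs, n_perm=30, alpha=0.05, seed=3)
        assert t_min <= t_05

    def test_reproducible_and_order_free(self, null_setup):
        """T is invariant to marker order within chromosomes (max is order-free)."""
        Y, covars, probs = null_setup
        t1 = perm_threshold(Y, covars, probs, n_perm=40, seed=5)
        t2 = perm_threshold(Y, covars, probs, n_perm=40, seed=5)
        assert t1 == t2
        shuffled = type(probs)(
            positions={c: probs.positions[c][::-1] for c in probs.positions},
            prob_ab={c: probs.prob_ab[c][:, ::-1] for c in probs.prob_ab},
            step=probs.step,
            error_prob=probs.error_prob,
        )
        t3 = perm_threshold(Y, covars, shuffled, n_perm=40, seed=5)
        assert t3 == pytest.approx(t1, abs=1e-12)


class TestForwardBackward:
    def test_pure_noise_gives_zero_qtl(self, null_setup):
        Y, covars, probs = null_setup
        T = perm_threshold(Y, covars, probs, n_perm=100, seed=21)
        hits = 0
        rng = np.random.default_rng(31)
        for _ in range(5):
            Ynull = rng.standard_normal(Y.shape)
            fit = forward_backward_search(Ynull, covars, probs, T, max_qtl=5)
            hits += fit.n_qtl > 0
        assert hits <= 1

    def test_recovers_planted_model(self, small_cross):
        from shapemapper.morpho import gpa, pca_reduce

        res = gpa(small_cross.phenotypes)
        pca = pca_reduce(res, 0.99)
        probs = calc_genoprob(small_cross, step=1.0)
        T = perm_threshold(pca.scores, small_cross.covariates, probs, n_perm=100, seed=41)
        fit = forward_backward_search(
            pca.scores, small_cross.covariates, probs, T, max_qtl=6
        )
        truth = [(q.chrom, q.pos) for q in small_cross.sim_truth.qtls]
        assert fit.n_qtl == len(truth)
        for chrom, pos in truth:
            match = [q for q in fit.qtl if q["chrom"] == chrom]
            assert len(match) == 1
            assert match[0]["ci_left"] - 1e-9 <= pos <= match[0]["ci_right"] + 1e-9
        # positions unique per chromosome by at least the refinement window
        for chrom in {c for c, _ in truth}:
            ps = sorted(q["pos"] for q in fit.qtl if q["chrom"] == chrom)
            assert all(b - a >= 10.0 for a, b in itertools.pairwise(ps))
        assert fit.plod == pytest.approx(fit.lod - fit.T * fit.n_qtl)

    def test_explicit_threshold_and_zero_model(self, null_setup):
        Y, covars, probs = null_setup
        fit = forward_backward_search(Y, covars, probs, T=50.0, max_qtl=3)
        assert fit.n_qtl == 0
        assert fit.plod == 0.0 and fit.lod == 0.0
        assert fit.B.shape[0] == 0


class TestBayesInterval:
    def test_delta_profile_single_cell(self):
        pos = np.arange(0.0, 50.0, 1.0)
        lod = np.zeros_like(pos)
        lod[20] = 30.0
        left, peak, right = bayes_interval(pos, lod)
        assert left == peak == right == 20.0

    def test_flat_profile_full_span(self):
        pos = np.arange(0.0, 50.0, 5.0)
        left, peak, right = bayes_interval(pos, np.ones_like(pos))
        assert left == 0.0 and right == 45.0

    def test_matches_brute_force_hpd_enumeration(self):
        """Smallest HPD set on a Gaussian-shaped profile, by direct enumeration."""
        pos = np.arange(0.0, 60.0, 1.0)
        lod = 8.0 * np.exp(-0.5 * ((pos - 25.0) / 6.0) ** 2)
        left, peak, right = bayes_interval(pos, lod, coverage=0.95)

        w = 10.0**lod
        w = w / w.sum()
        best = None
        for size in range(1, len(pos) + 1):
            for subset in itertools.combinations(np.argsort(-w)[: size + 4], size):
                if w[list(subset)].sum() >= 0.95:
                    span = (pos[list(subset)].min(), pos[list(subset)].max())
                    best = span
                    break
            if best:
                break
        assert (left, right) == best
        assert peak == 25.0


class TestEffectStatistics:
    def test_expected_h2_closed_form(self):
        beta = np.zeros(6)
        beta[0] = 1.0
        B = beta[None, :]
        assert expected_h2(beta, B, 0.25 * np.eye(6)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            expected_h2(np.zeros(6), B, np.eye(6))

    def test_plane_decomposition_cases(self, rng):
        k, d = 5, 3
        b = np.zeros((k, d))
        b[:, 2] = 1.0
        assert np.allclose(plane_decomposition(b.ravel(), k, d), [0, 0, 1])
        b = np.ones((k, d))
        assert np.allclose(plane_decomposition(b.ravel(), k, d), [1 / 3] * 3)
        b = rng.standard_normal(k * d)
        assert plane_decomposition(b, k, d).sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            plane_decomposition(np.zeros(k * d), k, d)

    def test_effect_summaries_on_planted_model(self, small_cross):
        from shapemapper.morpho import gpa, pca_reduce

        res = gpa(small_cross.phenotypes)
        pca = pca_reduce(res, 0.99)
        probs = calc_genoprob(small_cross, step=1.0)
        T = perm_threshold(pca.scores, small_cross.covariates, probs, n_perm=100, seed=51)
        fit = forward_backward_search(
            pca.scores, small_cross.covariates, probs, T, max_qtl=6
        )
        summs = effect_summaries(
            fit, pca.scores, probs, covariates=small_cross.covariates
        )
        truth_norm = np.linalg.norm(small_cross.sim_truth.qtls[0].beta)
        for s in summs:
            assert s.norm == pytest.approx(truth_norm, rel=0.25)
            assert 0.0 < s.pct_sst < 5.0
            # directional h2 planted at 0.3
            assert s.expected_h2 == pytest.approx(0.3, abs=0.1)
            assert s.pct_ss_proj == pytest.approx(100 * s.expected_h2, abs=10)
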