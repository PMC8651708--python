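import numpy as np
import pandas as pd
import pytest

import polytrainsel as pts
from _oracles import mme_gblup_oracle, pearson_oracle
from conftest import make_panel


def _split_trait(panel, trait, n_train):
    train = list(panel.genotype_ids[:n_train])
    test = list(panel.genotype_ids[n_train:])
    sub = pts.TraitSet(
        genotype_ids=train,
        values=trait.series().loc[train].to_numpy(),
        trait_name=trait.trait_name,
    )
    return train, test, sub


class TestGBLUP:
    def test_strong_shrinkage_limit_returns_training_mean(self, mid_panel):
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=1)
        train, test, sub = _split_trait(mid_panel, trait, 40)
        fit = pts.gblup_fit_predict(pts.vanraden_A(mid_panel), sub, test, delta=1e9)
        np.testing.assert_allclose(fit.predictions, sub.values.mean(), atol=1e-4)

    def test_matches_mixed_model_equations_oracle(self):
        rng = np.random.default_rng(8)
        b = rng.normal(size=(4, 4))
        a = b @ b.T + 0.5 * np.eye(4)
        rel = pts.RelationshipMatrix(ids=list("wxyz"), A=a)
        y = rng.normal(size=3)
        sub = pts.TraitSet(genotype_ids=list("wxy"), values=y)
        delta = 0.7
        fit = pts.gblup_fit_predict(rel, sub, list("wxyz"), delta=delta)
        beta, preds = mme_gblup_oracle(list("wxyz"), a, list("wxy"), y, list("wxyz"), delta)
        assert fit.intercept == pytest.approx(beta, abs=1e-10)
        np.testing.assert_allclose(fit.predictions.to_numpy(), preds, atol=1e-10)

    def test_equivalent_to_ridge_regression_on_Q(self, rng):
        """GBLUP with A = QQ'/c equals ridge on Q at penalty delta*c."""
        panel = make_panel(rng.integers(0, 5, (10, 50)))
        rel = pts.vanraden_A(panel)
        trait = pts.simulate_trait(panel, 5, 0.8, seed=3)
        train, test, sub = _split_trait(panel, trait, 7)
        delta = 0.9
        fit = pts.gblup_fit_predict(rel, sub, test, delta=delta)
        w = pts.recode_dosage(panel)
        qmat = w - w.mean(axis=0, keepdims=True)
        c = rel.denominator
        qt = qmat[:7]
        resid = sub.values - fit.intercept
        bhat = np.linalg.solve(qt.T @ qt + delta * c * np.eye(50), qt.T @ resid)
        ridge_preds = fit.intercept + qmat[7:] @ bhat
        np.testing.assert_allclose(fit.predictions.to_numpy(), ridge_preds, atol=1e-8)

    def test_reml_ratio_is_profile_maximum(self, mid_panel):
        from polytrainsel.models import _reml_profile

        trait = pts.simulate_trait(mid_panel, 30, 0.7, seed=4)
        train, test, sub = _split_trait(mid_panel, trait, 45)
        rel = pts.vanraden_A(mid_panel)
        fit = pts.gblup_fit_predict(rel, sub, test)
        delta_hat = fit.extras["delta"]
        k = rel.submatrix(train)
        s, u = np.linalg.eigh(k)
        s = np.maximum(s, 0)
        yt, xt = u.T @ sub.values, u.T @ np.ones(len(train))
        ll_hat = _reml_profile(s, yt, xt, delta_hat)[0]
        for d in delta_hat * np.array([0.5, 0.9, 0.99, 1.01, 1.1, 2.0]):
            assert _reml_profile(s, yt, xt, d)[0] <= ll_hat + 1e-7

    def test_zero_variance_phenotype_rejected(self, mid_panel):
        rel = pts.vanraden_A(mid_panel)
        sub = pts.TraitSet(genotype_ids=list(mid_panel.genotype_ids[:10]), values=np.ones(10))
        with pytest.raises(ValueError, match="variance"):
            pts.gblup_fit_predict(rel, sub, list(mid_panel.genotype_ids[10:]))


class TestRKHS:
    def test_kernel_diag_is_one(self, mid_panel):
        from polytrainsel.models import rkhs_distance

        d = rkhs_distance(mid_panel)
        k = np.exp(-d / 0.5)
        np.testing.assert_allclose(np.diag(k), 1.0)

    def test_chosen_theta_maximizes_grid_loglik(self, mid_panel):
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=5)
        train, test, sub = _split_trait(mid_panel, trait, 40)
        grid = [0.1, 0.3, 0.6, 1.0]
        best = pts.rkhs_fit_predict(mid_panel, sub, test, theta_grid=grid)
        for theta in grid:
            single = pts.rkhs_fit_predict(mid_panel, sub, test, theta_grid=[theta])
            assert single.loglik <= best.loglik + 1e-8
        assert best.theta in grid

    def test_frozen_kernel_equals_gblup(self, mid_panel):
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=6)
        train, test, sub = _split_trait(mid_panel, trait, 40)
        rel = pts.vanraden_A(mid_panel)
        g = pts.gblup_fit_predict(rel, sub, test)
        r = pts.rkhs_fit_predict(mid_panel, sub, test, kernel=rel.A)
        np.testing.assert_allclose(r.predictions.to_numpy(), g.predictions.to_numpy(), atol=1e-8)

    def test_empty_grid_rejected(self, mid_panel):
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=7)
        _, test, sub = _split_trait(mid_panel, trait, 40)
        with pytest.raises(ValueError, match="grid"):
            pts.rkhs_fit_predict(mid_panel, sub, test, theta_grid=[])


class TestBayesC:
    def test_same_seed_reproduces_exactly(self, mid_panel):
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=8)
        _, test, sub = _split_trait(mid_panel, trait, 40)
        f1 = pts.bayesc_fit_predict(mid_panel, sub, test, n_iter=300, burn_in=100, seed=5)
        f2 = pts.bayesc_fit_predict(mid_panel, sub, test, n_iter=300, burn_in=100, seed=5)
        np.testing.assert_array_equal(f1.predictions.to_numpy(), f2.predictions.to_numpy())
        assert f1.pi == f2.pi

    def test_pi_fixed_one_degenerates_to_intercept(self, mid_panel):
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=9)
        _, test, sub = _split_trait(mid_panel, trait, 40)
        fit = pts.bayesc_fit_predict(
            mid_panel, sub, test, n_iter=400, burn_in=200, seed=1, pi_fixed=1.0
        )
        np.testing.assert_allclose(fit.predictions.to_numpy(), fit.intercept, atol=1e-12)

    def test_pi_fixed_zero_matches_bayesian_ridge_oracle(self, rng):
        """pi=0 (all markers in) agrees with an independent Gibbs ridge
        sampler within Monte-Carlo error (3 SE over 5 seeds)."""
        panel = make_panel(rng.integers(0, 5, (30, 40)))
        trait = pts.simulate_trait(panel, 8, 0.8, seed=10)
        train, test, sub = _split_trait(panel, trait, 22)
        ours, theirs = [], []
        for s in range(5):
            fit = pts.bayesc_fit_predict(
                panel, sub, test, n_iter=2000, burn_in=500, seed=s, pi_fixed=0.0
            )
            ours.append(fit.predictions.to_numpy())
            theirs.append(
                _gibbs_ridge_oracle(panel, sub, test, n_iter=2000, burn_in=500, seed=100 + s)
            )
        ours, theirs = np.array(ours), np.array(theirs)
        diff = ours.mean(axis=0) - theirs.mean(axis=0)
        se = np.sqrt(ours.var(axis=0, ddof=1) / 5 + theirs.var(axis=0, ddof=1) / 5)
        assert np.all(np.abs(diff) <= 3 * se + 1e-9)

    def test_sigma_e_chain_mixes(self, mid_panel):
        az = pytest.importorskip("arviz")
        trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=11)
        _, test, sub = _split_trait(mid_panel, trait, 40)
        fit = pts.bayesc_fit_predict(mid_panel, sub, test, n_iter=5000, burn_in=2500, seed=2)
        ess = float(az.ess(np.array(fit.extras["sigma_e_trace"])[None, :]))
        assert ess > 50

    def test_constant_phenotype_rejected(self, mid_panel):
        sub = pts.TraitSet(genotype_ids=list(mid_panel.genotype_ids[:10]), values=np.zeros(10))
        with pytest.raises(ValueError, match="constant|variance"):
            pts.bayesc_fit_predict(mid_panel, sub, list(mid_panel.genotype_ids[10:]))


def _gibbs_ridge_oracle(panel, sub, predict_ids, n_iter, burn_in, seed):
    """Plain-numpy Gibbs sampler for y = mu + Wb + e with b ~ N(0, sigma_b^2 I).

    Matches the package's prior settings (df 5, R2 = 0.5 variance split,
    half-marker scaling) but shares no sampling code.
    """
    rng = np.random.default_rng(seed)
    w_full = pts.recode_dosage(panel)
    idx = {g: i for i, g in enumerate(panel.genotype_ids)}
    wt = w_full[[idx[g] for g in sub.genotype_ids]]
    wp = w_full[[idx[g] for g in predict_ids]]
    y = sub.values
    n, p = wt.shape
    df = 5.0
    vy = np.var(y, ddof=1)
    msx = np.sum(np.var(wt, axis=0, ddof=1))
    s_e = vy * 0.5 * (df + 2) / df
    s_b = vy * 0.5 / (0.5 * msx) * (df + 2) / df
    cjj = np.sum(wt**2, axis=0)
    mu, b = y.mean(), np.zeros(p)
    sigma_b, sigma_e = s_b, s_e
    e = y - mu
    b_sum = np.zeros(p)
    mu_sum = 0.0
    for it in range(n_iter):
        mu_new = rng.normal(mu + e.mean(), np.sqrt(sigma_e / n))
        e += mu - mu_new
        mu = mu_new
        for j in range(p):
            z = wt[:, j] @ e + cjj[j] * b[j]
            var_j = sigma_e / (cjj[j] + sigma_e / sigma_b)
            new_bj = rng.normal(var_j * z / sigma_e, np.sqrt(var_j))
            e += wt[:, j] * (b[j] - new_bj)
            b[j] = new_bj
        sigma_b = (b @ b + df * s_b) / rng.chisquare(df + p)
        sigma_e = (e @ e + df * s_e) / rng.chisquare(df + n)
        if it >= burn_in:
            b_sum += b
            mu_sum += mu
    kept = n_iter - burn_in
    return mu_sum / kept + wp @ (b_sum / kept)


@pytest.mark.parametrize("model", ["GBLUP", "RKHS", "BAYESC"])
def test_shift_invariance(model, mid_panel):
    """Adding a constant to y shifts predictions by the same constant."""
    trait = pts.simulate_trait(mid_panel, 10, 0.85, seed=12)
    train, test, sub = _split_trait(mid_panel, trait, 40)
    shifted = pts.TraitSet(genotype_ids=sub.genotype_ids, values=sub.values + 100.0)
    kw = {"n_iter": 300, "burn_in": 100, "seed": 3} if model == "BAYESC" else {}
    rel = pts.vanraden_A(mid_panel)

    def fit(t):
        if model == "GBLUP":
            return pts.gblup_fit_predict(rel, t, test)
        if model == "RKHS":
            return pts.rkhs_fit_predict(mid_panel, t, test, theta_grid=[0.5])
        return pts.bayesc_fit_predict(mid_panel, t, test, **kw)

    base, moved = fit(sub), fit(shifted)
    np.testing.assert_allclose(
        moved.predictions.to_numpy(), base.predictions.to_numpy() + 100.0, atol=1e-6
    )


class TestAccuracy:
    def test_hand_example_matches_formula_oracle(self):
        a = pd.Series([1.0, 2.0, 3.5, 2.2, 0.1], index=list("abcde"))
        b = pd.Series([0.9, 2.4, 3.0, 2.0, 0.4], index=list("abcde"))
        assert pts.accuracy(a, b) == pytest.approx(pearson_oracle(a, b), abs=1e-12)

    def test_perfect_and_inverted(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert pts.accuracy(a, a) == pytest.approx(1.0)
        assert pts.accuracy(a, -a) == pytest.approx(-1.0)

    def test_insufficient_overlap_and_zero_variance(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="overlap"):
            pts.accuracy(a, a)
        b = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        c = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="variance"):
            pts.accuracy(b, c)


def test_sparse_trait_model_ordering(default_panel):
    """Sparse-QTL traits: marker-selection and kernel models beat GBLUP on
    average over replicated 150/40 train/test splits."""
    accs = {"GBLUP": [], "RKHS": [], "BAYESC": []}
    rel = pts.vanraden_A(default_panel)
    ids = list(default_panel.genotype_ids)
    for s in range(10):
        trait = pts.simulate_trait(default_panel, n_qtl=10, h2=0.85, seed=200 + s)
        rng = np.random.default_rng(300 + s)
        perm = rng.permutation(len(ids))
        train = [ids[i] for i in perm[:150]]
        test = [ids[i] for i in perm[150:]]
        sub = pts.TraitSet(genotype_ids=train, values=trait.series().loc[train].to_numpy())
        obs = trait.series()
        g = pts.gblup_fit_predict(rel, sub, test)
        r = pts.rkhs_fit_predict(default_panel, sub, test)
        b = pts.bayesc_fit_predict(default_panel, sub, test, n_iter=1000, burn_in=500, seed=s)
        for name, fit in (("GBLUP", g), ("RKHS", r), ("BAYESC", b)):
            accs[name].append(pts.accuracy(fit.predictions, obs))
    means = {k: float(np.mean(v)) for k, v in accs.items()}
    assert means["BAYESC"] >= means["GBLUP"]
    assert means["RKHS"] >= means["GBLUP"] - 0.02
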