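"""Whole-genome prediction models: GBLUP, RKHS and BayesC-pi.

All three fit the single-random-effect mixed model y = X beta + g + e with
an intercept-only X on the training individuals:

* GBLUP: g ~ N(0, A sigma_g^2) with A the VanRaden genomic relationship
  matrix; variance components by REML via spectral decomposition of the
  training kernel, predictions by the joint-normal conditional mean.
* RKHS: same machinery with the Gaussian kernel K = exp(-D/theta), D a
  (squared) Euclidean distance on recoded dosages normalised by its mean;
  theta chosen on a grid in (0, 1] by maximal restricted log-likelihood.
* BayesC-pi: y = X beta + W b + e with a point-mass/normal mixture prior on
  marker effects b; the zero-effect proportion pi has a uniform prior and
  is estimated from the data by Gibbs sampling.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinship import RelationshipMatrix, recode_dosage
from .panel import DosagePanel, TraitSet

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "GPFit",
    "gblup_fit_predict",
    "rkhs_fit_predict",
    "bayesc_fit_predict",
    "accuracy",
]

DEFAULT_THETA_GRID = np.linspace(0.05, 1.0, 20)


@dataclasses.dataclass
class GPFit:
    """A fitted genomic prediction model with its predictions."""

    model: str
    intercept: float
    predictions: pd.Series  # predicted genotypic values for the requested ids
    var_g: float | None = None
    var_e: float | None = None
    loglik: float | None = None
    theta: float | None = None
    pi: float | None = None
    var_b: float | None = None
    mcmc: dict | None = None
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var_g is not None:
            assert self.var_g >= 0 and (self.var_e is None or self.var_e >= 0)
        if self.pi is not None:
            assert 0 <= self.pi <= 1


# ---------------------------------------------------------------------------
# REML machinery shared by GBLUP and RKHS
# ---------------------------------------------------------------------------

def _reml_profile(s: np.ndarray, yt: np.ndarray, xt: np.ndarray, delta: float):
    """GLS pieces and restricted log-likelihood at variance ratio delta.

    Works in the eigenbasis of the training kernel: s are eigenvalues,
    yt = U'y, xt = U'1.  Profiles sigma_g^2 out; returns (loglik, beta,
    sigma_g^2).
    """
    w = 1.0 / (s + delta)
    xwx = float(xt @ (w * xt))
    beta = float(xt @ (w * yt)) / xwx
    r = yt - xt * beta
    n_p = len(yt) - 1
    sigma_g = float(r @ (w * r)) / n_p
    if sigma_g <= 0:
        return -np.inf, beta, 0.0
    ll = -0.5 * (
        n_p * np.log(sigma_g)
        + np.sum(np.log(s + delta))
        + np.log(xwx)
        + n_p * (1 + np.log(2 * np.pi))
        - np.log(len(yt))
    )
    return ll, beta, sigma_g


def _fit_kernel_reml(
    kernel: np.ndarray,
    ids: list[str],
    trait: TraitSet,
    predict_ids: Sequence[str],
    model_name: str,
    delta: float | None = None,
    theta: float | None = None,
) -> GPFit:
    lookup = {g: i for i, g in enumerate(ids)}
    tr = np.array([lookup[g] for g in trait.genotype_ids])
    y = trait.values
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance in the training set")
    k_tt = kernel[np.ix_(tr, tr)]
    s, u = np.linalg.eigh(k_tt)
    if s[0] < -1e-8 * max(1.0, s[-1]):
        raise ValueError("kernel is not positive semidefinite on the training set")
    s = np.maximum(s, 0.0)
    yt, xt = u.T @ y, u.T @ np.ones(len(y))
    if delta is None:
        res = minimize_scalar(
            lambda t: -_reml_profile(s, yt, xt, np.exp(t))[0],
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
    ll, beta, sigma_g = _reml_profile(s, yt, xt, delta)
    # conditional mean under the joint normal with the full kernel
    alpha = u @ ((u.T @ (y - beta)) / (s + delta))
    pr = np.array([lookup[g] for g in predict_ids])
    preds = beta + kernel[np.ix_(pr, tr)] @ alpha
    return GPFit(
        model=model_name,
        intercept=beta,
        predictions=pd.Series(preds, index=list(predict_ids)),
        var_g=sigma_g,
        var_e=sigma_g * delta,
        loglik=ll,
        theta=theta,
        extras={"delta": delta},
    )


def gblup_fit_predict(
    A: RelationshipMatrix,
    trait: TraitSet,
    predict_ids: Sequence[str],
    delta: float | None = None,
) -> GPFit:
    """GBLUP: REML variance components on the training set, BLUP predictions.

    ``trait`` must be restricted to the training individuals; ``A`` must
    cover training and prediction ids.  ``delta`` fixes the variance ratio
    sigma_e^2/sigma_g^2 instead of estimating it (used by equivalence
    checks).
    """
    return _fit_kernel_reml(A.A, A.ids, trait, predict_ids, "GBLUP", delta=delta)


def rkhs_distance(panel: DosagePanel, squared: bool = True, normalize: bool = True) -> np.ndarray:
    """Distance matrix feeding the Gaussian kernel.

    Squared Euclidean distance on recoded dosages (plain Euclidean with
    ``squared=False``), divided by its off-diagonal mean when ``normalize``
    so a fixed theta grid in (0, 1] is well conditioned across panel sizes.
    """
    w = recode_dosage(panel)
    sq = np.sum(w**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2 * (w @ w.T)
    d = np.maximum(d, 0.0)
    if not squared:
        d = np.sqrt(d)
    np.fill_diagonal(d, 0.0)
    if normalize:
        off = d[np.tril_indices(d.shape[0], k=-1)]
        mean = off.mean() if off.size else 1.0
        if mean > 0:
            d = d / mean
    return 0.5 * (d + d.T)


def rkhs_fit_predict(
    panel: DosagePanel,
    trait: TraitSet,
    predict_ids: Sequence[str],
    theta_grid: Sequence[float] | None = None,
    squared: bool = True,
    normalize: bool = True,
    kernel: np.ndarray | None = None,
) -> GPFit:
    """RKHS regression with a Gaussian kernel and a theta grid search.

    For each theta in the grid, K = exp(-D/theta) replaces the relationship
    matrix in the GBLUP machinery; the theta with the largest restricted
    log-likelihood is returned.  A precomputed ``kernel`` bypasses the grid
    (structural-equivalence checks).
    """
    if kernel is not None:
        return _fit_kernel_reml(kernel, list(panel.genotype_ids), trait, predict_ids, "RKHS")
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(theta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty theta grid")
    d = rkhs_distance(panel, squared=squared, normalize=normalize)
    best: GPFit | None = None
    errors = []
    for theta in grid:
        try:
            fit = _fit_kernel_reml(
                np.exp(-d / theta),
                list(panel.genotype_ids),
                trait,
                predict_ids,
                "RKHS",
                theta=float(theta),
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            errors.append((theta, exc))
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise ValueError(f"all theta grid fits failed: {errors}")
    return best


# ---------------------------------------------------------------------------
# BayesC-pi Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _chi2(df: float) -> float:
    return 2.0 * np.random.gamma(df / 2.0, 1.0)


@njit(cache=True, fastmath=True)
def _beta_draw(a: float, b: float) -> float:
    x = np.random.gamma(a, 1.0)
    y = np.random.gamma(b, 1.0)
    return x / (x + y)


@njit(cache=True, fastmath=True)
def _bayesc_gibbs(
    y, wt, cjj, n_iter, burn_in, df_prior, s_b, s_e, pi_fixed, seed
):  # pragma: no cover - exercised through bayesc_fit_predict
    np.random.seed(seed)
    p, n = wt.shape
    mu = y.mean()
    b = np.zeros(p)
    incl = np.zeros(p, dtype=np.bool_)
    sigma_b = s_b
    sigma_e = s_e
    pi = 0.5 if pi_fixed < 0 else pi_fixed
    e = y - mu
    b_mean = np.zeros(p)
    incl_freq = np.zeros(p)
    mu_sum = 0.0
    pi_sum = 0.0
    sb_sum = 0.0
    se_trace = np.zeros(n_iter - burn_in)
    kept = 0
    for it in range(n_iter):
        # intercept
        mu_new = np.random.normal(mu + e.mean(), np.sqrt(sigma_e / n))
        e += mu - mu_new
        mu = mu_new
        # marker effects with inclusion indicators
        m_in = 0
        ssb = 0.0
        for j in range(p):
            wj = wt[j]
            bj = b[j]
            if incl[j]:
                z = np.dot(wj, e) + cjj[j] * bj
            else:
                z = np.dot(wj, e)
            c = cjj[j]
            v1 = c * sigma_b + sigma_e
            # log Bayes factor of inclusion vs exclusion
            log_bf = 0.5 * (z * z * sigma_b / (sigma_e * v1)) - 0.5 * np.log(v1 / sigma_e)
            if pi >= 1.0:
                prob_in = 0.0
            elif pi <= 0.0:
                prob_in = 1.0
            else:
                log_odds = log_bf + np.log(1.0 - pi) - np.log(pi)
                if log_odds > 35.0:
                    prob_in = 1.0
                elif log_odds < -35.0:
                    prob_in = 0.0
                else:
                    prob_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < prob_in:
                var_j = sigma_e / (c + sigma_e / sigma_b)
                mean_j = var_j * z / sigma_e
                bj_new = np.random.normal(mean_j, np.sqrt(var_j))
                if incl[j]:
                    e += wj * (bj - bj_new)
                else:
                    e -= wj * bj_new
                b[j] = bj_new
                incl[j] = True
                m_in += 1
                ssb += bj_new * bj_new
            else:
                if incl[j]:
                    e += wj * bj
                b[j] = 0.0
                incl[j] = False
        # variance components (scaled-inverse-chi-square conjugate updates)
        sigma_b = (ssb + df_prior * s_b) / _chi2(df_prior + m_in)
        sigma_e = (np.dot(e, e) + df_prior * s_e) / _chi2(df_prior + n)
        if pi_fixed < 0:
            pi = _beta_draw(1.0 + (p - m_in), 1.0 + m_in)
        if it >= burn_in:
            b_mean += b
            for j in range(p):
                if incl[j]:
                    incl_freq[j] += 1.0
            mu_sum += mu
            pi_sum += pi
            sb_sum += sigma_b
            se_trace[kept] = sigma_e
            kept += 1
    n_kept = n_iter - burn_in
    return (
        mu_sum / n_kept,
        b_mean / n_kept,
        incl_freq / n_kept,
        pi_sum / n_kept,
        sb_sum / n_kept,
        se_trace,
    )


def bayesc_fit_predict(
    panel: DosagePanel,
    trait: TraitSet,
    predict_ids: Sequence[str],
    n_iter: int = 5000,
    burn_in: int = 2500,
    seed: int = 0,
    pi_fixed: float | None = None,
    r2_prior: float = 0.5,
    df_prior: float = 5.0,
) -> GPFit:
    """BayesC-pi by Gibbs sampling on recoded markers.

    Priors: scaled-inverse-chi-square on the marker-effect and residual
    variances (df 5, scales set from the phenotypic variance split at
    R2 = ``r2_prior``, assuming half the markers contribute a priori), and
    pi ~ Beta(1, 1) updated from the inclusion counts.  Predictions are the
    intercept plus W times the posterior-mean effects.  ``pi_fixed`` pins
    the mixture weight (1 -> no marker enters, 0 -> a Bayesian ridge).
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if np.var(trait.values) == 0:
        raise ValueError("constant phenotype: BayesC likelihood is degenerate")
    w_full = recode_dosage(panel)
    lookup = {g: i for i, g in enumerate(panel.genotype_ids)}
    tr = np.array([lookup[g] for g in trait.genotype_ids])
    pr = np.array([lookup[g] for g in predict_ids])
    w = np.ascontiguousarray(w_full[tr].T)  # (p, n): marker-major for the Gibbs loop
    y = trait.values.astype(float)
    cjj = np.sum(w**2, axis=1)
    vy = float(np.var(y, ddof=1))
    msx = float(np.sum(np.var(w, axis=1, ddof=1)))
    s_e = vy * (1 - r2_prior) * (df_prior + 2) / df_prior
    s_b = vy * r2_prior / max(0.5 * msx, 1e-12) * (df_prior + 2) / df_prior
    mu, b_mean, incl_freq, pi_mean, sb_mean, se_trace = _bayesc_gibbs(
        y,
        w,
        cjj,
        int(n_iter),
        int(burn_in),
        float(df_prior),
        float(s_b),
        float(s_e),
        -1.0 if pi_fixed is None else float(pi_fixed),
        int(seed) % 2**31,
    )
    preds = mu + w_full[pr] @ b_mean
    return GPFit(
        model="BAYESC",
        intercept=float(mu),
        predictions=pd.Series(preds, index=list(predict_ids)),
        var_e=float(se_trace.mean()),
        var_b=float(sb_mean),
        pi=float(min(max(pi_mean, 0.0), 1.0)),
        mcmc={"n_iter": n_iter, "burn_in": burn_in, "seed": seed},
        extras={"inclusion_freq": incl_freq, "sigma_e_trace": se_trace, "b_mean": b_mean},
    )


def accuracy(predictions: pd.Series, observed: pd.Series) -> float:
    """Pearson correlation between predictions and observed phenotypes.

    Computed over the id overlap; requires at least 3 shared ids and
    nonzero variance on both sides.
    """
    common = predictions.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping ids (need >= 3)")
    a = predictions.loc[common].to_numpy(dtype=float)
    b = observed.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: accuracy undefined")
    return float(np.corrcoef(a, b)[0, 1])
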