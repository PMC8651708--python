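"""Cross-validation schemes for comparing training-set samplers.

Two designs produce accuracy records over methods x sizes x models:

* TV (training-validation): sample a training set of size n from the whole
  panel, fit, and validate on the complementary individuals; repeated
  ``reps`` times per method and size.
* TT (training-test): first hold out a random test set; every sampler then
  draws its training sets from the remaining pool and predicts that common
  test set, so methods are compared on identical targets.  The accuracy of
  one realization is the mean over the sampling repetitions, and the whole
  procedure is repeated over independent test sets.

Accuracies (Pearson r) are variance-stabilised with Fisher's z and the cell
means analysed by a full-factorial fixed-effects ANOVA with Type-I sums of
squares in the order method, size, model, method:size, method:model,
size:model, three-way; size enters as a numeric covariate.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .distances import euclidean_distance, to_similarity
from .kinship import RelationshipMatrix, vanraden_A
from .models import accuracy, bayesc_fit_predict, gblup_fit_predict, rkhs_fit_predict
from .panel import DosagePanel, TraitSet
from .samplers import cdmean_select, gd_sample, srs_sample, stratified_sample

__all__ = [
    "fisher_z",
    "run_tv_scheme",
    "run_tt_scheme",
    "anova_accuracy",
    "TT_TRAIN_SIZE_MENU",
]

RECORD_COLUMNS = [
    "scheme",
    "trait",
    "method",
    "model",
    "train_size",
    "test_size",
    "rep",
    "test_rep",
    "accuracy",
    "fisher_z",
]

TT_TRAIN_SIZE_MENU = {40: (25, 50, 75, 100), 70: (25, 50, 75, 100), 95: (30, 45, 60, 75)}

DEFAULT_CDMEAN_H2 = 0.5


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = float(r)
    if abs(r) >= 1:
        warnings.warn("|r| = 1: Fisher z is infinite", stacklevel=2)
        return float(np.sign(r) * np.inf)
    return float(np.arctanh(r))


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0] % 2**31)


class _SchemeContext:
    """Per-panel inputs shared by every sampling replicate."""

    def __init__(
        self,
        panel: DosagePanel,
        A: RelationshipMatrix | None = None,
        cdmean_kwargs: Mapping | None = None,
        model_kwargs: Mapping[str, Mapping] | None = None,
    ):
        self.panel = panel
        self.A = vanraden_A(panel) if A is None else A
        self.similarity = to_similarity(euclidean_distance(panel))
        self.strata = panel.strata
        # desk-scale search settings for the many replicates of a scheme run;
        # the standalone sampler keeps its larger defaults
        self.cdmean_kwargs = {"max_stall": 300, "n_starts": 1, **(cdmean_kwargs or {})}
        self.model_kwargs = {k.upper(): dict(v) for k, v in (model_kwargs or {}).items()}

    def draw_training(
        self,
        method: str,
        candidates: list[str],
        n: int,
        seed: int,
        target_ids: list[str] | None,
    ) -> list[str]:
        method = method.upper()
        if method == "SRS":
            return srs_sample(candidates, n, seed).training_ids
        if method == "STRAT":
            if self.strata is None:
                raise ValueError("stratified sampling requires stratum labels")
            idx = self.panel.index_of(candidates)
            labels = [str(self.strata[i]) for i in idx]
            return stratified_sample(candidates, labels, n, seed).training_ids
        if method == "GD":
            return gd_sample(self.similarity, candidates, n, seed).training_ids
        if method == "CDMEAN":
            return cdmean_select(
                self.A,
                candidates,
                n,
                h2=DEFAULT_CDMEAN_H2,
                target_ids=target_ids,
                seed=seed,
                **self.cdmean_kwargs,
            ).training_ids
        raise ValueError(f"unknown sampling method {method!r}")

    def fit_predict(
        self, model: str, trait: TraitSet, train_ids: list[str], predict_ids: list[str], seed: int
    ) -> pd.Series:
        model = model.upper()
        sub = TraitSet(
            genotype_ids=train_ids,
            values=trait.series().loc[train_ids].to_numpy(),
            trait_name=trait.trait_name,
            heritability=trait.heritability,
        )
        kw = self.model_kwargs.get(model, {})
        if model == "GBLUP":
            return gblup_fit_predict(self.A, sub, predict_ids, **kw).predictions
        if model == "RKHS":
            return rkhs_fit_predict(self.panel, sub, predict_ids, **kw).predictions
        if model == "BAYESC":
            kw = {"n_iter": 1000, "burn_in": 500, **kw}
            return bayesc_fit_predict(self.panel, sub, predict_ids, seed=seed, **kw).predictions
        raise ValueError(f"unknown model {model!r}")


def _record(scheme, trait, method, model, n_train, n_test, rep, test_rep, r):
    return {
        "scheme": scheme,
        "trait": trait,
        "method": method,
        "model": model,
        "train_size": n_train,
        "test_size": n_test,
        "rep": rep,
        "test_rep": test_rep,
        "accuracy": r,
        "fisher_z": fisher_z(r) if np.isfinite(r) else np.nan,
    }


def run_tv_scheme(
    panel: DosagePanel,
    traits: Sequence[TraitSet],
    methods: Sequence[str] = ("SRS", "STRAT", "GD", "CDMEAN"),
    models: Sequence[str] = ("GBLUP", "RKHS", "BAYESC"),
    sizes: Sequence[int] = (50, 75, 100, 125, 150),
    reps: int = 100,
    seed: int = 0,
    cdmean_kwargs: Mapping | None = None,
    model_kwargs: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Training-validation scheme: train on n, validate on the complement.

    Sampler inputs (relationship matrix, similarity matrix, strata) are
    computed once per panel.  Replicates are seeded by a counter-based
    scheme, so results do not depend on execution order.
    """
    if max(sizes) >= panel.n_individuals:
        raise ValueError("training sizes must be smaller than the panel")
    ctx = _SchemeContext(panel, cdmean_kwargs=cdmean_kwargs, model_kwargs=model_kwargs)
    all_ids = list(panel.genotype_ids)
    rows = []
    for ti, trait in enumerate(traits):
        obs = trait.series()
        for mi, method in enumerate(methods):
            for n in sizes:
                for rep in range(reps):
                    s = _child_seed(seed, 11, ti, mi, n, rep)
                    train = ctx.draw_training(method, all_ids, n, s, target_ids=None)
                    valid = [g for g in all_ids if g not in set(train)]
                    for model in models:
                        try:
                            preds = ctx.fit_predict(model, trait, train, valid, seed=s)
                            r = accuracy(preds, obs)
                        except ValueError as exc:
                            warnings.warn(
                                f"undefined accuracy for {method}/{model}/n={n}: {exc}",
                                stacklevel=2,
                            )
                            r = np.nan
                        rows.append(
                            _record("TV", trait.trait_name, method.upper(), model.upper(),
                                    n, len(valid), rep, None, r)
                        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_tt_scheme(
    panel: DosagePanel,
    traits: Sequence[TraitSet],
    methods: Sequence[str] = ("SRS", "STRAT", "GD", "CDMEAN"),
    models: Sequence[str] = ("GBLUP", "RKHS", "BAYESC"),
    test_size: int = 40,
    train_sizes: Sequence[int] | None = None,
    n_test_sets: int = 50,
    n_sampling_reps: int = 50,
    seed: int = 0,
    cdmean_kwargs: Mapping | None = None,
    model_kwargs: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Training-test scheme: an independent common test set per realization.

    Each record is one realization: the mean accuracy over
    ``n_sampling_reps`` training draws for one (trait, method, size, model,
    test set).  CDmean uses targeted contrasts on the held-out test set.
    """
    if train_sizes is None:
        train_sizes = TT_TRAIN_SIZE_MENU.get(test_size, (25, 50, 75, 100))
    if test_size in TT_TRAIN_SIZE_MENU:
        allowed = set(TT_TRAIN_SIZE_MENU[test_size])
        if not set(train_sizes).issubset(allowed):
            raise ValueError(
                f"test size {test_size} admits train sizes {sorted(allowed)}, "
                f"got {sorted(set(train_sizes) - allowed)}"
            )
    if test_size + max(train_sizes) > panel.n_individuals:
        raise ValueError("test size plus largest training size exceeds the panel")
    ctx = _SchemeContext(panel, cdmean_kwargs=cdmean_kwargs, model_kwargs=model_kwargs)
    all_ids = list(panel.genotype_ids)
    rows = []
    for trep in range(n_test_sets):
        test_ids = srs_sample(all_ids, test_size, _child_seed(seed, 21, trep)).training_ids
        pool = [g for g in all_ids if g not in set(test_ids)]
        for ti, trait in enumerate(traits):
            obs = trait.series()
            for mi, method in enumerate(methods):
                for n in train_sizes:
                    acc: dict[str, list[float]] = {m.upper(): [] for m in models}
                    for rep in range(n_sampling_reps):
                        s = _child_seed(seed, 22, trep, ti, mi, n, rep)
                        train = ctx.draw_training(method, pool, n, s, target_ids=test_ids)
                        for model in models:
                            try:
                                preds = ctx.fit_predict(model, trait, train, test_ids, seed=s)
                                acc[model.upper()].append(accuracy(preds, obs))
                            except ValueError as exc:
                                warnings.warn(
                                    f"undefined accuracy for {method}/{model}/n={n}: {exc}",
                                    stacklevel=2,
                                )
                    for model in models:
                        vals = acc[model.upper()]
                        r = float(np.mean(vals)) if vals else np.nan
                        rows.append(
                            _record("TT", trait.trait_name, method.upper(), model.upper(),
                                    n, test_size, None, trep, r)
                        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def anova_accuracy(records: pd.DataFrame, typ: int = 1) -> pd.DataFrame:
    """Full-factorial ANOVA of Fisher-z cell means.

    The response is the Fisher z of the mean accuracy of each
    (method, size, model) cell; size is a numeric covariate, method and
    model are factors.  Requires a complete grid and a single trait.
    Type-I sums of squares in the printed term order by default
    (``typ=2`` for Type-II).
    """
    if records["trait"].nunique() > 1:
        raise ValueError("anova_accuracy expects records for a single trait")
    cells = (
        records.groupby(["method", "train_size", "model"], as_index=False)["accuracy"]
        .mean()
    )
    methods = sorted(records["method"].unique())
    sizes = sorted(records["train_size"].unique())
    models = sorted(records["model"].unique())
    expected = {(a, b, c) for a in methods for b in sizes for c in models}
    present = {tuple(r) for r in cells[["method", "train_size", "model"]].itertuples(index=False)}
    missing = expected - present
    if missing or cells["accuracy"].isna().any():
        raise ValueError(f"incomplete method x size x model grid; missing cells: {sorted(missing)}")
    cells = cells.assign(
        z=cells["accuracy"].map(fisher_z),
        size=cells["train_size"].astype(float),
    )
    terms = [
        ("method", "C(method)"),
        ("size", "size"),
        ("model", "C(model)"),
        ("method:size", "C(method):size"),
        ("method:model", "C(method):C(model)"),
        ("size:model", "size:C(model)"),
        ("method:size:model", "C(method):size:C(model)"),
    ]
    if typ == 1:
        # sequential (Type-I) sums of squares in exactly the printed term
        # order; patsy would otherwise regroup numeric-covariate terms
        rows = []
        prev = smf.ols("z ~ 1", data=cells).fit()
        rhs = "1"
        for name, term in terms:
            rhs = f"{rhs} + {term}"
            fit = smf.ols(f"z ~ {rhs}", data=cells).fit()
            rows.append(
                {
                    "term": name,
                    "df": int(prev.df_resid - fit.df_resid),
                    "sum_sq": float(prev.ssr - fit.ssr),
                }
            )
            prev = fit
        resid_df = int(prev.df_resid)
        resid_ss = float(prev.ssr)
        ms_resid = resid_ss / resid_df if resid_df else np.nan
        for row in rows:
            row["mean_sq"] = row["sum_sq"] / row["df"]
            row["F"] = row["mean_sq"] / ms_resid
            row["PR(>F)"] = float(stats.f.sf(row["F"], row["df"], resid_df))
        rows.append(
            {
                "term": "residual", "df": resid_df, "sum_sq": resid_ss,
                "mean_sq": ms_resid, "F": np.nan, "PR(>F)": np.nan,
            }
        )
        return pd.DataFrame(rows, columns=["term", "df", "sum_sq", "mean_sq", "F", "PR(>F)"])
    formula = "z ~ " + " + ".join(t for _, t in terms)
    fit = smf.ols(formula, data=cells).fit()
    table = sm.stats.anova_lm(fit, typ=typ)
    pretty = {t: name for name, t in terms}
    pretty["Residual"] = "residual"
    out = table.rename(index=pretty).reset_index(names="term")
    out["df"] = out["df"].astype(int)
    out["mean_sq"] = out["sum_sq"] / out["df"]
    return out[["term", "df", "sum_sq", "mean_sq", "F", "PR(>F)"]]
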