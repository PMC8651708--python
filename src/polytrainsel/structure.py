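"""Population-structure summaries: AMOVA variance fractions, pairwise Fst, PCA.

AMOVA partitions marker variance among and within predefined groups
(strata) and reports the among-group variance-component fraction
sigma2_among / (sigma2_among + sigma2_within), using the standard
unequal-group-size coefficient n0.  Two unit codings are supported:

* ``unit="allele"`` (default): each individual contributes its q allele
  copies as Bernoulli units.  Under the Balding-Nichols generator this
  fraction estimates the differentiation parameter F directly, and the
  pairwise two-group version (Phi-statistic) recovers the pairwise Fst.
* ``unit="dosage"``: individuals are the units, with their dosage vectors;
  this is the squared-Euclidean-distance AMOVA on genotypes.  Binomial
  within-individual sampling then sits in the within-group component, which
  inflates the among fraction to roughly qF/(qF + 1 - F) relative to F.

A frequency-based Hudson-style Fst estimator is available as an
alternative to the Phi-statistic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .panel import DosagePanel

__all__ = [
    "StructureReport",
    "amova_between_fraction",
    "pairwise_fst",
    "pca_scores",
    "structure_report",
]


@dataclasses.dataclass
class StructureReport:
    between_fraction: float
    strata: list[str]
    pairwise_fst: np.ndarray
    pc_variance: np.ndarray

    def __post_init__(self) -> None:
        assert -0.05 <= self.between_fraction <= 1.0
        assert float(np.sum(self.pc_variance)) <= 1.0 + 1e-9

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "between_fraction": self.between_fraction,
                    "strata": self.strata,
                    "pairwise_fst": self.pairwise_fst.tolist(),
                    "pc_variance": self.pc_variance.tolist(),
                },
                indent=2,
            )
        )


def _group_summaries(
    panel: DosagePanel, strata: np.ndarray, unit: str
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per-group, per-marker unit counts, sums and sums of squares."""
    d = panel.dosage_float()
    labels = [str(s) for s in np.unique(strata)]
    counts, sums, sqsums = [], [], []
    for lab in labels:
        rows = np.asarray([str(s) for s in strata]) == lab
        dg = d[rows]
        obs = ~np.isnan(dg)
        s = np.nansum(dg, axis=0)
        if unit == "allele":
            counts.append(obs.sum(axis=0) * panel.ploidy)
            sums.append(s)
            sqsums.append(s)  # Bernoulli units: x^2 = x
        elif unit == "dosage":
            counts.append(obs.sum(axis=0).astype(float))
            sums.append(s)
            sqsums.append(np.nansum(dg**2, axis=0))
        else:
            raise ValueError(f"unknown unit {unit!r}")
    return counts, sums, sqsums


def _amova_fraction(
    counts: list[np.ndarray], sums: list[np.ndarray], sqsums: list[np.ndarray]
) -> float:
    """Among-group variance fraction from per-group marker summaries."""
    g = len(counts)
    n_units = np.vstack(counts)  # (g, m)
    s = np.vstack(sums)
    ss = np.vstack(sqsums)
    n_tot = n_units.sum(axis=0)
    ok = n_tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        grand = s.sum(axis=0)
        ss_total = ss.sum(axis=0) - grand**2 / n_tot
        ss_within = (ss - np.where(n_units > 0, s**2 / np.maximum(n_units, 1), 0.0)).sum(axis=0)
    ss_among = ss_total - ss_within
    df_among = float(ok.sum()) * (g - 1)
    df_within = float((n_tot - g)[ok].sum())
    if df_within <= 0:
        raise ValueError("every stratum must contain at least 2 units")
    ms_among = ss_among[ok].sum() / df_among
    ms_within = ss_within[ok].sum() / df_within
    # unequal-size coefficient, averaged over markers
    with np.errstate(divide="ignore", invalid="ignore"):
        n0 = (n_tot - (n_units**2).sum(axis=0) / n_tot)[ok].mean() / (g - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n0
    total = sigma_a + sigma_w
    if total <= 0:
        return 0.0
    return float(sigma_a / total)


def _check_strata(panel: DosagePanel, strata: np.ndarray | None) -> np.ndarray:
    if strata is None:
        strata = panel.strata
    if strata is None:
        raise ValueError("no stratum labels available")
    strata = np.asarray([str(s) for s in strata])
    if strata.shape[0] != panel.n_individuals:
        raise ValueError("strata length mismatch")
    labs, cnt = np.unique(strata, return_counts=True)
    if len(labs) < 2:
        raise ValueError("need at least 2 strata")
    if cnt.min() < 2:
        raise ValueError(f"stratum {labs[np.argmin(cnt)]!r} has fewer than 2 individuals")
    return strata


def amova_between_fraction(
    panel: DosagePanel, strata: np.ndarray | None = None, unit: str = "allele"
) -> float:
    """Among-group fraction of molecular variance for the given strata."""
    strata = _check_strata(panel, strata)
    return _amova_fraction(*_group_summaries(panel, strata, unit))


def pairwise_fst(
    panel: DosagePanel,
    strata: np.ndarray | None = None,
    method: str = "phi",
    unit: str = "allele",
) -> tuple[list[str], np.ndarray]:
    """Pairwise differentiation between strata; diagonal 0.

    ``method="phi"`` (default) runs a two-group AMOVA per pair and reports
    the Phi-statistic; ``method="hudson"`` uses the frequency-based Hudson
    estimator (ratio of averages over markers).
    """
    strata = _check_strata(panel, strata)
    labels = [str(s) for s in np.unique(strata)]
    g = len(labels)
    out = np.zeros((g, g))
    counts, sums, sqsums = _group_summaries(panel, strata, unit)
    d = panel.dosage_float()
    for a in range(g):
        for b in range(a + 1, g):
            if method == "phi":
                val = _amova_fraction(
                    [counts[a], counts[b]], [sums[a], sums[b]], [sqsums[a], sqsums[b]]
                )
            elif method == "hudson":
                val = _hudson_fst(panel, d, strata, labels[a], labels[b])
            else:
                raise ValueError(f"unknown method {method!r}")
            out[a, b] = out[b, a] = val
    return labels, out


def _hudson_fst(
    panel: DosagePanel, d: np.ndarray, strata: np.ndarray, la: str, lb: str
) -> float:
    q = panel.ploidy
    num_t = den_t = 0.0
    for j in range(panel.n_markers):
        col = d[:, j]
        pa_obs = col[(strata == la) & ~np.isnan(col)]
        pb_obs = col[(strata == lb) & ~np.isnan(col)]
        n1, n2 = len(pa_obs) * q, len(pb_obs) * q
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = pa_obs.sum() / n1, pb_obs.sum() / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num_t += num
        den_t += den
    return num_t / den_t if den_t > 0 else 0.0


def pca_scores(
    panel: DosagePanel, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Principal component scores of the centered (mean-imputed) dosage matrix.

    Returns ``(scores, pc_variance)`` where ``pc_variance`` is the fraction
    of total variance explained by each returned component (non-increasing).
    """
    d = panel.dosage_float()
    col_means = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_means[None, :], d) - col_means[None, :]
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    frac = s**2 / np.sum(s**2)
    scores = u[:, :n_components] * s[:n_components]
    return scores, frac[:n_components]


def structure_report(
    panel: DosagePanel,
    strata: np.ndarray | None = None,
    n_components: int = 10,
    unit: str = "allele",
) -> StructureReport:
    strata_arr = _check_strata(panel, strata)
    labels, fst = pairwise_fst(panel, strata_arr, unit=unit)
    _, pcv = pca_scores(panel, n_components)
    return StructureReport(
        between_fraction=amova_between_fraction(panel, strata_arr, unit=unit),
        strata=labels,
        pairwise_fst=fst,
        pc_variance=pcv,
    )
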