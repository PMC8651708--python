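"""VanRaden additive genomic relationship matrix for dosage data.

Dosages d in {0..q} are recoded to W = (d - q/2)/(q/2), so for tetraploids
{0,1,2,3,4} -> {-1,-0.5,0,0.5,1}.  With p_j the reference-allele frequency
of marker j, the centered matrix is Q_ij = W_ij - (1 - 2 p_j) and

    A = Q Q' / (2 * sum_j p_j (1 - p_j)).

The column mean of W is exactly 1 - 2 p_j when p_j is estimated from the
same panel, so Q is the column-centered recode, column means of Q are zero
and A 1 ~ 0.  (Equivalently, Q = W_ref + 1 - 2 p_j with W_ref the recode of
reference-allele dosage; the two codings differ only by a sign flip of Q's
columns and give the same A.)  Missing dosages are
mean-imputed in W here (kinship and genomic prediction only; the distance
measures use pairwise deletion instead), which keeps A positive
semidefinite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .panel import DosagePanel

__all__ = ["RelationshipMatrix", "recode_dosage", "vanraden_A"]


@dataclasses.dataclass
class RelationshipMatrix:
    """Additive realized genomic relationship matrix with its provenance."""

    ids: list[str]
    A: np.ndarray
    ref_allele_freq: np.ndarray | None = None  # p_j used in the centering
    denominator: float | None = None  # 2 * sum p_j (1 - p_j)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("A shape does not match ids")
        if np.max(np.abs(self.A - self.A.T)) > 1e-10:
            raise ValueError("A must be symmetric")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.ids)}
        idx = np.array([lookup[g] for g in ids])
        return self.A[np.ix_(idx, idx)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.A)[0])


def recode_dosage(panel: DosagePanel) -> np.ndarray:
    """Recode dosages to W = (d - q/2)/(q/2); missing entries -> marker mean of W."""
    q = panel.ploidy
    w = (panel.dosage_float() - q / 2) / (q / 2)
    col_means = np.nanmean(w, axis=0)
    return np.where(np.isnan(w), col_means[None, :], w)


def vanraden_A(panel: DosagePanel, ref_allele_freq: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden A from a dosage panel.

    ``ref_allele_freq`` defaults to the panel estimate
    p_j = 1 - mean(dosage_j)/q.  Requires at least two polymorphic markers;
    an all-monomorphic panel has a zero denominator and is rejected.
    """
    w = recode_dosage(panel)
    d = panel.dosage_float()
    n_poly = int(np.sum(np.nanmax(d, axis=0) > np.nanmin(d, axis=0)))
    if n_poly < 2:
        raise ValueError(f"need >= 2 polymorphic markers, found {n_poly}")
    if ref_allele_freq is None:
        p = 1.0 - panel.allele_frequencies()
    else:
        p = np.asarray(ref_allele_freq, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("zero VanRaden denominator: no polymorphic markers")
    qmat = w - (1.0 - 2.0 * p[None, :])
    a = qmat @ qmat.T / denom
    a = 0.5 * (a + a.T)
    return RelationshipMatrix(
        ids=list(panel.genotype_ids),
        A=a,
        ref_allele_freq=p,
        denominator=denom,
    )
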