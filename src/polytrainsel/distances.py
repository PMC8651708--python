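"""Pairwise genetic distance / similarity measures on allele dosages.

Four measures suited to biallelic dosage data in polyploids:

* Nei's genetic distance (infinite-alleles model, on per-locus allele
  proportions),
* Euclidean distance on raw dosages (purely geometric),
* Jaccard index (intersection over union of alternate-allele counts),
* Kosman-Leonard similarity (shared allele copies out of ploidy q).

Each measure returns a :class:`PairMatrix` that knows whether it is a
distance (zero diagonal) or a similarity (unit diagonal, entries in [0, 1]).
Distances convert to similarities via :func:`to_similarity`, matching what a
radial-exclusion sampler expects as input.  Matrices are compared with a
Mantel permutation test.

Missing dosages are handled by pairwise deletion: each pair uses its shared
non-missing markers, with sums renormalised by the effective marker count so
measures remain comparable across pairs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .panel import DosagePanel

__all__ = [
    "PairMatrix",
    "nei_distance",
    "euclidean_distance",
    "jaccard_similarity",
    "kosman_leonard_similarity",
    "to_similarity",
    "mantel_correlation",
]

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-12


@dataclasses.dataclass
class PairMatrix:
    """Square symmetric matrix over individuals: a distance or a similarity.

    ``pair_counts`` records the effective number of markers behind each
    entry (missing-data bookkeeping); with complete data it is constant.
    """

    ids: list[str]
    values: np.ndarray
    role: str  # "distance" | "similarity"
    measure: str = ""
    pair_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if self.role not in ("distance", "similarity"):
            raise ValueError(f"unknown role {self.role!r}")
        finite = np.isfinite(self.values)
        asym = np.abs(self.values - self.values.T)
        if np.nanmax(np.where(finite & finite.T, asym, 0.0)) > SYMMETRY_TOL:
            raise ValueError("matrix is not symmetric")
        diag = np.diag(self.values)
        if self.role == "distance":
            if np.any(diag != 0) or np.any(self.values[finite] < 0):
                raise ValueError("distance matrix must have zero diagonal, entries >= 0")
        else:
            if np.max(np.abs(diag - 1)) > 1e-9:
                raise ValueError("similarity matrix must have unit diagonal")
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError("similarity entries must lie in [0, 1]")
            self.values = np.clip(self.values, 0.0, 1.0)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        return self.values[np.tril_indices(len(self.ids), k=-1)]


def _pairwise_setup(panel: DosagePanel) -> tuple[np.ndarray, np.ndarray]:
    d = panel.dosages.astype(float)
    obs = (~panel.missing).astype(float)
    return d * obs, obs  # masked dosages, observation indicator


def _shared_counts(obs: np.ndarray) -> np.ndarray:
    return obs @ obs.T


def nei_distance(panel: DosagePanel) -> PairMatrix:
    """Nei's distance on per-locus allele proportions p = dosage/q.

    Uses the single global ratio over loci (not a per-locus average):
    D_XY = -ln( sum_j sum_i p_ij,x p_ij,y / sqrt(sum_j sum_i p_ij,x^2 *
    sum_j sum_i p_ij,y^2) ) with the allele sum over the alternate allele
    (p) and the reference allele (1 - p).  Orthogonal profiles give a zero
    numerator and are reported as +inf.
    """
    q = panel.ploidy
    dm, obs = _pairwise_setup(panel)
    p = dm / q  # alt-allele proportion, zeroed where missing
    pref = (1.0 - panel.dosages / q) * obs  # reference proportion, zeroed where missing
    # cross terms restricted to markers observed in both individuals
    num = p @ p.T + pref @ pref.T
    sq = p**2 + pref**2  # per-individual, per-marker squared proportions
    # sum of squares over markers shared with the partner
    sx = sq @ obs.T  # (i, k): sum over markers observed in both
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / np.sqrt(sx * sx.T)
        ratio = np.clip(ratio, 0.0, 1.0)
        dist = -np.log(ratio)
    np.fill_diagonal(dist, 0.0)
    dist = np.where(np.isfinite(dist) | np.isinf(dist), dist, np.inf)
    dist = 0.5 * (dist + dist.T)
    return PairMatrix(
        ids=list(panel.genotype_ids),
        values=dist,
        role="distance",
        measure="nei",
        pair_counts=_shared_counts(obs),
    )


def euclidean_distance(panel: DosagePanel) -> PairMatrix:
    """Euclidean distance on raw dosages, D_XY = sqrt(sum_j (X_j - Y_j)^2).

    No centering or scaling.  With missing data the sum runs over shared
    non-missing markers and is rescaled by r / r_effective so distances stay
    on the all-marker scale; a pair with no shared markers is an error.
    """
    dm, obs = _pairwise_setup(panel)
    shared = _shared_counts(obs)
    if np.any(shared == 0):
        i, k = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"individuals '{panel.genotype_ids[i]}' and '{panel.genotype_ids[k]}' "
            "share no non-missing markers"
        )
    # sum over shared markers of (x - y)^2, via masked expansion
    x2 = (dm**2) @ obs.T
    cross = dm @ dm.T
    ss = x2 + x2.T - 2 * cross
    ss = np.maximum(ss, 0.0)
    r = panel.n_markers
    dist = np.sqrt(ss * (r / shared))
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    return PairMatrix(
        ids=list(panel.genotype_ids),
        values=dist,
        role="distance",
        measure="euclidean",
        pair_counts=shared,
    )


def jaccard_similarity(panel: DosagePanel, complement: bool = False) -> PairMatrix:
    """Jaccard index on alternate-allele counts, as a ratio of sums.

    S_XY = sum_j min(X_j, Y_j) / sum_j max(X_j, Y_j) over shared non-missing
    markers (the union term is capped at q per marker by construction).  The
    formula is already a similarity, so by default no further transform is
    applied; ``complement=True`` instead treats the ratio as if it were a
    distance and returns 1 - S_XY (the alternative reading).  A pair of
    all-reference-homozygote profiles (denominator 0) is defined as
    similarity 1 and logged.
    """
    n = panel.n_individuals
    d = panel.dosage_float()
    vals = np.ones((n, n))
    counts = np.zeros((n, n))
    for i in range(n):
        xi = d[i]
        both = ~np.isnan(xi)[None, :] & ~np.isnan(d)
        mn = np.where(both, np.minimum(xi[None, :], d), 0.0).sum(axis=1)
        mx = np.where(both, np.maximum(xi[None, :], d), 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(mx > 0, mn / np.where(mx > 0, mx, 1.0), 1.0)
        if np.any(mx == 0):
            logger.info("jaccard: pair(s) with all-zero union treated as similarity 1")
        vals[i] = s
        counts[i] = both.sum(axis=1)
    np.fill_diagonal(vals, 1.0)
    vals = 0.5 * (vals + vals.T)
    if complement:
        vals = 1.0 - vals
        np.fill_diagonal(vals, 1.0)
    return PairMatrix(
        ids=list(panel.genotype_ids),
        values=np.clip(vals, 0.0, 1.0),
        role="similarity",
        measure="jaccard_complement" if complement else "jaccard",
        pair_counts=counts,
    )


def kosman_leonard_similarity(panel: DosagePanel) -> PairMatrix:
    """Kosman-Leonard similarity: shared allele copies out of ploidy q.

    Shared copies at marker j are min(X_j, Y_j) + min(q - X_j, q - Y_j)
    (alternate plus reference copies), averaged over shared non-missing
    markers: S_XY = (1/r) sum_j shared_j / q.  For biallelic markers this
    equals 1 - Manhattan(X, Y)/(q r).
    """
    q = panel.ploidy
    n = panel.n_individuals
    d = panel.dosage_float()
    vals = np.ones((n, n))
    counts = np.zeros((n, n))
    for i in range(n):
        xi = d[i]
        both = ~np.isnan(xi)[None, :] & ~np.isnan(d)
        shared = np.minimum(xi[None, :], d) + np.minimum(q - xi[None, :], q - d)
        tot = np.where(both, shared, 0.0).sum(axis=1)
        r_eff = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[i] = np.where(r_eff > 0, tot / (q * np.maximum(r_eff, 1)), np.nan)
        counts[i] = r_eff
    np.fill_diagonal(vals, 1.0)
    vals = 0.5 * (vals + vals.T)
    return PairMatrix(
        ids=list(panel.genotype_ids),
        values=np.clip(vals, 0.0, 1.0),
        role="similarity",
        measure="kosman_leonard",
        pair_counts=counts,
    )


def to_similarity(m: PairMatrix) -> PairMatrix:
    """Convert a distance matrix to the similarity form samplers expect.

    Euclidean distances map through 1 - D/max(D); Nei (and any other
    unbounded measure) through clamp(1 - D, 0, 1), with +inf mapping to 0.
    Similarity inputs are returned unchanged.  An all-zero distance matrix
    maps to the identity-like all-ones similarity (logged).
    """
    if m.role == "similarity":
        return m
    d = m.values
    if m.measure == "euclidean":
        finite = d[np.isfinite(d)]
        dmax = finite.max() if finite.size else 0.0
        if dmax == 0:
            logger.info("to_similarity: all-zero distance matrix; returning all-ones")
            s = np.ones_like(d)
        else:
            s = 1.0 - d / dmax
    else:
        s = np.where(np.isinf(d), 0.0, np.clip(1.0 - d, 0.0, 1.0))
    np.fill_diagonal(s, 1.0)
    return PairMatrix(
        ids=list(m.ids),
        values=np.clip(s, 0.0, 1.0),
        role="similarity",
        measure=m.measure,
        pair_counts=m.pair_counts,
    )


def _as_distance_values(m: PairMatrix) -> np.ndarray:
    return 1.0 - m.values if m.role == "similarity" else m.values


def mantel_correlation(
    a: PairMatrix,
    b: PairMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two pairwise matrices over the same individuals.

    Both matrices are harmonised to the distance role (similarities via
    1 - S).  Returns the Pearson correlation of strictly-lower-triangle
    entries and a permutation p-value over random joint row/column
    permutations of one matrix, with the identity permutation counted so
    p > 0 always: p = #{|r_perm| >= |r_obs|, incl. identity} / (n_perm + 1).
    """
    if a.ids != b.ids:
        raise ValueError("matrices must be over the same ids in the same order")
    da, db = _as_distance_values(a), _as_distance_values(b)
    if not (np.isfinite(da).all() and np.isfinite(db).all()):
        raise ValueError("Mantel test requires finite matrices")
    n = len(a.ids)
    tril = np.tril_indices(n, k=-1)
    va, vb = da[tril], db[tril]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant lower triangle: Mantel correlation undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    vb_c = vb - vb.mean()
    denom = np.sqrt((va - va.mean()) @ (va - va.mean()) * (vb_c @ vb_c))
    hits = 1  # identity permutation
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = db[np.ix_(perm, perm)][tril]
        dp_c = dp - dp.mean()
        r_perm = float((va - va.mean()) @ dp_c / denom)
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, hits / (n_perm + 1)
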