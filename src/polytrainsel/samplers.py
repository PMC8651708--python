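"""Training-set construction: SRS, stratified, genetic-distance, CDmean.

Four samplers produce a :class:`SampleDesign` of exactly ``n`` training
individuals from a candidate pool:

* simple random sampling (every candidate equally likely),
* stratified random sampling with proportional allocation
  n_S = (n/N) * N_S, reconciled to the total by largest remainder,
* genetic-distance sampling: random draws with radial exclusion -- after
  each pick, every remaining candidate within distance r of it is discarded
  (core-collection style); r is tuned so the realized sample size matches n,
* CDmean: stochastic exchange search maximizing the mean generalized
  coefficient of determination of contrasts between unphenotyped
  individuals and the candidate average,

      CD(c) = diag[ c'(A - lambda (Z'MZ + lambda A^-1)^-1) c / (c'A c) ],

  with lambda = (1 - h2)/h2 the residual-to-genetic variance ratio
  (h2 = 0.5 by default, so lambda = 1), Z the training incidence matrix and
  M the projector orthogonal to the intercept.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .distances import PairMatrix
from .kinship import RelationshipMatrix

__all__ = [
    "SampleDesign",
    "srs_sample",
    "stratified_sample",
    "gd_sample",
    "cd_contrast_values",
    "cdmean_select",
]

DEFAULT_RIDGE = 1e-6


@dataclasses.dataclass
class SampleDesign:
    """An ordered training set plus the recipe that produced it."""

    training_ids: list[str]
    method: str
    parameters: dict
    seed: int
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.training_ids)) != len(self.training_ids):
            raise ValueError("training ids must be unique")

    @property
    def n(self) -> int:
        return len(self.training_ids)


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def srs_sample(candidates: Sequence[str], n: int, seed: int = 0) -> SampleDesign:
    """Uniform sample of ``n`` candidates without replacement."""
    candidates = list(candidates)
    if n > len(candidates):
        raise ValueError(f"cannot sample {n} from {len(candidates)} candidates")
    picks = _rng(seed, 1).choice(len(candidates), size=n, replace=False)
    return SampleDesign(
        training_ids=[candidates[i] for i in picks],
        method="SRS",
        parameters={"n": n},
        seed=seed,
    )


def proportional_allocation(n: int, stratum_sizes: Sequence[int]) -> np.ndarray:
    """Largest-remainder rounding of the proportional quotas n * N_S / N."""
    sizes = np.asarray(stratum_sizes, dtype=float)
    total = sizes.sum()
    quota = n * sizes / total
    alloc = np.floor(quota).astype(int)
    rem = n - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:rem]] += 1
    return alloc


def stratified_sample(
    candidates: Sequence[str],
    strata: Sequence[str],
    n: int,
    seed: int = 0,
) -> SampleDesign:
    """Proportional stratified sample: SRS within each stratum."""
    candidates = list(candidates)
    strata = [str(s) for s in strata]
    if len(strata) != len(candidates):
        raise ValueError("strata labels must align with candidates")
    if n > len(candidates):
        raise ValueError(f"cannot sample {n} from {len(candidates)} candidates")
    labels = sorted(set(strata))
    if len(labels) == 1:  # degenerate stratification: plain SRS
        design = srs_sample(candidates, n, seed)
        return dataclasses.replace(
            design, method="STRAT", parameters={"n": n, "allocation": {labels[0]: n}}
        )
    members = {lab: [c for c, s in zip(candidates, strata) if s == lab] for lab in labels}
    alloc = proportional_allocation(n, [len(members[lab]) for lab in labels])
    for lab, k in zip(labels, alloc):
        if k > len(members[lab]):
            raise ValueError(
                f"allocation requires {k} from stratum {lab!r} of size {len(members[lab])}"
            )
    chosen: list[str] = []
    for idx, (lab, k) in enumerate(zip(labels, alloc)):
        rng = _rng(seed, 2, idx)
        picks = rng.choice(len(members[lab]), size=k, replace=False)
        chosen.extend(members[lab][i] for i in picks)
    return SampleDesign(
        training_ids=chosen,
        method="STRAT",
        parameters={"n": n, "allocation": {lab: int(k) for lab, k in zip(labels, alloc)}},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genetic-distance sampling (radial exclusion)
# ---------------------------------------------------------------------------

def _radial_exclusion(dist: np.ndarray, order: np.ndarray, r: float) -> list[int]:
    """Greedy pass: pick along ``order``, discarding neighbours at distance < r."""
    alive = np.ones(dist.shape[0], dtype=bool)
    picked: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        picked.append(int(i))
        alive &= ~(dist[i] < r)  # strict: ties at exactly r survive
        alive[i] = False
    return picked


def gd_sample(
    similarity: PairMatrix,
    candidates: Sequence[str],
    n: int,
    seed: int = 0,
    radius: float | None = None,
    max_bisect: int = 60,
) -> SampleDesign:
    """Genetic-distance sampling on ``1 - similarity``.

    With ``radius`` given, individuals are drawn uniformly at random with
    radial exclusion until ``n`` are selected (radius 0 excludes nothing and
    reduces to SRS).  Without a radius, r is tuned by bisection -- with the
    pick order frozen per evaluation -- until exhausting the candidate pool
    yields exactly ``n`` picks; at a step discontinuity the tightest radius
    yielding >= n is used and the surplus is trimmed uniformly at random
    (recorded in the diagnostics).  Every returned sample has minimum
    pairwise distance >= the achieved radius.
    """
    if similarity.role != "similarity":
        raise ValueError("gd_sample requires a similarity matrix (diag 1, [0,1])")
    candidates = list(candidates)
    if n > len(candidates):
        raise ValueError(f"cannot sample {n} from {len(candidates)} candidates")
    lookup = {g: i for i, g in enumerate(similarity.ids)}
    idx = np.array([lookup[c] for c in candidates])
    dist = 1.0 - similarity.values[np.ix_(idx, idx)]
    rng = _rng(seed, 3)
    order = rng.permutation(len(candidates))

    if radius is not None:
        picked = _radial_exclusion(dist, order, radius)
        if len(picked) < n:
            raise ValueError(
                f"radius {radius} exhausts the pool after {len(picked)} picks (< {n})"
            )
        picked = picked[:n]
        r_final, trimmed = float(radius), 0
    else:
        # capacity check: clusters of identical profiles can never be split
        tiny = 1e-12
        capacity = len(_radial_exclusion(dist, order, tiny))
        if capacity < n:
            i = _duplicate_cluster(dist)
            raise ValueError(
                f"only {capacity} distinct profiles among candidates (< {n}); "
                f"duplicate cluster includes {[candidates[j] for j in i]}"
            )
        lo, hi = tiny, float(dist.max()) * (1 + 1e-9) + tiny
        best_r, best_picks = tiny, _radial_exclusion(dist, order, tiny)
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            picks = _radial_exclusion(dist, order, mid)
            if len(picks) >= n:
                lo = mid
                if mid > best_r:
                    best_r, best_picks = mid, picks
                if len(picks) == n:
                    break
            else:
                hi = mid
        picked = list(best_picks)
        trimmed = len(picked) - n
        if trimmed:
            keep = rng.choice(len(picked), size=n, replace=False)
            picked = [picked[i] for i in sorted(keep)]
        r_final = best_r
    sample_dist = dist[np.ix_(picked, picked)]
    min_pair = float(sample_dist[np.tril_indices(n, k=-1)].min()) if n > 1 else np.inf
    return SampleDesign(
        training_ids=[candidates[i] for i in picked],
        method="GD",
        parameters={"n": n, "radius": r_final, "measure": similarity.measure},
        seed=seed,
        diagnostics={"achieved_radius": r_final, "trimmed": trimmed, "min_pairwise_distance": min_pair},
    )


def _duplicate_cluster(dist: np.ndarray) -> list[int]:
    for i in range(dist.shape[0]):
        dup = np.flatnonzero(dist[i] <= 0)
        if len(dup) > 1:
            return [int(j) for j in dup]
    return []


# ---------------------------------------------------------------------------
# CDmean
# ---------------------------------------------------------------------------

def _contrast_matrix(n_total: int, target_idx: np.ndarray, cand_idx: np.ndarray) -> np.ndarray:
    """Columns c_t = e_t - (1/N_cand) 1_cand for each target t."""
    c = np.zeros((n_total, len(target_idx)))
    c[cand_idx, :] -= 1.0 / len(cand_idx)
    c[target_idx, np.arange(len(target_idx))] += 1.0
    return c


def cd_contrast_values(
    A: RelationshipMatrix,
    training_ids: Sequence[str],
    target_ids: Sequence[str],
    lam: float,
    candidate_ids: Sequence[str] | None = None,
    ridge: float = DEFAULT_RIDGE,
    _A_inv: np.ndarray | None = None,
) -> np.ndarray:
    """Generalized coefficient of determination of target contrasts.

    Evaluates CD(c) = c'(A - lambda (Z'MZ + lambda A^-1)^-1)c / (c'Ac) for
    one contrast per target, where Z maps the training observations onto
    individuals and M projects out the intercept.  Contrasts compare each
    target with the mean of ``candidate_ids`` (all individuals of ``A`` by
    default).  An empty training set gives CD = 0 for every contrast.  A
    small ridge stabilises the inverse of A.
    """
    ids = A.ids
    lookup = {g: i for i, g in enumerate(ids)}
    tr = np.array([lookup[g] for g in training_ids], dtype=int)
    tg = np.array([lookup[g] for g in target_ids], dtype=int)
    cand = (
        np.arange(len(ids))
        if candidate_ids is None
        else np.array([lookup[g] for g in candidate_ids], dtype=int)
    )
    if len(tg) == 0:
        return np.array([])
    if len(tr) == 0:
        return np.zeros(len(tg))
    n_tot = len(ids)
    a = A.A + ridge * np.eye(n_tot)
    a_inv = np.linalg.inv(a) if _A_inv is None else _A_inv
    t = np.zeros(n_tot)
    t[tr] = 1.0
    # Z'MZ with intercept-only X over the training rows: diag(t) - t t'/n_tr
    b = lam * a_inv + np.diag(t) - np.outer(t, t) / len(tr)
    c = _contrast_matrix(n_tot, tg, cand)
    try:
        binv_c = np.linalg.solve(b, c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular CD inner matrix despite ridge") from exc
    ac = a @ c
    denom = np.einsum("ij,ij->j", c, ac)
    numer = denom - lam * np.einsum("ij,ij->j", c, binv_c)
    return numer / denom


class _CDWorkspace:
    """Incremental evaluation of the mean CD objective during exchange search.

    Maintains the dense inverse of B = lambda A^-1 + diag(t) - t t'/n_tr
    across single-swap proposals via four rank-1 (Sherman-Morrison)
    updates, and evaluates every contrast in O(N^2) using
    c'Mc = M_tt - 2 (M u)_t + u'M u for c_t = e_t - u,  u = 1_cand / N_cand.
    Produces values identical to :func:`cd_contrast_values` (refreshing the
    exact inverse periodically to cap round-off drift).
    """

    def __init__(self, A: RelationshipMatrix, candidates: list[str], lam: float, ridge: float):
        self.ids = A.ids
        self.lookup = {g: i for i, g in enumerate(self.ids)}
        n_tot = len(self.ids)
        self.a = A.A + ridge * np.eye(n_tot)
        self.m0 = lam * np.linalg.inv(self.a)
        self.lam = lam
        self.u = np.zeros(n_tot)
        cand_idx = [self.lookup[g] for g in candidates]
        self.u[cand_idx] = 1.0 / len(cand_idx)
        au = self.a @ self.u
        # per-target denominator c'Ac, precomputed for every individual
        self.af = np.diag(self.a) - 2.0 * au + float(self.u @ au)
        self.binv: np.ndarray | None = None
        self.t: np.ndarray | None = None
        self.n_tr = 0
        self._accepts_since_refresh = 0

    def set_design(self, sel_idx: list[int]) -> None:
        n_tot = len(self.ids)
        self.t = np.zeros(n_tot)
        self.t[sel_idx] = 1.0
        self.n_tr = len(sel_idx)
        b = self.m0 + np.diag(self.t) - np.outer(self.t, self.t) / self.n_tr
        self.binv = np.linalg.inv(b)
        self._accepts_since_refresh = 0

    @staticmethod
    def _rank1(binv: np.ndarray, v: np.ndarray, sigma: float) -> np.ndarray:
        bv = binv @ v
        return binv - (sigma / (1.0 + sigma * float(v @ bv))) * np.outer(bv, bv)

    def swapped_inverse(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of B after swapping selected i out and candidate j in."""
        t_new = self.t.copy()
        t_new[i], t_new[j] = 0.0, 1.0
        binv = self._rank1(self.binv, np.eye(1, len(self.t), i).ravel(), -1.0)
        e_j = np.zeros(len(self.t))
        e_j[j] = 1.0
        binv = self._rank1(binv, e_j, 1.0)
        binv = self._rank1(binv, self.t, 1.0 / self.n_tr)
        binv = self._rank1(binv, t_new, -1.0 / self.n_tr)
        return binv, t_new

    def mean_cd(self, binv: np.ndarray, target_idx: np.ndarray) -> float:
        bu = binv @ self.u
        qf = np.diag(binv) - 2.0 * bu + float(self.u @ bu)
        cd = 1.0 - self.lam * qf[target_idx] / self.af[target_idx]
        return float(cd.mean())

    def accept(self, binv: np.ndarray, t_new: np.ndarray, exact_every: int = 100) -> None:
        self.binv, self.t = binv, t_new
        self._accepts_since_refresh += 1
        if self._accepts_since_refresh >= exact_every:
            self.set_design(list(np.flatnonzero(self.t)))


def cdmean_select(
    A: RelationshipMatrix,
    candidates: Sequence[str],
    n: int,
    h2: float = 0.5,
    target_ids: Sequence[str] | None = None,
    seed: int = 0,
    max_stall: int = 2000,
    n_starts: int = 3,
    ridge: float = DEFAULT_RIDGE,
) -> SampleDesign:
    """CDmean training-set selection by stall-bounded stochastic exchange.

    Starting from an SRS sample, one selected individual is repeatedly
    proposed to swap with one non-selected candidate, and the swap is
    accepted iff the mean CD strictly increases; the search stops after
    ``max_stall`` consecutive rejections.  ``n_starts`` independent restarts
    are run and the best objective kept.  With ``target_ids`` given
    (independent-test-set use) the contrasts are fixed on those targets;
    otherwise the contrasts are the currently non-selected candidates,
    recomputed after every accepted swap.  ``h2`` sets
    lambda = (1 - h2)/h2 (0.5 -> lambda = 1); it is a planning input, not
    the heritability of any particular trait.
    """
    candidates = list(candidates)
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    lam = (1.0 - h2) / h2
    if n >= len(candidates):
        return SampleDesign(
            training_ids=candidates,
            method="CDMEAN",
            parameters={"n": len(candidates), "h2": h2, "lambda": lam},
            seed=seed,
            diagnostics={"mean_cd": np.nan, "note": "n >= candidates, all selected"},
        )
    targeted = target_ids is not None
    ws = _CDWorkspace(A, candidates, lam, ridge)
    fixed_targets = (
        np.array([ws.lookup[g] for g in target_ids], dtype=int) if targeted else None
    )

    def targets_for(pool_idx: list[int]) -> np.ndarray:
        return fixed_targets if targeted else np.array(pool_idx, dtype=int)

    best: tuple[float, list[int], list[float]] | None = None
    for start in range(n_starts):
        rng = _rng(seed, 4, start)
        start_ids = srs_sample(candidates, n, seed=int(rng.integers(2**31))).training_ids
        sel = [ws.lookup[g] for g in start_ids]
        pool = [ws.lookup[c] for c in candidates if c not in set(start_ids)]
        ws.set_design(sel)
        cur = ws.mean_cd(ws.binv, targets_for(pool))
        trajectory = [cur]
        stall = 0
        while stall < max_stall:
            i = int(rng.integers(len(sel)))
            j = int(rng.integers(len(pool)))
            binv_new, t_new = ws.swapped_inverse(sel[i], pool[j])
            sel[i], pool[j] = pool[j], sel[i]
            new = ws.mean_cd(binv_new, targets_for(pool))
            if new > cur:
                cur = new
                trajectory.append(cur)
                stall = 0
                ws.accept(binv_new, t_new)
            else:
                sel[i], pool[j] = pool[j], sel[i]  # revert
                stall += 1
        # exact objective of the final design, free of incremental drift
        final_ids = [ws.ids[i] for i in sel]
        exact = float(
            cd_contrast_values(
                A,
                final_ids,
                [ws.ids[i] for i in targets_for(pool)],
                lam,
                candidate_ids=candidates,
                ridge=ridge,
            ).mean()
        )
        if best is None or exact > best[0]:
            best = (exact, list(sel), trajectory)
    assert best is not None
    mean_cd, sel_idx, trajectory = best
    sel = [ws.ids[i] for i in sel_idx]
    return SampleDesign(
        training_ids=sel,
        method="CDMEAN",
        parameters={
            "n": n,
            "h2": h2,
            "lambda": lam,
            "targeted": targeted,
            "max_stall": max_stall,
            "n_starts": n_starts,
        },
        seed=seed,
        diagnostics={"mean_cd": mean_cd, "trajectory": trajectory},
    )
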