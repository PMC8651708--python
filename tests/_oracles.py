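"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain per-pair / per-element loops, straight
from the formula definitions, deliberately sharing no code with the
package's vectorised implementations.
"""

import math

import numpy as np


def _pair_profiles(panel, a, b):
    """Dosage profiles of individuals a, b restricted to shared markers."""
    d = panel.dosage_float()
    keep = ~np.isnan(d[a]) & ~np.isnan(d[b])
    return d[a][keep], d[b][keep], int(keep.sum())


def nei_pair(panel, a, b):
    x, y, _ = _pair_profiles(panel, a, b)
    q = panel.ploidy
    num = sxx = syy = 0.0
    for xj, yj in zip(x, y):
        px, py = xj / q, yj / q
        for pa, pb in ((px, py), (1 - px, 1 - py)):
            num += pa * pb
            sxx += pa * pa
            syy += pb * pb
    if num == 0:
        return math.inf
    return -math.log(num / math.sqrt(sxx * syy))


def euclidean_pair(panel, a, b):
    x, y, r_eff = _pair_profiles(panel, a, b)
    ss = sum((xj - yj) ** 2 for xj, yj in zip(x, y))
    return math.sqrt(ss * panel.n_markers / r_eff)


def jaccard_pair(panel, a, b):
    x, y, _ = _pair_profiles(panel, a, b)
    mn = sum(min(xj, yj) for xj, yj in zip(x, y))
    mx = sum(max(xj, yj) for xj, yj in zip(x, y))
    return mn / mx if mx > 0 else 1.0


def kosman_pair(panel, a, b):
    x, y, r_eff = _pair_profiles(panel, a, b)
    q = panel.ploidy
    tot = sum(min(xj, yj) + min(q - xj, q - yj) for xj, yj in zip(x, y))
    return tot / (q * r_eff)


def vanraden_oracle(panel):
    """Element-by-element evaluation of the VanRaden relationship matrix."""
    q = panel.ploidy
    d = panel.dosage_float()
    n, m = d.shape
    w = np.empty((n, m))
    for j in range(m):
        col = d[:, j]
        mean = np.nanmean(col)
        for i in range(n):
            v = col[i] if not np.isnan(col[i]) else mean
            w[i, j] = (v - q / 2) / (q / 2)
    p = np.array([1 - np.nanmean(d[:, j]) / q for j in range(m)])  # reference freq
    qmat = np.empty_like(w)
    for j in range(m):
        for i in range(n):
            qmat[i, j] = w[i, j] - (1 - 2 * p[j])
    denom = 2 * sum(pj * (1 - pj) for pj in p)
    a = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            a[i, k] = sum(qmat[i, j] * qmat[k, j] for j in range(m)) / denom
    return a


def cd_oracle(ids, a_mat, training_ids, target_ids, lam, candidate_ids=None, ridge=1e-6):
    """Direct dense-algebra evaluation of the CD-of-contrasts formula."""
    lookup = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    a = a_mat + ridge * np.eye(n)
    tr = [lookup[g] for g in training_ids]
    cand = list(range(n)) if candidate_ids is None else [lookup[g] for g in candidate_ids]
    n_tr = len(tr)
    z = np.zeros((n_tr, n))
    for row, i in enumerate(tr):
        z[row, i] = 1.0
    x = np.ones((n_tr, 1))
    m_proj = np.eye(n_tr) - x @ np.linalg.pinv(x.T @ x) @ x.T
    inner = z.T @ m_proj @ z + lam * np.linalg.inv(a)
    g = a - lam * np.linalg.inv(inner)
    out = []
    for t in target_ids:
        c = np.zeros(n)
        for i in cand:
            c[i] -= 1.0 / len(cand)
        c[lookup[t]] += 1.0
        out.append(float(c @ g @ c / (c @ a @ c)))
    return np.array(out)


def mme_gblup_oracle(ids, a_mat, train_ids, y, predict_ids, delta):
    """Henderson mixed-model equations at a fixed variance ratio delta."""
    lookup = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    tr = [lookup[g] for g in train_ids]
    n_tr = len(tr)
    z = np.zeros((n_tr, n))
    for row, i in enumerate(tr):
        z[row, i] = 1.0
    x = np.ones((n_tr, 1))
    a_inv = np.linalg.inv(a_mat)
    lhs = np.zeros((1 + n, 1 + n))
    lhs[0, 0] = n_tr
    lhs[0, 1:] = x.T @ z
    lhs[1:, 0] = (x.T @ z).ravel()
    lhs[1:, 1:] = z.T @ z + delta * a_inv
    rhs = np.concatenate([x.T @ y, z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    beta, u = sol[0], sol[1:]
    return beta, np.array([beta + u[lookup[g]] for g in predict_ids])


def amova_allele_oracle(panel, strata):
    """Allele-copy AMOVA among-group fraction by explicit unit expansion."""
    q = panel.ploidy
    d = panel.dosage_float()
    labels = sorted(set(str(s) for s in strata))
    g = len(labels)
    ss_among_tot = ss_within_tot = 0.0
    df_a = df_w = 0.0
    n0_list = []
    for j in range(panel.n_markers):
        units = {lab: [] for lab in labels}
        for i in range(panel.n_individuals):
            if np.isnan(d[i, j]):
                continue
            k = int(d[i, j])
            units[str(strata[i])].extend([1] * k + [0] * (q - k))
        counts = {lab: len(units[lab]) for lab in labels}
        n_tot = sum(counts.values())
        if n_tot == 0:
            continue
        allv = [v for lab in labels for v in units[lab]]
        grand = np.mean(allv)
        ss_total = sum((v - grand) ** 2 for v in allv)
        ss_within = sum(
            (v - np.mean(units[lab])) ** 2 for lab in labels for v in units[lab]
        )
        ss_among_tot += ss_total - ss_within
        ss_within_tot += ss_within
        df_a += g - 1
        df_w += n_tot - g
        n0_list.append(
            (n_tot - sum(c * c for c in counts.values()) / n_tot) / (g - 1)
        )
    ms_a = ss_among_tot / df_a
    ms_w = ss_within_tot / df_w
    sigma_a = (ms_a - ms_w) / np.mean(n0_list)
    return sigma_a / (sigma_a + ms_w)


def pearson_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / math.sqrt(np.sum(am**2) * np.sum(bm**2)))
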