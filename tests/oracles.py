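"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by the most transparent route available
(brute force, exhaustive enumeration, a second library), staying
independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm, rankdata


def brute_force_disk_mask(height: int, width: int, center, diameter: float):
    """Disk membership by looping every pixel and testing the distance rule."""
    cx, cy = center
    r = diameter / 2.0
    mask = np.zeros((height, width), dtype=bool)
    for py in range(height):
        for px in range(width):
            # pixel centres: (px+0.5, py+0.5); ROI centre: (cx+0.5, cy+0.5)
            dx = (px + 0.5) - (cx + 0.5)
            dy = (py + 0.5) - (cy + 0.5)
            if dx * dx + dy * dy <= r * r:
                mask[py, px] = True
    return mask


def two_pass_mean_sd(values):
    """Textbook two-pass mean / population SD."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var**0.5


def midranks(values):
    """Average ranks computed by explicit sorting, without scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_on_midranks(x, y):
    """Spearman rho as the Pearson correlation of explicit mid-ranks."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def spearman_exact_p(x, y):
    """Two-sided permutation p of |rho| by full enumeration (n <= 8)."""
    x = list(x)
    n = len(x)
    obs = abs(pearson_on_midranks(x, y))
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(pearson_on_midranks([x[i] for i in perm], y))
        hits += r >= obs - 1e-12
        total += 1
    return hits / total


def fleiss_kappa_formula(counts):
    """Fleiss kappa by explicit per-item loops (independent of the package)."""
    counts = np.asarray(counts, dtype=float)
    n_items, n_cats = counts.shape
    r = counts[0].sum()
    p_is = []
    for i in range(n_items):
        agree = sum(counts[i, j] * (counts[i, j] - 1) for j in range(n_cats))
        p_is.append(agree / (r * (r - 1)))
    p_bar = sum(p_is) / n_items
    p_j = [counts[:, j].sum() / (n_items * r) for j in range(n_cats)]
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def _pairwise_q(v, X, Y):
    """|standardized rank statistic| * sqrt(2) for rows of index arrays."""
    na, nb = X.shape[1], Y.shape[1]
    N = na + nb
    pooled = v[np.hstack([X, Y])]
    ranks = rankdata(pooled, axis=1)
    ra = ranks[:, :na].sum(axis=1)
    expect = na * (N + 1) / 2.0
    var = na * nb / (N * (N - 1.0)) * (
        (ranks**2).sum(axis=1) - N * (N + 1.0) ** 2 / 4.0
    )
    return np.abs((ra - expect) / np.sqrt(var)) * np.sqrt(2.0)


def joint_assignment_count(sizes) -> int:
    from math import comb

    n1, n2, n3 = sizes
    return comb(n1 + n2 + n3, n1) * comb(n2 + n3, n2)


def steel_dwass_exact_family_p(values, sizes):
    """Exact familywise Steel-Dwass p-values by exhaustive relabelling.

    Enumerates every assignment of the pooled values to three groups of the
    given sizes, computes all three pairwise standardized rank statistics
    (mid-ranks, tie-corrected variance — the same statistic the package
    uses) and takes the familywise maximum of ``|t|*sqrt(2)``.  The exact
    adjusted p for an observed pair is the fraction of assignments whose
    maximum reaches the observed value — the quantity the studentized-range
    reference approximates.

    Returns ``(q_observed_per_pair, exact_p_per_pair)`` with pairs ordered
    (0,1), (0,2), (1,2).
    """
    v = np.asarray(values, dtype=float)
    n1, n2, n3 = sizes
    N = n1 + n2 + n3
    c1 = np.array(list(itertools.combinations(range(N), n1)))
    rem1 = np.array(
        [np.setdiff1d(np.arange(N), c, assume_unique=True) for c in c1]
    )
    c2rel = np.array(list(itertools.combinations(range(N - n1), n2)))
    c3rel = np.array(
        [np.setdiff1d(np.arange(N - n1), c, assume_unique=True) for c in c2rel]
    )
    m1, m2 = c1.shape[0], c2rel.shape[0]
    A = np.repeat(c1, m2, axis=0)
    B = rem1[:, c2rel].reshape(m1 * m2, n2)
    C = rem1[:, c3rel].reshape(m1 * m2, n3)
    maxq = np.maximum(
        np.maximum(_pairwise_q(v, A, B), _pairwise_q(v, A, C)),
        _pairwise_q(v, B, C),
    )
    offs = np.cumsum((0, n1, n2, n3))
    groups = [np.arange(offs[i], offs[i + 1])[None, :] for i in range(3)]
    q_obs, p_exact = [], []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        q = float(_pairwise_q(v, groups[i], groups[j])[0])
        q_obs.append(q)
        p_exact.append(float(np.mean(maxq >= q - 1e-9)))
    return q_obs, p_exact


def wilcoxon_normal_p(a, b):
    """Two-sided tie-corrected normal-approximation rank-sum p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    N = na + nb
    ranks = rankdata(np.concatenate([a, b]))
    ra = ranks[:na].sum()
    expect = na * (N + 1) / 2.0
    var = na * nb / (N * (N - 1.0)) * (
        (ranks**2).sum() - N * (N + 1.0) ** 2 / 4.0
    )
    z = (ra - expect) / np.sqrt(var)
    return 2.0 * norm.sf(abs(z))
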