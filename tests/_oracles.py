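"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: morphology is done with
Euclidean distance transforms and connected-component flood fills instead
of structuring elements; co-occurrence with an O(n^2) distance matrix
instead of a spatial index; the Cox check with a direct grid search of the
partial likelihood instead of Newton iteration.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# Morphology (per-pixel Euclidean distance + flood fill)
# ---------------------------------------------------------------------------

def edt_dilate(mask: np.ndarray, r: float) -> np.ndarray:
    """Closed-ball dilation: pixels within Euclidean distance r of the set."""
    if not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= r


def edt_erode(mask: np.ndarray, r: float) -> np.ndarray:
    """Closed-ball erosion: pixels whose distance to the complement exceeds r.

    The complement includes everything beyond the image border.
    """
    pad = int(np.ceil(r)) + 1
    m = np.pad(mask, pad, constant_values=False)
    if not (~m).any():
        return mask.copy()
    out = ndi.distance_transform_edt(m) > r
    return out[pad:-pad, pad:-pad]


def flood_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the image border
    (4-connectivity, matching binary_fill_holes' default)."""
    bg = ~mask
    labels, n = ndi.label(bg)
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])))
    out = mask.copy()
    for lab in range(1, n + 1):
        if lab not in border_labels:
            out |= labels == lab
    return out


def tas_oracle(tumour: np.ndarray, stroma: np.ndarray, r_dil: int, r_fill: int) -> np.ndarray:
    """Reference TAS: hole_fill(close(dilate(tumour, r_dil), r_fill)) & stroma,
    with all operations on an infinite background plane."""
    pad = r_dil + r_fill + 1
    t = np.pad(tumour, pad, constant_values=False)
    env = edt_dilate(t, r_dil) if r_dil > 0 else t.copy()
    if r_fill > 0:
        env = edt_erode(edt_dilate(env, r_fill), r_fill)
    env = flood_fill_holes(env)
    env = env[pad:-pad, pad:-pad]
    return env & stroma


def random_blob_mask(rng: np.random.Generator, shape=(128, 128), n_blobs=5,
                     r_range=(4, 18)) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        r = rng.uniform(*r_range)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def cm_all_pairs(points: np.ndarray, type_idx: np.ndarray, k: int, radius: float) -> np.ndarray:
    """O(n^2) unordered-pair co-occurrence count matrix."""
    cm = np.zeros((k, k), dtype=np.int64)
    if len(points) < 2:
        return cm
    d = cdist(points, points)
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= radius:
                a, b = type_idx[i], type_idx[j]
                if a == b:
                    cm[a, a] += 1
                else:
                    cm[a, b] += 1
                    cm[b, a] += 1
    return cm


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def mw_exact_enumeration(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating which pooled positions form
    group A over the observed mid-ranks."""
    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n = a.size, a.size + b.size
    ranks = rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mu = n_a * (n - n_a) / 2
    dev = abs(u_obs - mu)
    hits = sum(
        1
        for idx in combinations(range(n), n_a)
        if abs(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2 - mu) >= dev - 1e-12
    )
    return hits / comb(n, n_a)


def kw_hand_formula(groups) -> float:
    """Kruskal-Wallis H without tie correction: 12/(N(N+1)) * sum n_g rbar_g^2 - 3(N+1)."""
    from scipy.stats import rankdata

    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += a.size * r.mean() ** 2
        start += a.size
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def cox_partial_loglik_1d(beta: float, x: np.ndarray, time: np.ndarray,
                          event: np.ndarray) -> float:
    """Direct (loop-based) Efron partial log-likelihood for one covariate."""
    ll = 0.0
    for t in np.unique(time[event]):
        risk = time >= t
        dead = event & (time == t)
        d = int(dead.sum())
        w = np.exp(beta * x)
        s = w[risk].sum()
        wd = w[dead].sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(s - (l / d) * wd)
    return ll


def logrank_hand_table(time, event, group1) -> float:
    """Per-event-time O-E / hypergeometric-variance chi-square, naive loops."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group1 = np.asarray(group1, bool)
    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group1).sum())
        d = int((event & (time == t)).sum())
        d1 = int((event & (time == t) & group1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v
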