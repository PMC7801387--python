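"""Independent brute-force oracles used by the tests.

These implementations deliberately share no code with the package: the
persistence oracle reduces the *full* boundary matrix over every simplex of
dimensions 0-2, the AUC oracle counts all pairs explicitly, and the variance
oracles resample.  They are only feasible at tiny sizes.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform


def brute_force_rips_h1(points: np.ndarray, max_filtration: float | None = None):
    """H1 intervals of a Rips filtration by full boundary-matrix reduction.

    Enumerates every vertex, edge and triangle, sorts all simplices by
    (filtration value, dimension, vertex tuple), reduces the complete
    boundary matrix over GF(2) with plain column operations, and reads off
    the (edge, triangle) pivot pairs plus unpaired positive edges (capped at
    ``max_filtration``).  Zero-length intervals are dropped.
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    D = squareform(pdist(X)) if n > 1 else np.zeros((1, 1))
    cap = float(D.max()) if max_filtration is None else float(max_filtration)

    simplices = [((i,), 0.0) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        simplices.append(((i, j), float(D[i, j])))
    for i, j, k in itertools.combinations(range(n), 3):
        val = max(D[i, j], D[i, k], D[j, k])
        if val <= cap:
            simplices.append(((i, j, k), float(val)))
    simplices = [s for s in simplices if len(s[0]) < 3 or s[1] <= cap]
    # drop edges above the cap: they are outside the filtration
    simplices = [s for s in simplices if not (len(s[0]) == 2 and s[1] > cap)]
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {verts: i for i, (verts, _) in enumerate(simplices)}

    columns: list[set[int]] = []
    for verts, _ in simplices:
        if len(verts) == 1:
            columns.append(set())
        else:
            facets = itertools.combinations(verts, len(verts) - 1)
            columns.append({index[f] for f in facets})

    low_to_col: dict[int, int] = {}
    pairs: dict[int, int] = {}
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in low_to_col:
                low_to_col[low] = j
                pairs[low] = j
                break
            col ^= columns[low_to_col[low]]

    intervals = []
    paired = set(pairs) | set(pairs.values())
    for low, j in pairs.items():
        verts_low, val_low = simplices[low]
        verts_hi, val_hi = simplices[j]
        if len(verts_low) == 2 and len(verts_hi) == 3 and val_hi > val_low:
            intervals.append((val_low, val_hi))
    for j, (verts, val) in enumerate(simplices):
        if len(verts) == 2 and not columns[j] and j not in pairs and val < cap:
            # positive edge never killed by a triangle: essential cycle
            if j not in set(pairs.values()):
                intervals.append((val, cap))
    return sorted(intervals)


def brute_force_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney count, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bootstrap_auc_diff_variance(score_a, score_b, labels, n_boot=100_000, seed=0) -> float:
    """Stratified bootstrap variance of AUC_a - AUC_b (classes resampled)."""
    score_a = np.asarray(score_a, float)
    score_b = np.asarray(score_b, float)
    labels = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    pos = np.where(labels)[0]
    neg = np.where(~labels)[0]
    pi = pos[rng.integers(0, len(pos), (n_boot, len(pos)))]
    ni = neg[rng.integers(0, len(neg), (n_boot, len(neg)))]

    def aucs(s):
        sp = s[pi][:, :, None]
        sn = s[ni][:, None, :]
        return (sp > sn).mean(axis=(1, 2)) + 0.5 * (sp == sn).mean(axis=(1, 2))

    d = aucs(score_a) - aucs(score_b)
    return float(d.var(ddof=1))


def sort_and_pick_median(values) -> float:
    """Median by explicit sort (odd: middle; even: mean of middle two)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else 0.5 * (v[mid - 1] + v[mid])
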