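"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct definition available
(exhaustive enumeration, textbook formula, O(n^3) greedy search) and is
kept free of any code path from the package under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def upgma_reference(X: np.ndarray) -> np.ndarray:
    """Greedy O(n^3) UPGMA on Euclidean row distances, SciPy linkage format.

    Inter-cluster distance is the mean over all leaf pairs; ties broken by
    the lowest cluster-index pair.  New clusters are numbered n, n+1, ...
    in merge order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    diff = X[:, None, :] - X[None, :, :]
    leaf_d = np.sqrt((diff**2).sum(axis=-1))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    Z = []
    nxt = n
    while len(members) > 1:
        best = None
        ids = sorted(members)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = leaf_d[np.ix_(members[a], members[b])].mean()
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        Z.append([a, b, d, len(members[a]) + len(members[b])])
        members[nxt] = members.pop(a) + members.pop(b)
        nxt += 1
    return np.array(Z)


def assert_same_merge_history(Z1: np.ndarray, Z2: np.ndarray, rtol: float = 1e-8) -> None:
    assert Z1.shape == Z2.shape
    for r1, r2 in zip(Z1, Z2):
        assert sorted((int(r1[0]), int(r1[1]))) == sorted((int(r2[0]), int(r2[1])))
        np.testing.assert_allclose(r1[2], r2[2], rtol=rtol, atol=1e-12)
        assert int(r1[3]) == int(r2[3])


def pearson_reference(x, y) -> float:
    """Textbook Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def hypergeom_upper_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P[overlap >= k] by enumerating every size-n draw from an N universe.

    All 2^N subsets are enumerated as bitmasks; the set is the first K
    elements.
    """
    masks = np.arange(1 << N, dtype=np.uint32)
    sizes = np.bitwise_count(masks)
    kmask = np.uint32((1 << K) - 1)
    successes = np.bitwise_count(masks & kmask)
    sel = sizes == n
    return float(np.mean(successes[sel] >= k))


def mannwhitney_exact_reference(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by direct pair counting over all labelings.

    U is computed as the count of (case, control) pairs with case > control
    plus half the tied pairs; the p-value is the fraction of all C(n+m, n)
    labelings whose U deviates from nm/2 at least as much as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)

    def u_of(case_idx) -> float:
        mask = np.zeros(N, dtype=bool)
        mask[list(case_idx)] = True
        diff = pooled[mask][:, None] - pooled[~mask][None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    obs = u_of(range(n))
    center = n * (N - n) / 2.0
    obs_dev = abs(obs - center)
    hits = total = 0
    for comb in combinations(range(N), n):
        total += 1
        if abs(u_of(comb) - center) >= obs_dev - 1e-9:
            hits += 1
    return obs, hits / total


def attribution_reference(clusters, display, groups):
    """Cluster x group attribution scores by an explicit double loop."""
    import pandas as pd

    out = {}
    for c in sorted(set(clusters.values())):
        feats = [f for f, lab in clusters.items() if lab == c]
        row = {}
        for g in dict.fromkeys(groups.values()):
            samples = [s for s, lab in groups.items() if lab == g]
            vals = [display.loc[f, s] for f in feats for s in samples]
            row[g] = float(np.mean(vals))
        out[c] = row
    return pd.DataFrame(out).T


def pca_fraction_reference(X: np.ndarray) -> np.ndarray:
    """Explained-variance fractions from the eigendecomposition of the
    feature-centered scatter matrix (X is samples x features)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    w = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
    w = np.clip(w, 0.0, None)
    return w / w.sum()
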