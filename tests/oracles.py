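"""Independent naive reimplementations used as oracles in tests.

Everything here is deliberately brute force and shares no code with the
package: plain agglomerative clustering by repeated matrix scans,
silhouettes by double loops, minimax path distances by relaxation.
"""

import itertools

import numpy as np


def naive_linkage_cophenetic(points: np.ndarray, method: str) -> np.ndarray:
    """Cophenetic distance matrix by explicit agglomeration.

    Supports single, complete, UPGMA (average) and Ward (D2, reported
    heights follow the Lance-Williams recursion on squared distances).
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = [[i] for i in range(n)]
    dist = d.copy()
    np.fill_diagonal(dist, np.inf)
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        k = dist.shape[0]
        i, j = divmod(np.argmin(dist), k)
        if i > j:
            i, j = j, i
        height = dist[i, j]
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = height
        merged = clusters[i] + clusters[j]
        new_dist = np.full(k - 2, np.inf)
        others = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        for new_idx, other_idx in enumerate(idx for idx in range(k) if idx not in (i, j)):
            dik, djk = dist[i, other_idx], dist[j, other_idx]
            ni, nj, nk = len(clusters[i]), len(clusters[j]), len(clusters[other_idx])
            if method == "single":
                val = min(dik, djk)
            elif method == "complete":
                val = max(dik, djk)
            elif method == "upgma":
                val = (ni * dik + nj * djk) / (ni + nj)
            elif method == "ward":
                val = np.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * height**2)
                    / (ni + nj + nk)
                )
            else:
                raise ValueError(method)
            new_dist[new_idx] = val
        keep = [idx for idx in range(k) if idx not in (i, j)]
        dist = dist[np.ix_(keep, keep)]
        dist = np.pad(dist, ((0, 1), (0, 1)), constant_values=np.inf)
        dist[-1, :-1] = new_dist
        dist[:-1, -1] = new_dist
        clusters = others + [merged]
    return coph


def minimax_path_distances(d: np.ndarray) -> np.ndarray:
    """Minimum over all paths of the maximum edge weight (n small)."""
    f = d.copy().astype(float)
    n = len(d)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                f[i, j] = min(f[i, j], max(f[i, k], f[k, j]))
    return f


def naive_silhouette(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean-silhouette by double loop; singletons score 0."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            s[i] = 0.0
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        s[i] = (b - a) / max(a, b)
    return s


def naive_binary_correlation(d: np.ndarray, labels: np.ndarray) -> float:
    """Pearson r between pairwise distances and the different-cluster indicator."""
    pairs = list(itertools.combinations(range(len(labels)), 2))
    x = np.array([d[i, j] for i, j in pairs])
    y = np.array([float(labels[i] != labels[j]) for i, j in pairs])
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


def naive_covariance_eigen(X: np.ndarray):
    """Eigendecomposition of the sample covariance, descending order."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]
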