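"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (explicit
loops, textbook formulas) and stays independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def pearson_matrix_oracle(features: np.ndarray) -> np.ndarray:
    """Per-pair Pearson correlations via scipy, negatives clamped, zero diagonal."""
    n = features.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = sps.pearsonr(features[i], features[j]).statistic
            out[i, j] = out[j, i] = max(r, 0.0)
    return out


def transitivity_oracle(w: np.ndarray) -> float:
    """Sum of cube-root triangle intensities over connected triplets, by loops."""
    n = w.shape[0]
    tri = 0.0
    for i in range(n):
        for j in range(n):
            for h in range(n):
                if i != j and j != h and i != h:
                    tri += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
    denom = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        denom += k * (k - 1)
    return tri / denom if denom > 0 else 0.0


def clustering_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tri += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        out[i] = tri / (k * (k - 1))
    return out


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/weight, by the textbook triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_oracle(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall_oracle(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def path_length_oracle(w: np.ndarray) -> float:
    n = w.shape[0]
    d = floyd_warshall_oracle(w)
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def connected_oracle(w: np.ndarray) -> bool:
    """Breadth-first reachability from node 0."""
    n = w.shape[0]
    if n <= 1:
        return True
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j not in seen and w[i, j] > 0:
                seen.add(j)
                frontier.append(j)
    return len(seen) == n


def balanced_two_way_anova_oracle(
    y: np.ndarray, a: np.ndarray, b: np.ndarray
) -> dict[str, tuple[float, int, int]]:
    """Textbook sums-of-squares decomposition for a balanced 2x2 design.

    Returns {effect: (F, df_num, df_den)} for the two main effects and the
    interaction, from explicit cell means.
    """
    levels_a, levels_b = sorted(set(a)), sorted(set(b))
    assert len(levels_a) == 2 and len(levels_b) == 2
    n_cell = len(y) // 4
    grand = y.mean()
    ss_a = ss_b = ss_ab = ss_err = 0.0
    mean_a = {la: y[a == la].mean() for la in levels_a}
    mean_b = {lb: y[b == lb].mean() for lb in levels_b}
    for la in levels_a:
        ss_a += 2 * n_cell * (mean_a[la] - grand) ** 2
    for lb in levels_b:
        ss_b += 2 * n_cell * (mean_b[lb] - grand) ** 2
    for la in levels_a:
        for lb in levels_b:
            cell = y[(a == la) & (b == lb)]
            cm = cell.mean()
            ss_ab += n_cell * (cm - mean_a[la] - mean_b[lb] + grand) ** 2
            ss_err += ((cell - cm) ** 2).sum()
    df_err = len(y) - 4
    out = {}
    for name, ss in [("diagnosis", ss_a), ("disinhibition", ss_b), ("diagnosis:disinhibition", ss_ab)]:
        out[name] = (float((ss / 1) / (ss_err / df_err)), 1, df_err)
    return out
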