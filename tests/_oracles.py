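"""Independent brute-force oracles used by the test suite.

Every function here is deliberately written in the most literal way possible
(double loops, explicit formulas, numerical integration) and is independent
of the implementation paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, special


def pairwise_euclidean_bruteforce(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(np.sum((x[i] - x[j]) ** 2))
    return d


def knn_union_bruteforce(distances: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrized kNN adjacency with lower-index tie-breaking."""
    n = distances.shape[0]
    directed = np.zeros((n, n))
    for i in range(n):
        order = sorted((distances[i, j], j) for j in range(n) if j != i)
        for _, j in order[:k]:
            directed[i, j] = 1.0
    return np.maximum(directed, directed.T)


def norm_operator_bruteforce(adjacency: np.ndarray) -> np.ndarray:
    n = adjacency.shape[0]
    a_tilde = adjacency + np.eye(n)
    deg = a_tilde.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = a_tilde[i, j] / (np.sqrt(deg[i]) * np.sqrt(deg[j]))
    return out


def auc_paircount(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def t_quantile_integrated(p: float, df: int) -> float:
    """Student-t quantile via numerical integration of the density."""

    def pdf(t: float) -> float:
        c = special.gamma((df + 1) / 2) / (
            np.sqrt(df * np.pi) * special.gamma(df / 2)
        )
        return c * (1 + t * t / df) ** (-(df + 1) / 2)

    def cdf(x: float) -> float:
        val, _ = integrate.quad(pdf, 0.0, x)
        return 0.5 + val

    return optimize.brentq(lambda x: cdf(x) - p, 0.0, 1000.0, xtol=1e-12)


def mlp_forward_bruteforce(
    x: np.ndarray, conv_weights: list[np.ndarray], head_w: np.ndarray, head_b: np.ndarray
) -> np.ndarray:
    """Per-node MLP: what a GCN reduces to when the operator is the identity."""
    out = np.zeros((x.shape[0], 2))
    for i in range(x.shape[0]):
        h = x[i]
        for w in conv_weights:
            h = np.maximum(h @ w, 0.0)
        out[i] = h @ head_w + head_b
    return out
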