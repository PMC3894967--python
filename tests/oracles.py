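"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity from textbook definitions without
touching the package's implementation paths: PCA via dense
eigendecomposition of the sample cross-product matrix, Welch's t from
its closed-form statistic and Welch-Satterthwaite degrees of freedom,
Pearson/Spearman from explicit sums, and correlation p-values from the
t transform evaluated pairwise in loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def pca1_eig(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-PC scores and eigenvalue shares via eigendecomposition of
    the samples x samples cross-product matrix of a row-standardized
    probes x samples array."""
    x = z.T  # samples x probes, columns centered
    c = x @ x.T
    eigvals, eigvecs = np.linalg.eigh(c)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    scores = eigvecs[:, order[0]] * math.sqrt(eigvals[0])
    shares = eigvals / eigvals.sum()
    return scores, shares


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return float(2 * t_dist.sf(abs(t), n - 2))


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by their average rank."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    return pearson_r(average_ranks(x), average_ranks(y))


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return float(t), float(2 * t_dist.sf(abs(t), df))


def connectivity_bruteforce(z: np.ndarray, alpha: float) -> np.ndarray:
    """Per-gene connection counts by looping over all gene pairs."""
    g, n = z.shape
    counts = np.zeros(g, dtype=int)
    for i in range(g):
        for j in range(i + 1, g):
            r = pearson_r(z[i], z[j])
            if pearson_p(r, n) < alpha:
                counts[i] += 1
                counts[j] += 1
    return counts
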