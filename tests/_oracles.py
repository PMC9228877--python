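"""Independent brute-force oracles used to validate the implementation.

These deliberately take different computational routes from the package:
exact binomial-coefficient arithmetic for hypergeometric tails, explicit
enumeration of all set partitions for modularity optima, and joint-entropy
arithmetic for NMI.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Hashable, Iterator, Mapping

import numpy as np


def hypergeom_tail(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact pmf summation."""
    total = Fraction(0)
    denom = math.comb(n_universe, n_b)
    for x in range(max(k, 0), min(n_a, n_b) + 1):
        if n_b - x <= n_universe - n_a:
            total += Fraction(math.comb(n_a, x) * math.comb(n_universe - n_a, n_b - x), denom)
    return float(min(total, Fraction(1)))


def set_partitions(n: int) -> Iterator[list[int]]:
    """All partitions of n items as restricted-growth label strings."""

    def rec(labels: list[int], k: int):
        if len(labels) == n:
            yield list(labels)
            return
        for c in range(k + 1):
            labels.append(c)
            yield from rec(labels, k + 1 if c == k else k)
            labels.pop()

    yield from rec([], 0)


def modularity_dense(weights: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Q from the dense weight matrix: (1/2m) sum_ij B_ij [c_i == c_j]."""
    labels = np.asarray(labels)
    degrees = weights.sum(axis=1)
    two_m = degrees.sum()
    b = weights - gamma * np.outer(degrees, degrees) / two_m
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum() / two_m)


def best_partition_exhaustive(weights: np.ndarray, gamma: float = 1.0) -> tuple[float, list[int]]:
    """Globally optimal modularity over every partition (small n only)."""
    best_q, best_labels = -np.inf, None
    for labels in set_partitions(weights.shape[0]):
        q = modularity_dense(weights, labels, gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def all_partition_q(weights: np.ndarray, partitions: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Vectorised Q for many partitions (P x n label array) of one graph."""
    degrees = weights.sum(axis=1)
    two_m = degrees.sum()
    b = weights - gamma * np.outer(degrees, degrees) / two_m
    same = partitions[:, :, None] == partitions[:, None, :]
    return (same * b[None, :, :]).sum(axis=(1, 2)) / two_m


def nmi_entropy(
    labelling_a: Mapping[Hashable, Hashable], labelling_b: Mapping[Hashable, Hashable]
) -> float:
    """NMI via I = H(A) + H(B) - H(A,B), arithmetic-mean normalization."""
    items = list(labelling_a)
    n = len(items)

    def entropy(counts) -> float:
        return -sum(c / n * math.log(c / n) for c in counts)

    ca: dict = {}
    cb: dict = {}
    cab: dict = {}
    for it in items:
        a, b = labelling_a[it], labelling_b[it]
        ca[a] = ca.get(a, 0) + 1
        cb[b] = cb.get(b, 0) + 1
        cab[(a, b)] = cab.get((a, b), 0) + 1
    h_a, h_b = entropy(ca.values()), entropy(cb.values())
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mi = h_a + h_b - entropy(cab.values())
    return mi / ((h_a + h_b) / 2.0)


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.5) -> np.ndarray:
    """Symmetric non-negative weight matrix with at least one edge."""
    while True:
        mask = rng.random((n, n)) < p_edge
        w = rng.uniform(0.1, 3.0, (n, n)) * mask
        w = np.triu(w, k=1)
        w = w + w.T
        if w.sum() > 0:
            return w
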