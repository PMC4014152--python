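"""Independent oracles used to freeze expected values in the tests.

Everything here deliberately avoids the package's own recursion and fitting
code paths: colony-size probabilities come from explicit enumeration of
binary lineage trees, extinction probabilities from fixed-point iteration,
and regression coefficients from a direct solve of the normal equations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def tree_shapes(n_leaves: int):
    """All full binary tree shapes with ``n_leaves`` leaves (Catalan many)."""
    if n_leaves == 1:
        return (None,)
    shapes = []
    for left in range(1, n_leaves):
        for ls in tree_shapes(left):
            for rs in tree_shapes(n_leaves - left):
                shapes.append((ls, rs))
    return tuple(shapes)


def tree_probability(shape, depth, p1_at) -> float:
    """Probability of one lineage tree: leaves die, internal nodes divide."""
    if shape is None:
        return p1_at(depth)
    left, right = shape
    return (
        (1.0 - p1_at(depth))
        * tree_probability(left, depth + 1, p1_at)
        * tree_probability(right, depth + 1, p1_at)
    )


def enumerated_pmf(p1_at, n_max: int) -> np.ndarray:
    """Colony-size probabilities by exhaustive tree enumeration."""
    f = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        f[n] = sum(tree_probability(s, 0, p1_at) for s in tree_shapes(n))
    return f


def extinction_fixed_point(p: float, tol: float = 1e-15) -> float:
    """Smaller root of q = p + (1 - p) q**2 by monotone iteration from 0."""
    q = 0.0
    for _ in range(100_000):
        q_next = p + (1.0 - p) * q * q
        if abs(q_next - q) < tol:
            return q_next
        q = q_next
    return q


def normal_equations_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) from a direct 2x2 normal-equations solve."""
    n = len(x)
    A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return float(intercept), float(slope)


def catalan(k: int) -> int:
    from math import comb

    return comb(2 * k, k) // (k + 1)
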