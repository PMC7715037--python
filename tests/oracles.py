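"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the
implementation it validates: SVD-whitening CCA vs the generalized
eigenproblem, simplex grid search vs Blahut–Arimoto, exhaustive assignment
enumeration vs greedy partition search, and a direct probability recursion
vs the engine's log-space Bayesian loop.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def cca_first_correlation_svd(x: np.ndarray, y: np.ndarray) -> float:
    """Largest canonical correlation via SVD whitening (textbook route).

    Center both variable sets, whiten each with its thin SVD, and take the
    largest singular value of the cross-product of the whitened bases.
    """
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    ux, sx, _ = np.linalg.svd(x.T, full_matrices=False)
    uy, sy, _ = np.linalg.svd(y.T, full_matrices=False)
    ux = ux[:, sx > 1e-12 * sx.max()]
    uy = uy[:, sy > 1e-12 * sy.max()]
    svals = np.linalg.svd(ux.T @ uy, compute_uv=False)
    return float(np.clip(svals.max(), 0.0, 1.0))


def mutual_information_bits(p: np.ndarray, w: np.ndarray) -> float:
    """Direct I(X;Y) from the joint distribution, 0 log 0 = 0."""
    joint = p[:, None] * w
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    total = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if joint[i, j] > 0:
                total += joint[i, j] * math.log2(joint[i, j] / (px[i] * py[j]))
    return total


def capacity_grid_search(w: np.ndarray, step: float = 0.01) -> float:
    """Channel capacity by brute-force search over a simplex grid."""
    k = w.shape[0]
    n = int(round(1.0 / step))
    best = 0.0
    for combo in itertools.combinations(range(n + k - 1), k - 1):
        counts = []
        prev = -1
        for c in combo:
            counts.append(c - prev - 1)
            prev = c
        counts.append(n + k - 2 - prev)
        p = np.array(counts, dtype=float) / n
        best = max(best, mutual_information_bits(p, w))
    return best


def z_channel_capacity(eps: float) -> float:
    """Closed-form capacity of the Z-channel [[1, 0], [eps, 1-eps]].

    C = log2(1 + (1 - eps) * eps^(eps / (1 - eps))).
    """
    return math.log2(1.0 + (1.0 - eps) * eps ** (eps / (1.0 - eps)))


def best_partition_exhaustive(
    posterior: np.ndarray, w: np.ndarray, n_boxes: int
) -> tuple[float, tuple[int, ...]]:
    """Exhaustive maximum of I(intended box; decoded box) over assignments."""
    n_chars = len(posterior)
    best_info, best_assign = -1.0, None
    for assign in itertools.product(range(n_boxes), repeat=n_chars):
        mass = np.zeros(n_boxes)
        for c, b in zip(range(n_chars), assign):
            mass[b] += posterior[c]
        total = mass.sum()
        info = mutual_information_bits(mass / total, w) if total > 0 else 0.0
        if info > best_info:
            best_info, best_assign = info, assign
    return best_info, best_assign


def queries_to_threshold(
    n_chars: int,
    n_boxes: int,
    correct_lk: float,
    incorrect_lk: float,
    threshold: float,
    max_queries: int = 1000,
) -> int:
    """Queries until the target's posterior strictly exceeds the threshold.

    Independent numerical recursion for the symmetric fixture: uniform prior
    over ``n_chars`` characters; every query the target's box receives
    likelihood ``correct_lk`` and the others ``incorrect_lk``.  A fixed
    partition can never cross the threshold (the target's box-mates share
    its likelihood factor), so the recursion re-partitions each query with
    mass balancing: characters sorted by mass (descending, index ascending
    on ties) are dealt largest-first into the currently lightest box — the
    balanced-load assignment that any expected-information maximizer
    approximates for a symmetric channel.
    """
    masses = np.full(n_chars, 1.0 / n_chars)  # index 0 is the target
    for n in range(1, max_queries + 1):
        order = sorted(range(n_chars), key=lambda c: (-masses[c], c))
        loads = np.zeros(n_boxes)
        box_of = np.empty(n_chars, dtype=int)
        for c in order:
            b = int(np.argmin(loads))
            box_of[c] = b
            loads[b] += masses[c]
        target_box = box_of[0]
        factors = np.where(box_of == target_box, correct_lk, incorrect_lk)
        masses = masses * factors
        masses = masses / masses.sum()
        if masses[0] > threshold:
            return n
    raise RuntimeError("threshold never crossed")
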