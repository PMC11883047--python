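"""Independent reference implementations used only to check the pipeline.

These deliberately avoid the code paths they verify: the subgraph-centrality
oracle is a truncated Taylor series (the implementation uses scipy's matrix
exponential), and the component-count oracle is a hand-written breadth-first
flood fill (the implementation uses scipy.ndimage labeling).
"""

from __future__ import annotations

from collections import deque

import numpy as np


def taylor_sc_diagonal(adjacency: np.ndarray, terms: int = 30) -> np.ndarray:
    """diag(exp(A)) via the truncated series sum_k A^k / k!."""
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    total = np.eye(n)
    power = np.eye(n)
    factorial = 1.0
    for k in range(1, terms + 1):
        power = power @ A
        factorial *= k
        total = total + power / factorial
    return np.diag(total).copy()


def flood_fill_component_count(mask: np.ndarray) -> int:
    """Number of 4-connected True components, by explicit BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
    return count


def random_lattice_adjacency(
    rng: np.random.Generator, max_side: int = 10
) -> np.ndarray:
    """Random small weighted 4-neighbour lattice (<= max_side^2 nodes)."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    mask = rng.random((h, w)) > 0.5
    n = h * w
    A = np.zeros((n, n))
    idx = np.arange(n).reshape(h, w)
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w:
                    wgt = 0.01 if mask[r, c] != mask[r2, c2] else 1.0
                    A[idx[r, c], idx[r2, c2]] = wgt
                    A[idx[r2, c2], idx[r, c]] = wgt
    return A
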