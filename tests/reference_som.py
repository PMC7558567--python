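"""Straight-line reference implementation of the supervised SOM update rule.

Everything is recomputed independently with plain Python loops: hexagonal
lattice distances come from a breadth-first search over the odd-r offset
neighbour table (not from cube-coordinate algebra), Euclidean distances and
the Gaussian neighbourhood are written out elementwise, and the exponential
schedule is re-derived from its definition. Only the initial weights and
the presentation order are shared with the implementation under test, so
any disagreement isolates a defect in the update arithmetic.
"""

import math
from collections import deque

# odd-r offset neighbour steps: (row parity) -> [(dr, dc), ...]
_EVEN = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
_ODD = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]


def hex_distances_bfs(rows, cols):
    """All-pairs lattice distances by BFS over the hex neighbour graph."""
    n = rows * cols
    dist = [[None] * n for _ in range(n)]
    for start in range(n):
        dist[start][start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            r, c = divmod(u, cols)
            steps = _ODD if r % 2 else _EVEN
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    v = rr * cols + cc
                    if dist[start][v] is None:
                        dist[start][v] = dist[start][u] + 1
                        queue.append(v)
    return dist


def train_reference(
    X, Y, init_w, orders, rows, cols,
    lr_initial, lr_final, sigma_initial, sigma_final,
):
    """Sequential SOM training with explicit loops.

    X: n x p list-of-lists (standardized features); Y: n x q scaled class
    indicators; init_w: units x (p+q) initial weights; orders: one index
    sequence per epoch. Returns the final units x (p+q) weights.
    """
    n = len(X)
    units = rows * cols
    dim = len(init_w[0])
    W = [list(map(float, row)) for row in init_w]
    D = hex_distances_bfs(rows, cols)
    total = sum(len(o) for o in orders)
    t = 0
    for order in orders:
        for i in order:
            sample = list(X[i]) + list(Y[i])
            if total <= 1:
                alpha, sigma = lr_initial, sigma_initial
            else:
                frac = t / (total - 1)
                alpha = lr_initial * (lr_final / lr_initial) ** frac
                sigma = sigma_initial * (sigma_final / sigma_initial) ** frac
            # BMU by exhaustive search, ties to the lowest unit index
            best, best_d = 0, float("inf")
            for u in range(units):
                d = 0.0
                for k in range(dim):
                    diff = sample[k] - W[u][k]
                    d += diff * diff
                if d < best_d:
                    best, best_d = u, d
            for u in range(units):
                h = math.exp(-(D[best][u] ** 2) / (2.0 * sigma * sigma))
                for k in range(dim):
                    W[u][k] += alpha * h * (sample[k] - W[u][k])
            t += 1
    return W
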