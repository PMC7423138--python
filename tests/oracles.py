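"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: betweenness by
exhaustive simple-path enumeration, the sparse-CCA objective by dense grid
search over the constraint set, and BH adjustment by the literal step-up
definition.
"""

from __future__ import annotations

import itertools

import numpy as np

EDGE_EPS = 1e-12


def betweenness_enumeration(W: np.ndarray) -> np.ndarray:
    """Betweenness by enumerating every simple path between every node pair.

    Fractional credit when several paths tie for shortest; endpoints get no
    credit. Feasible for graphs up to ~8 nodes.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    adj = {i: [j for j in range(n) if j != i and W[i, j] > EDGE_EPS] for i in range(n)}
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = []

        def extend(path, length):
            node = path[-1]
            if node == t:
                paths.append((length, tuple(path)))
                return
            for nxt in adj[node]:
                if nxt not in path:
                    extend(path + [nxt], length + 1.0 / W[node, nxt])

        extend([s], 0.0)
        if not paths:
            continue
        best = min(length for length, _ in paths)
        shortest = [p for length, p in paths if length <= best * (1 + 1e-12)]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def _sphere3(phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Grid of unit vectors in R^3 from spherical angle grids."""
    pp, tt = np.meshgrid(phi, theta, indexing="ij")
    return np.stack(
        [np.sin(pp) * np.cos(tt), np.sin(pp) * np.sin(tt), np.cos(pp)], axis=-1
    ).reshape(-1, 3)


def scca_grid_max(M: np.ndarray, c1: float, c2: float) -> float:
    """max u' M v over {||u||2<=1, ||u||1<=c1} x {||v||2<=1, ||v||1<=c2}, p=3, q=2.

    The maximum of a bilinear form over this convex set is attained at
    points of unit L2 norm, so the sphere (u) and circle (v) are searched on
    a coarse 0.01-radian grid followed by three local zoom rounds. Both signs
    are covered because the v circle spans a full revolution.
    """
    assert M.shape == (3, 2)

    def evaluate(phis, thetas, psis):
        U = _sphere3(phis, thetas)
        U = U[np.abs(U).sum(axis=1) <= c1]
        V = np.stack([np.cos(psis), np.sin(psis)], axis=-1)
        V = V[np.abs(V).sum(axis=1) <= c2]
        if U.size == 0 or V.size == 0:
            return -np.inf, None
        S = U @ M  # (Nu, 2)
        best_val, best_arg = -np.inf, None
        chunk = 256
        for start in range(0, V.shape[0], chunk):
            block = S @ V[start : start + chunk].T
            idx = np.unravel_index(np.argmax(block), block.shape)
            if block[idx] > best_val:
                best_val = float(block[idx])
                best_arg = (U[idx[0]], V[start + idx[1]])
        return best_val, best_arg

    step = 0.01
    phis = np.arange(0.0, np.pi + step, step)
    thetas = np.arange(0.0, 2 * np.pi, step)
    psis = np.arange(0.0, 2 * np.pi, step)
    best, arg = evaluate(phis, thetas, psis)

    # local refinement around the incumbent, 10x finer per round
    u_best, v_best = arg
    phi0 = np.arccos(np.clip(u_best[2], -1, 1))
    theta0 = np.arctan2(u_best[1], u_best[0])
    psi0 = np.arctan2(v_best[1], v_best[0])
    width = 2 * step
    for _ in range(3):
        step /= 10.0
        phis = np.arange(phi0 - width, phi0 + width + step, step)
        thetas = np.arange(theta0 - width, theta0 + width + step, step)
        psis = np.arange(psi0 - width, psi0 + width + step, step)
        val, arg = evaluate(phis, thetas, psis)
        if val > best and arg is not None:
            best = val
            u_best, v_best = arg
            phi0 = np.arccos(np.clip(u_best[2], -1, 1))
            theta0 = np.arctan2(u_best[1], u_best[0])
            psi0 = np.arctan2(v_best[1], v_best[0])
        width = 2 * step
    return best


def bh_stepup(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: adj_i = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    adj = np.empty(m)
    for i in range(m):
        vals = [p_sorted[j] * m / (j + 1) for j in range(i, m)]
        adj[i] = min(min(vals), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
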