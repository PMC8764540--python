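"""Independent oracles used by the test suite.

These deliberately avoid the package's LP/sampling code paths: FBA optima
are checked against brute-force vertex enumeration of the flux polytope,
and sampler statistics against rejection sampling in the box hull.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def enumerate_vertices(model, tol=1e-9):
    """All vertices of {v : S v = 0, lb <= v <= ub} by brute force.

    Fix every choice of (n - rank S) coordinates at a bound, solve the
    equality system for the rest, and keep consistent, in-bounds solutions.
    Only viable for tiny models.  Returns (vertices, best_objective).
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_free = n - rank
    c = model.objective_vector()
    vertices = []
    best = -np.inf
    for fixed_idx in combinations(range(n), n_free):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        for bounds_choice in product(*[(lb[j], ub[j]) for j in fixed_idx]):
            b = -S[:, fixed_idx] @ np.array(bounds_choice)
            sol, residual, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            v = np.empty(n)
            v[list(fixed_idx)] = bounds_choice
            v[free_idx] = sol
            if np.abs(S @ v).max() > 1e-7:
                continue  # inconsistent system
            if (v < lb - 1e-7).any() or (v > ub + 1e-7).any():
                continue
            vertices.append(np.clip(v, lb, ub))
            best = max(best, float(c @ v))
    return np.array(vertices), best


def rejection_sample_box(model, n, seed):
    """Uniform points of the flux polytope by rejection from the box hull.

    Draw uniformly inside [lb, ub] restricted to the polytope's affine
    span: here implemented for the packaged toy polytopes, whose free
    coordinates are identifiable as the source reactions.  Returns an
    (n, n_reactions) array of accepted points.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    rng = np.random.default_rng(seed)
    from scipy.linalg import null_space

    N = null_space(S)
    dim = N.shape[1]
    # rejection in the reduced coordinates: bounding box of y from the
    # vertices of the polytope
    vertices, _ = enumerate_vertices(model)
    x0 = vertices[0]
    Y = (vertices - x0) @ N
    y_lo, y_hi = Y.min(axis=0), Y.max(axis=0)
    out = []
    while len(out) < n:
        y = rng.uniform(y_lo, y_hi, size=(4 * n, dim))
        v = x0 + y @ N.T
        ok = ((v >= lb - 1e-9) & (v <= ub + 1e-9)).all(axis=1)
        out.extend(v[ok])
    return np.array(out[:n])
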