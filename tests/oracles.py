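"""Independent reference implementations used to check the package.

Everything here is written directly from the model equations / problem
definitions, deliberately not calling the package's own computational
paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def rk4_batch(p, y0, t_end, h=1e-3, t_breaks=()):
    """Fixed-step classic Runge-Kutta integration of the batch model.

    The right-hand side is written out term by term from the rate laws;
    state order X, E, S_cell, Glc, Fru, S_reactor, Levan.  Integration is
    split at ``t_breaks`` (the degradation onset) so the step never
    straddles the switch.  Derivatives of exhausted pools are floored at
    zero, mirroring the model's boundary behaviour.
    """

    def f(t, y):
        X, E, S_cell, Glc, Fru, S, Lev = np.maximum(y, 0.0)
        mu = p.mu_max * S / (p.Ks + S)
        v1 = mu * X / p.Y_XS
        v2 = p.alpha * mu * X
        v3 = p.vmax_hyd * S / (p.KM_hyd + S)
        a = S / p.KM_trans1
        b = Fru * S / p.KM_trans2
        v4 = (p.vmax_trans1 * a + p.vmax_trans2 * b) / (1.0 + a + b)
        Leff = (1.0 - p.degradable_fraction_complement) * Lev
        v5 = (p.vmax_levdeg * Leff / (p.KM_levdeg + Leff)
              if t >= p.t_levdeg_onset else 0.0)
        ep = p.alpha * X
        dy = np.array([
            (mu - p.kd) * X,
            v2,
            v1,
            (v3 + v4) * ep,
            (v3 - v4 + v5) * ep,
            -v1 - (v3 + v4) * ep,
            (v4 - v5) * ep,
        ])
        return np.where((y <= 0.0) & (dy < 0.0), 0.0, dy)

    breaks = sorted({0.0, *(b for b in t_breaks if 0.0 < b < t_end), t_end})
    y = np.asarray(y0, dtype=float).copy()
    saved = {0.0: y.copy()}
    for a_, b_ in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(round((b_ - a_) / h)))
        hh = (b_ - a_) / n
        t = a_
        for _ in range(n):
            k1 = f(t, y)
            k2 = f(t + hh / 2, y + hh / 2 * k1)
            k3 = f(t + hh / 2, y + hh / 2 * k2)
            k4 = f(t + hh, y + hh * k3)
            y = y + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += hh
        saved[b_] = y.copy()
    return saved


def min_total_flux_bruteforce(A, lb, ub, obj_cutoff=999.0):
    """Minimal total flux over the vertices of {v : A v = 0, lb<=v<=ub}.

    Works on the irreversible (all lb >= 0 except fixed equalities)
    formulation.  Columns with lb == ub are constants; every vertex with a
    free variable pinned at a huge upper bound would exceed ``obj_cutoff``
    and is skipped, so only lower-bound (zero) nonbasic assignments are
    enumerated: choose a basis of free columns, solve, keep bound-feasible
    solutions.  Returns (best objective, best full flux vector).
    """
    A = np.asarray(A, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = A.shape[1]
    fixed = np.isclose(lb, ub)
    free_idx = [j for j in range(n) if not fixed[j]]
    v_fixed = np.where(fixed, lb, 0.0)
    b = -A @ v_fixed
    m = np.linalg.matrix_rank(A[:, free_idx]) if free_idx else 0

    best_obj, best_v = np.inf, None
    for basis in combinations(free_idx, m):
        B = A[:, basis]
        x, residual, rank, _ = np.linalg.lstsq(B, b, rcond=None)
        if np.linalg.norm(A[:, basis] @ x - b) > 1e-8:
            continue
        v = v_fixed.copy()
        v[list(basis)] = x
        if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
            continue
        obj = float(np.sum(v))
        if obj < best_obj:
            best_obj, best_v = obj, v
    return best_obj, best_v


def split_irreversible_matrix(model):
    """Independent irreversible split (forward column per reaction,
    backward column per reversible reaction) for the brute-force oracle."""
    cols, lbs, ubs = [], [], []
    for j in range(model.n_reactions):
        lo, hi = model.lb[j], model.ub[j]
        cols.append(model.S[:, j])
        lbs.append(max(lo, 0.0))
        ubs.append(max(hi, 0.0))
        if lo < 0:
            cols.append(-model.S[:, j])
            lbs.append(max(-hi, 0.0))
            ubs.append(-lo)
    return np.column_stack(cols), np.array(lbs), np.array(ubs)
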