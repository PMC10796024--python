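"""Freidlin-Wentzell transition actions and minimum-action paths.

For small noise, the probability of a fluctuation path ``x(t)`` connecting
two attractors scales as ``exp(-S/2d)`` with the action

    S[x] = 1/2 * integral_0^T || dx/dt - f(x) ||^2 dt.

Minimizing S over paths with fixed endpoints yields the most probable
transition route and its cost.  For gradient systems ``f = -grad V`` the
minimal uphill action equals ``2 * (V(saddle) - V(start))``, which the test
suite uses as an independent oracle.

Paths here are discretized on ``L`` nodes with a (possibly non-uniform)
time grid; the action uses midpoint quadrature.  Minimization is
bound-constrained (abundances must stay non-negative), runs over a schedule
of total times ``T`` keeping the best result, and re-meshes the time grid to
concentrate nodes where the path moves fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dynamics import GLVSystem


@dataclass
class TransitionPath:
    """Discretized path with its Freidlin-Wentzell action."""

    nodes: np.ndarray      # (L, N)
    times: np.ndarray      # (L,)
    action: float
    constrained: bool = True
    converged: bool = True
    grad_norm: float = 0.0

    @property
    def L(self) -> int:
        return len(self.nodes)

    @property
    def T(self) -> float:
        return float(self.times[-1] - self.times[0])

    def resample(self, L: int) -> "TransitionPath":
        """Linear re-interpolation onto L uniformly spaced times."""
        t_new = np.linspace(self.times[0], self.times[-1], L)
        nodes = np.column_stack(
            [np.interp(t_new, self.times, self.nodes[:, i])
             for i in range(self.nodes.shape[1])]
        )
        return TransitionPath(nodes=nodes, times=t_new, action=self.action,
                              constrained=self.constrained,
                              converged=self.converged,
                              grad_norm=self.grad_norm)


def system_functions(net, params, gammas=None):
    """Drift and Jacobian callables for a compiled network system."""
    system = GLVSystem(net, params, gammas)
    return system.drift, system.jacobian


def action(nodes, times, f) -> float:
    """Midpoint-quadrature action of a discretized path.

    Zero iff the path solves ``dx/dt = f(x)`` at every quadrature point.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    times = np.asarray(times, dtype=float)
    if len(nodes) < 2:
        raise ValueError("a path needs at least two nodes")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing (zero-length segment)")
    v = np.diff(nodes, axis=0) / dt[:, None]
    mids = 0.5 * (nodes[1:] + nodes[:-1])
    fm = np.array([f(m) for m in mids])
    r = v - fm
    return float(0.5 * np.sum(np.sum(r * r, axis=1) * dt))


def action_refined(nodes, times, f, factor: int = 4) -> float:
    """Action of the piecewise-linear path on a ``factor``-x finer grid.

    Guards against the coarse-grid degeneracy in which a single long segment
    hops a barrier at spuriously low midpoint-quadrature cost: refining the
    quadrature makes such a segment pay the full cost of crawling through
    the barrier region at near-zero velocity.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    times = np.asarray(times, dtype=float)
    t_fine = np.unique(np.concatenate(
        [np.linspace(times[k], times[k + 1], factor + 1)
         for k in range(len(times) - 1)]
    ))
    fine = np.column_stack(
        [np.interp(t_fine, times, nodes[:, i]) for i in range(nodes.shape[1])]
    )
    return action(fine, t_fine, f)


def _action_and_grad(interior, x0, x1, times, f, jac):
    L = len(times)
    N = len(x0)
    nodes = np.vstack([x0, interior.reshape(L - 2, N), x1])
    dt = np.diff(times)
    v = np.diff(nodes, axis=0) / dt[:, None]
    mids = 0.5 * (nodes[1:] + nodes[:-1])
    fm = np.array([f(m) for m in mids])
    r = v - fm
    S = 0.5 * np.sum(np.sum(r * r, axis=1) * dt)
    # gradient wrt interior nodes: segments k-1 and k touch node k
    Jr = np.array([jac(m).T @ rk for m, rk in zip(mids, r)])
    g = np.zeros((L, N))
    g[1:] += r - 0.5 * dt[:, None] * Jr
    g[:-1] += -r - 0.5 * dt[:, None] * Jr
    return S, g[1:-1].ravel()


def _remesh(nodes, times):
    """Equidistribute arc length: concentrate time nodes where motion is fast."""
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1) + 1e-12
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0.0, cum[-1], len(times))
    t_new = np.interp(s_new, cum, times)
    # keep strict monotonicity
    t_new = np.maximum.accumulate(t_new)
    eps = 1e-9 * (times[-1] - times[0])
    for i in range(1, len(t_new)):
        if t_new[i] <= t_new[i - 1]:
            t_new[i] = t_new[i - 1] + eps
    nodes_new = np.column_stack(
        [np.interp(t_new, times, nodes[:, i]) for i in range(nodes.shape[1])]
    )
    return nodes_new, t_new


def minimize_action(
    x_i,
    x_j,
    f,
    jac,
    L: int = 20,
    T_schedule=(20.0, 50.0, 100.0, 200.0),
    constrained: bool = True,
    waypoint=None,
    via=None,
    seed: int = 0,
    n_remesh: int = 1,
    maxiter: int = 500,
) -> TransitionPath:
    """Minimum-action path between two states.

    Optimizes the interior nodes of an ``L``-node path from ``x_i`` to
    ``x_j`` (endpoints fixed) with L-BFGS-B, subject to node non-negativity
    when ``constrained``.  For each total time ``T`` in the schedule the
    path is optimized on a uniform grid, re-meshed ``n_remesh`` times by
    arc-length equidistribution and re-optimized; the best result over the
    schedule is returned, ranked by the refined-quadrature action (see
    :func:`action_refined`).  The initial path is a straight line (through
    ``waypoint`` if given) plus one seeded perturbed restart; ``via`` may
    list additional candidate way-states (e.g. coexisting attractors) that
    seed extra bent initial paths, letting the optimizer discover indirect
    corridors the straight line misses.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    N = len(x_i)
    if np.allclose(x_i, x_j):
        times = np.linspace(0.0, float(T_schedule[0]), L)
        return TransitionPath(np.tile(x_i, (L, 1)), times, 0.0, constrained)
    rng = np.random.default_rng(seed)

    def _bent(w):
        w = np.asarray(w, dtype=float)
        half = (L + 1) // 2
        s1 = np.linspace(0.0, 1.0, half)[:, None]
        s2 = np.linspace(0.0, 1.0, L - half + 1)[:, None]
        return np.vstack([(1 - s1) * x_i + s1 * w,
                          ((1 - s2) * w + s2 * x_j)[1:]])

    s = np.linspace(0.0, 1.0, L)[:, None]
    base = (1 - s) * x_i + s * x_j if waypoint is None else _bent(waypoint)
    scale = 0.1 * np.max(np.abs(x_j - x_i))
    inits = [base]
    pert = base + rng.normal(0.0, scale, size=base.shape)
    pert[0], pert[-1] = x_i, x_j
    if constrained:
        pert = np.clip(pert, 0.0, None)
    inits.append(pert)
    if via is not None:
        via_list = [via] if np.ndim(via) == 1 else list(via)
        inits.extend(_bent(w) for w in via_list)

    best = None
    bounds = [(0.0, None)] * ((L - 2) * N) if constrained else None
    for T in T_schedule:
        for init in inits:
            nodes = init.copy()
            times = np.linspace(0.0, float(T), L)
            for round_ in range(n_remesh + 1):
                res = optimize.minimize(
                    _action_and_grad,
                    nodes[1:-1].ravel(),
                    args=(x_i, x_j, times, f, jac),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
                )
                nodes = np.vstack([x_i, res.x.reshape(L - 2, N), x_j])
                if round_ < n_remesh:
                    nodes, times = _remesh(nodes, times)
            S = action_refined(nodes, times, f)
            cand = TransitionPath(
                nodes=nodes, times=times, action=S, constrained=constrained,
                converged=bool(res.success),
                grad_norm=float(np.max(np.abs(res.jac))),
            )
            if best is None or cand.action < best.action:
                best = cand
    return best


def indirect_path(x_i, x_mid, x_j, f, jac, L: int = 20, **kwargs) -> TransitionPath:
    """Transition path forced through an intermediate attractor.

    Concatenates the minimum-action paths ``x_i -> x_mid`` and
    ``x_mid -> x_j``, resamples to ``L`` nodes total and reports the action
    of the resampled path (same discretized functional as a direct L-node
    path, so the indirect action can never fall below a fully optimized
    direct one).
    """
    if x_mid is None:
        raise ValueError("indirect path requires an intermediate state")
    leg1 = minimize_action(x_i, x_mid, f, jac, L=L, **kwargs)
    leg2 = minimize_action(x_mid, x_j, f, jac, L=L, **kwargs)
    t2 = leg2.times - leg2.times[0] + leg1.times[-1]
    nodes = np.vstack([leg1.nodes, leg2.nodes[1:]])
    times = np.concatenate([leg1.times, t2[1:]])
    full = TransitionPath(nodes=nodes, times=times, action=np.nan,
                          constrained=leg1.constrained,
                          converged=leg1.converged and leg2.converged)
    out = full.resample(L)
    out.action = action_refined(out.nodes, out.times, f)
    return out


def path_distance(p_direct: TransitionPath, p_indirect: TransitionPath) -> float:
    """Squared-Euclidean path distance PD = sum_i ||y_i^dir - y_i^ind||^2.

    Paths with differing node counts are resampled to the direct path's L.
    """
    a, b = p_direct, p_indirect
    if a.L != b.L:
        b = b.resample(a.L)
    return float(np.sum((a.nodes - b.nodes) ** 2))


def action_asymmetry(x_i, x_j, f, jac, **kwargs) -> float:
    """Forward-minus-backward minimum action, dS = S(i->j) - S(j->i).

    Negative values mean the ``i -> j`` transition is the easier direction.
    """
    fwd = minimize_action(x_i, x_j, f, jac, **kwargs)
    bwd = minimize_action(x_j, x_i, f, jac, **kwargs)
    return fwd.action - bwd.action


def normalize_path_heatmap(path: TransitionPath) -> np.ndarray:
    """Per-species min-max normalization of a path to [0, 1].

    Species whose abundance is constant along the path map to zero.
    """
    nodes = path.nodes
    lo = nodes.min(axis=0)
    hi = nodes.max(axis=0)
    span = hi - lo
    out = np.zeros_like(nodes)
    ok = span > 0
    out[:, ok] = (nodes[:, ok] - lo[ok]) / span[ok]
    return out
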