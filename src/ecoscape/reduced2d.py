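"""Closed-form analysis of the two-dimensional mean-field model.

Aggregating plants and pollinators into single effective abundances P', A'
with mean mutualistic strengths <gammaP>, <gammaA> gives

    dP'/dt = alpha P' - beta P'^2 + <gP> A' / (1 + h <gP> A') * P' + mu
    dA'/dt = alpha A' - beta A'^2 - kappa A' + <gA> P' / (1 + h <gA> P') * A' + mu

With mu ~ 0 the fixed points are available in closed form: the origin, the
plant-free point (0, (alpha-kappa)/beta), the pollinator-free "low" point
(alpha/beta, 0) and up to two interior points whose A' solves a quadratic
q1 A'^2 + q2 A' + q3 = 0.  Linear stability is also closed-form; the
headline property is that this 2-D model admits at most two stable states
(high and low) — it cannot produce the intermediate state, which is why the
full multidimensional network model is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .networks import BipartiteNetwork, ModelParameters, build_gamma


@dataclass
class ReducedParams:
    """Parameters of the 2-D mean-field model (all non-negative)."""

    alpha: float = 0.3
    beta: float = 1.0
    kappa: float = 1.07
    h: float = 0.2
    mu: float = 0.0
    gammaP_mean: float = 1.0   # <gammaP>: strength plants receive
    gammaA_mean: float = 1.0   # <gammaA>: strength pollinators receive

    def __post_init__(self):
        for name in ("alpha", "beta", "kappa", "h", "mu",
                     "gammaP_mean", "gammaA_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "ReducedParams":
        from dataclasses import replace as _replace
        return _replace(self, **kw)


def reduce_network(net: BipartiteNetwork, params: ModelParameters) -> ReducedParams:
    """Effective 2-D parameters implied by a full network.

    The mean mutualistic strengths are the species-averaged row sums of the
    directed strength matrices (mean per-capita gain a species receives).
    """
    g = build_gamma(net, params)
    return ReducedParams(
        alpha=float(np.mean(params.alpha_P)),
        beta=float(np.mean(params.beta_intra_P)),
        kappa=float(np.mean(params.kappa)),
        h=params.h,
        mu=params.mu_P,
        gammaP_mean=float(g.gamma_PA.sum(axis=1).mean()),
        gammaA_mean=float(g.gamma_AP.sum(axis=1).mean()),
    )


def drift_2d(state, rp: ReducedParams) -> np.ndarray:
    """Vector field of the 2-D mean-field model."""
    P, A = state
    gP, gA = rp.gammaP_mean, rp.gammaA_mean
    dP = (rp.alpha * P - rp.beta * P**2
          + gP * A / (1 + rp.h * gP * A) * P + rp.mu)
    dA = (rp.alpha * A - rp.beta * A**2 - rp.kappa * A
          + gA * P / (1 + rp.h * gA * P) * A + rp.mu)
    return np.array([dP, dA])


def jacobian_2d(state, rp: ReducedParams) -> np.ndarray:
    P, A = state
    gP, gA = rp.gammaP_mean, rp.gammaA_mean
    mP = gP * A / (1 + rp.h * gP * A)
    mA = gA * P / (1 + rp.h * gA * P)
    return np.array([
        [rp.alpha - 2 * rp.beta * P + mP,
         P * gP / (1 + rp.h * gP * A) ** 2],
        [A * gA / (1 + rp.h * gA * P) ** 2,
         rp.alpha - rp.kappa - 2 * rp.beta * A + mA],
    ])


@dataclass
class FixedPoint2D:
    P: float
    A: float
    kind: str            # origin | plant_free | pollinator_free | interior_low | interior_high
    stable: bool = False
    eigenvalues: tuple = None


def quadratic_coefficients(rp: ReducedParams):
    """Coefficients (q1, q2, q3) of the interior-equilibrium quadratic in A'."""
    a, b, h = rp.alpha, rp.beta, rp.h
    gP, gA = rp.gammaP_mean, rp.gammaA_mean
    q1 = b**2 * h * gP + h**2 * gP * gA * a * b + h * b * gP * gA
    q2 = (b * (h * gA * a + b) - a * h * gP * gA - gP * gA
          + (rp.kappa - a) * (h * gP * b + h**2 * gP * gA * a + h * gP * gA))
    q3 = (rp.kappa - a) * (h * gA * a + b) - gA * a
    return q1, q2, q3


def _interior_P(A, rp):
    gP = rp.gammaP_mean
    return (rp.alpha + gP * A / (1 + rp.h * gP * A)) / rp.beta


def fixed_points_2d(rp: ReducedParams, include_diagnostics: bool = False):
    """All fixed points of the mu ~ 0 reduced model.

    Returns the real non-negative fixed points; with
    ``include_diagnostics`` also returns a dict holding the quadratic
    discriminant and any excluded (complex/negative) interior roots.
    """
    a, b = rp.alpha, rp.beta
    pts = [
        FixedPoint2D(0.0, 0.0, "origin"),
        FixedPoint2D(a / b, 0.0, "pollinator_free"),
    ]
    if a - rp.kappa > 0:
        pts.append(FixedPoint2D(0.0, (a - rp.kappa) / b, "plant_free"))
    q1, q2, q3 = quadratic_coefficients(rp)
    diag = {"q": (q1, q2, q3)}
    if abs(q1) < 1e-14:
        # degenerate (h = 0 or gammaP = 0): linear equation q2 A + q3 = 0
        roots = [-q3 / q2] if abs(q2) > 1e-14 else []
        diag["discriminant"] = np.nan
    else:
        disc = q2**2 - 4 * q1 * q3
        diag["discriminant"] = disc
        roots = []
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-q2 - sq) / (2 * q1), (-q2 + sq) / (2 * q1)]
            if abs(roots[1] - roots[0]) < 1e-6:
                roots = roots[:1]  # saddle-node double root
    roots = sorted(roots)
    excluded = [r for r in roots if r <= 0]
    kept = [r for r in roots if r > 0]
    diag["excluded_interior_roots"] = excluded
    kinds = (["interior_high"] if len(kept) == 1
             else ["interior_low", "interior_high"])
    for r, kind in zip(kept, kinds):
        pts.append(FixedPoint2D(_interior_P(r, rp), r, kind))
    for fp in pts:
        eigs = np.linalg.eigvals(jacobian_2d((fp.P, fp.A), rp))
        fp.eigenvalues = tuple(eigs)
        fp.stable = bool(np.max(eigs.real) < 0)
    if include_diagnostics:
        return pts, diag
    return pts


def stability_2d(fp: FixedPoint2D, rp: ReducedParams,
                 tol: float = 1e-8) -> bool:
    """Stability by closed-form criterion, cross-checked numerically.

    Origin and the plant-free point are always unstable (alpha > 0); the
    pollinator-free point is stable iff
    ``kappa > alpha + <gA>(alpha/beta) / (1 + h <gA> alpha/beta)``; an
    interior point is stable iff ``p1 A'^2 + p2 A' + p3 > 0``.  A
    disagreement with the numeric Jacobian eigenvalues raises.
    """
    a, b, h = rp.alpha, rp.beta, rp.h
    gP, gA = rp.gammaP_mean, rp.gammaA_mean
    if fp.kind in ("origin", "plant_free"):
        closed = False if a > 0 else None
    elif fp.kind == "pollinator_free":
        x = gA * a / b
        closed = rp.kappa > a + x / (1 + h * x)
    else:
        p1 = (b * h * gP + h**2 * gP * gA * a + h * gP * gA) ** 2
        p2 = 2 * (h * gP * b + h**2 * gP * gA * a + h * gP * gA) * (b + h * gA * a)
        p3 = (h * gA * a + b) ** 2 - gA * gP
        closed = p1 * fp.A**2 + p2 * fp.A + p3 > 0
    numeric = bool(np.max(np.real(fp.eigenvalues)) < 0)
    if closed is not None and closed != numeric:
        # borderline cases (eigenvalue within tol of zero) are tolerated
        if np.min(np.abs(np.real(fp.eigenvalues))) > tol:
            raise AssertionError(
                f"closed-form stability ({closed}) disagrees with numeric "
                f"eigenvalues {fp.eigenvalues} at {fp.kind}"
            )
    return numeric


def saddle_node_kappa(rp: ReducedParams):
    """Kappa at which the two interior equilibria merge (discriminant = 0).

    The discriminant is quadratic in kappa; the smaller root is returned
    (the larger one corresponds to a negative A' and is discarded).  Returns
    NaN when no saddle-node exists for positive kappa.
    """
    # q2 = u2 + kappa * v2, q3 = u3 + kappa * v3, q1 constant
    base = rp.replace(kappa=0.0)
    q1, u2, u3 = quadratic_coefficients(base)
    one = rp.replace(kappa=1.0)
    _, w2, w3 = quadratic_coefficients(one)
    v2, v3 = w2 - u2, w3 - u3
    # disc(kappa) = (u2 + k v2)^2 - 4 q1 (u3 + k v3)
    A = v2**2
    B = 2 * u2 * v2 - 4 * q1 * v3
    C = u2**2 - 4 * q1 * u3
    if abs(A) < 1e-300:
        return np.nan
    disc = B**2 - 4 * A * C
    if disc < 0:
        return np.nan
    roots = sorted([(-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A)])
    pos = [r for r in roots if r > 0]
    return float(pos[0]) if pos else np.nan


def double_root_A(rp: ReducedParams) -> float:
    """Closed-form A' at the saddle-node (the double root of the quadratic)."""
    a, b, h = rp.alpha, rp.beta, rp.h
    gP, gA = rp.gammaP_mean, rp.gammaA_mean
    num = np.sqrt(gA * gP**3) - b * gP - a * h * gA * gP
    den = h * gA * gP**2 + b * h * gP**2 + a * h**2 * gA * gP**2
    return float(num / den)


def kappa_bifurcation_2d(rp: ReducedParams, kappa_range, n: int = 201):
    """Interior-branch structure along kappa.

    Returns (table, kappa_star): a list of dicts with the number of positive
    interior roots and the stable branches at each kappa, plus the
    saddle-node kappa (NaN when absent in the range).  The positive-root
    count follows the 1 -> 2 -> 1 -> 0 pattern when the saddle-node and the
    root sign changes all occur inside the range.
    """
    k_lo, k_hi = kappa_range
    ks = np.linspace(k_lo, k_hi, n)
    rows = []
    for k in ks:
        pts = fixed_points_2d(rp.replace(kappa=float(k)))
        interior = [p for p in pts if p.kind.startswith("interior")]
        rows.append({
            "kappa": float(k),
            "n_interior": len(interior),
            "n_stable_interior": sum(p.stable for p in interior),
            "branches": [(p.P, p.A, p.stable) for p in pts],
        })
    k_star = saddle_node_kappa(rp)
    if not (k_lo <= k_star <= k_hi):
        k_star = np.nan
    return rows, k_star


def count_stable_states(rp: ReducedParams) -> int:
    """Number of stable fixed points of the reduced model (at most 2)."""
    return sum(fp.stable for fp in fixed_points_2d(rp))


def numeric_fixed_points_2d(rp: ReducedParams, grid: int = 12, lim: float = 4.0):
    """Independent numeric root-finder from a dense grid of starts.

    Used as a cross-check that no interior equilibrium is missed by the
    closed forms.  Returns unique non-negative roots.
    """
    roots = []
    for P0 in np.linspace(0, lim, grid):
        for A0 in np.linspace(0, lim, grid):
            sol = optimize.root(lambda s: drift_2d(s, rp), [P0, A0],
                                method="hybr")
            if not sol.success:
                continue
            x = sol.x
            if np.min(x) < -1e-8 or np.max(np.abs(drift_2d(x, rp))) > 1e-9:
                continue
            x = np.clip(x, 0.0, None)
            if not any(np.max(np.abs(x - r)) < 1e-6 for r in roots):
                roots.append(x)
    return roots
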