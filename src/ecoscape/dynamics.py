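"""Deterministic dynamics of mutualistic plant-pollinator networks.

The model is a generalized Lotka-Volterra system with a saturating
(Holling type II) mutualistic benefit.  For plant ``i`` and pollinator ``j``::

    dP_i/dt = alpha_i P_i - sum_k beta_ik P_i P_k
              + P_i * m_i / (1 + h m_i) + mu_P,      m_i = sum_l gamma_PA[i,l] A_l
    dA_j/dt = (alpha_j - kappa_j) A_j - sum_m beta_jm A_j A_m
              + A_j * v_j / (1 + h v_j) + mu_A,      v_j = sum_n gamma_AP[j,n] P_n

States are ordered ``[P_1..P_NP, A_1..A_NA]``.  The module finds attractors
by multi-start integration with a Newton polish, classifies them into
high / intermediate / low abundance states, and tabulates multistability
scenarios under random pollinator removal and on parameter grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .networks import (
    BipartiteNetwork,
    GammaMatrices,
    ModelParameters,
    build_gamma,
    remove_pollinators,
    _per_species,
)

#: abundances below this are treated as extinct throughout the package
EXTINCTION_THRESHOLD = 1e-3

SCENARIO_CODES = ("H", "HI", "HL", "HIL", "I", "IL", "L", "T", "other")


class GLVSystem:
    """Compiled vector field for one (network, parameters) pair.

    Precomputes per-species parameter vectors and interaction matrices so the
    drift can be evaluated on batches of states (rows of a matrix), which the
    attractor search and the Langevin integrators rely on.
    """

    def __init__(
        self,
        net: BipartiteNetwork,
        params: ModelParameters,
        gammas: GammaMatrices | None = None,
    ):
        self.net = net
        self.params = params
        self.gammas = gammas if gammas is not None else build_gamma(net, params)
        nP, nA = net.n_plants, net.n_pollinators
        self.n_plants, self.n_pollinators = nP, nA
        self.n = nP + nA
        self.alpha_P = _per_species(params.alpha_P, nP, "alpha_P")
        self.alpha_A = _per_species(params.alpha_A, nA, "alpha_A")
        self.bintra_P = _per_species(params.beta_intra_P, nP, "beta_intra_P")
        self.bintra_A = _per_species(params.beta_intra_A, nA, "beta_intra_A")
        self.binter_P = float(params.beta_inter_P)
        self.binter_A = float(params.beta_inter_A)
        self.kappa = _per_species(params.kappa, nA, "kappa")
        self.h = float(params.h)
        self.mu_P = float(params.mu_P)
        self.mu_A = float(params.mu_A)
        # full competition matrices, used by the Jacobian
        self.B_P = self.binter_P * (np.ones((nP, nP)) - np.eye(nP)) + np.diag(
            self.bintra_P
        )
        self.B_A = self.binter_A * (np.ones((nA, nA)) - np.eye(nA)) + np.diag(
            self.bintra_A
        )

    # -- vector field -----------------------------------------------------
    def drift_many(self, X: np.ndarray) -> np.ndarray:
        """Drift evaluated row-wise on a batch of states, shape (R, N)."""
        X = np.atleast_2d(X)
        nP = self.n_plants
        P, A = X[:, :nP], X[:, nP:]
        m = A @ self.gammas.gamma_PA.T
        v = P @ self.gammas.gamma_AP.T
        compP = (self.bintra_P - self.binter_P) * P + self.binter_P * P.sum(
            axis=1, keepdims=True
        )
        compA = (self.bintra_A - self.binter_A) * A + self.binter_A * A.sum(
            axis=1, keepdims=True
        )
        dP = P * (self.alpha_P - compP + m / (1.0 + self.h * m)) + self.mu_P
        dA = (
            A * (self.alpha_A - self.kappa - compA + v / (1.0 + self.h * v))
            + self.mu_A
        )
        return np.concatenate([dP, dA], axis=1)

    def drift(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("drift received a non-finite state")
        return self.drift_many(x[None, :])[0]

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the drift at a single state."""
        x = np.asarray(x, dtype=float)
        nP, nA = self.n_plants, self.n_pollinators
        P, A = x[:nP], x[nP:]
        gPA, gAP = self.gammas.gamma_PA, self.gammas.gamma_AP
        m = gPA @ A
        v = gAP @ P
        hm = 1.0 + self.h * m
        hv = 1.0 + self.h * v
        J = np.zeros((self.n, self.n))
        # plant block: d(dP_i)/dP_k
        JPP = -P[:, None] * self.B_P
        JPP[np.diag_indices(nP)] += (
            self.alpha_P - self.B_P @ P + m / hm
        )
        # d(dP_i)/dA_l : quotient rule on the Holling term
        JPA = (P / hm**2)[:, None] * gPA
        JAA = -A[:, None] * self.B_A
        JAA[np.diag_indices(nA)] += (
            self.alpha_A - self.kappa - self.B_A @ A + v / hv
        )
        JAP = (A / hv**2)[:, None] * gAP
        J[:nP, :nP] = JPP
        J[:nP, nP:] = JPA
        J[nP:, :nP] = JAP
        J[nP:, nP:] = JAA
        return J


def drift(x, net, params, gammas=None) -> np.ndarray:
    """Time derivative of the abundance vector (see module docstring)."""
    return GLVSystem(net, params, gammas).drift(x)


def jacobian(x, net, params, gammas=None) -> np.ndarray:
    """Analytic Jacobian of the drift at ``x``."""
    return GLVSystem(net, params, gammas).jacobian(x)


# -- attractors -----------------------------------------------------------

@dataclass
class Attractor:
    """A linearly stable fixed point of the deterministic dynamics."""

    state: np.ndarray
    label: str = "other"
    weight: float = 0.0
    n_alive_pollinators: int = 0
    jacobian_spectrum: np.ndarray = field(default=None)

    @property
    def total_abundance(self) -> float:
        return float(self.state.sum())


@dataclass
class AttractorSet:
    attractors: list
    n_nonconverged: int = 0
    scenario: str = "other"

    def __iter__(self):
        return iter(self.attractors)

    def __len__(self):
        return len(self.attractors)

    def by_label(self, label: str) -> Attractor:
        for a in self.attractors:
            if a.label == label:
                return a
        raise KeyError(f"no attractor labelled {label!r}")


def _integrate_batch(system: GLVSystem, X0: np.ndarray, t_max: float,
                     dt: float = 0.05, check_every: int = 200,
                     settle_tol: float = 1e-9) -> np.ndarray:
    """Fixed-step RK4 relaxation of a batch of initial conditions.

    Abundances are clipped at zero after every step (the non-negative orthant
    is forward invariant for the exact flow; clipping removes numerical
    undershoot).
    """
    X = np.clip(np.array(X0, dtype=float), 0.0, None)
    n_steps = int(np.ceil(t_max / dt))
    f = system.drift_many
    for k in range(n_steps):
        k1 = f(X)
        k2 = f(np.clip(X + 0.5 * dt * k1, 0.0, None))
        k3 = f(np.clip(X + 0.5 * dt * k2, 0.0, None))
        k4 = f(np.clip(X + dt * k3, 0.0, None))
        X = X + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(X, 0.0, None, out=X)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("trajectory diverged during relaxation")
        if (k + 1) % check_every == 0:
            if np.max(np.abs(f(X))) < settle_tol:
                break
    return X


def _cluster_rows(X: np.ndarray, radius: float) -> list[np.ndarray]:
    """Greedy clustering of row vectors by infinity-norm distance."""
    groups: list[list[int]] = []
    reps: list[np.ndarray] = []
    for i, row in enumerate(X):
        for g, rep in enumerate(reps):
            if np.max(np.abs(row - rep)) < radius:
                groups[g].append(i)
                break
        else:
            groups.append([i])
            reps.append(row)
    return [np.array(g) for g in groups]


def find_attractors(
    net: BipartiteNetwork,
    params: ModelParameters,
    n_starts: int = 50,
    seed: int = 0,
    t_max: float = 400.0,
    tol: float = 1e-8,
    merge_radius: float = 1e-3,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    x_hi: float | None = None,
    gammas: GammaMatrices | None = None,
    sampler: str = "block",
) -> AttractorSet:
    """Locate stable fixed points by multi-start relaxation + Newton polish.

    Initial conditions cover the full abundance range: with the default
    ``sampler='block'``, each start draws two independent block amplitudes
    ``rP, rA ~ U(0, x_hi)`` (default ``x_hi = max(alpha/beta, 3)``) and
    samples plants/pollinators uniformly from ``[0, rP]`` / ``[0, rA]``, so
    starts with abundant plants but scarce pollinators (the
    intermediate/low basins) are well represented; ``sampler='uniform'``
    draws plain uniform states on ``[0, x_hi]^N``.  Endpoints
    of the deterministic flow are clustered within ``merge_radius`` (infinity
    norm), polished by a Newton solve and verified: residual drift below
    ``tol`` and Jacobian spectral abscissa negative.  Basin weights ``phi_j``
    are the fraction of starts reaching each attractor; non-convergent or
    unstable endpoints are excluded from the weights and counted.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    system = GLVSystem(net, params, gammas)
    rng = np.random.default_rng(seed)
    if x_hi is None:
        ratios = [
            float(np.max(a) / np.min(b))
            for a, b in ((system.alpha_P, system.bintra_P),
                         (system.alpha_A, system.bintra_A))
            if len(a) > 0
        ]
        x_hi = max(ratios + [3.0])
    if sampler == "uniform":
        X0 = rng.uniform(0.0, x_hi, size=(n_starts, system.n))
    elif sampler == "block":
        amps = rng.uniform(0.0, x_hi, size=(n_starts, 2))
        U = rng.random((n_starts, system.n))
        X0 = np.concatenate(
            [
                U[:, : system.n_plants] * amps[:, :1],
                U[:, system.n_plants:] * amps[:, 1:],
            ],
            axis=1,
        )
    else:
        raise ValueError("sampler must be 'block' or 'uniform'")
    X_end = _integrate_batch(system, X0, t_max)

    attractors: list[Attractor] = []
    n_bad = 0
    for idx in _cluster_rows(X_end, merge_radius):
        rep = X_end[idx].mean(axis=0)
        sol = optimize.root(system.drift, rep, jac=system.jacobian, method="hybr")
        x_star = np.clip(sol.x, 0.0, None)
        resid = np.max(np.abs(system.drift(x_star)))
        if not sol.success or resid > tol or np.min(x_star) < -1e-9:
            n_bad += len(idx)
            continue
        if np.max(np.abs(x_star - rep)) > 10 * merge_radius + 0.05 * np.max(rep):
            # Newton jumped away from the relaxed endpoint (slow transient)
            n_bad += len(idx)
            continue
        eigs = np.linalg.eigvals(system.jacobian(x_star))
        if np.max(eigs.real) >= 0:
            n_bad += len(idx)
            continue
        # merge with an already accepted attractor if the polish landed there
        for a in attractors:
            if np.max(np.abs(a.state - x_star)) < merge_radius:
                a.weight += len(idx)
                break
        else:
            n_alive = int(
                np.sum(x_star[system.n_plants:] > extinction_threshold)
            )
            attractors.append(
                Attractor(
                    state=x_star,
                    weight=float(len(idx)),
                    n_alive_pollinators=n_alive,
                    jacobian_spectrum=eigs,
                )
            )
    if n_bad:
        warnings.warn(
            f"{n_bad}/{n_starts} starts did not converge to a verified "
            "attractor and were excluded from basin weights",
            stacklevel=2,
        )
    total = sum(a.weight for a in attractors)
    if total > 0:
        for a in attractors:
            a.weight /= total
    _label_attractors(attractors, net.n_plants, extinction_threshold)
    aset = AttractorSet(attractors=attractors, n_nonconverged=n_bad)
    aset.scenario = scenario_code(attractors)
    return aset


def classify_state(
    state: np.ndarray,
    context: list[np.ndarray],
    n_plants: int,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> str:
    """Label a stable state as ``high`` / ``intermediate`` / ``low`` / ``other``.

    ``low`` iff every pollinator is extinct.  A state with some but fewer
    than half of the pollinators alive is ``intermediate`` (most pollinators
    lost, typically only the generalists persisting).  Among the remaining
    states (at least half the pollinators alive), the one with the largest
    total abundance in the coexisting ``context`` is ``high``; any other is
    ``other``.
    """
    atts = [Attractor(state=np.asarray(s, dtype=float)) for s in context]
    target = np.asarray(state, dtype=float)
    _label_attractors(atts, n_plants, extinction_threshold)
    for a in atts:
        if np.array_equal(a.state, target):
            return a.label
    raise ValueError("state must be a member of context")


def _label_attractors(attractors, n_plants: int, extinction_threshold: float):
    for a in attractors:
        pol = a.state[n_plants:]
        a.n_alive_pollinators = int(np.sum(pol > extinction_threshold))
    non_low = [a for a in attractors if a.n_alive_pollinators > 0]
    for a in attractors:
        if a.n_alive_pollinators == 0:
            a.label = "low"
    if not non_low:
        return
    n_pol = len(attractors[0].state) - n_plants
    majority = [a for a in non_low if a.n_alive_pollinators >= 0.5 * n_pol]
    for a in non_low:
        if a.n_alive_pollinators < 0.5 * n_pol:
            a.label = "intermediate"
    if majority:
        top = max(majority, key=lambda a: a.total_abundance)
        for a in majority:
            a.label = "high" if a is top else "other"


def scenario_code(attractors) -> str:
    """Map a multiset of attractor labels to a multistability scenario code.

    ``H``, ``HI``, ``HL``, ``HIL``, ``IL``, ``L`` follow the label multiset;
    ``T`` (tetrastability-like) covers two or more intermediate states; any
    other combination is ``other``.
    """
    labels = sorted(a.label for a in attractors)
    n_int = labels.count("intermediate")
    if n_int >= 2:
        return "T"
    if "other" in labels or not labels:
        return "other"
    key = (
        "H" * labels.count("high")
        + "I" * n_int
        + "L" * labels.count("low")
    )
    mapping = {
        "H": "H", "HI": "HI", "HL": "HL", "HIL": "HIL",
        "I": "I", "IL": "IL", "L": "L",
    }
    return mapping.get(key, "other")


def removal_census(
    net: BipartiteNetwork,
    params: ModelParameters,
    fractions,
    n_subnets: int = 100,
    seed: int = 0,
    **attractor_kw,
) -> pd.DataFrame:
    """Scenario proportions under random pollinator removal.

    For each removal fraction, generates ``n_subnets`` seeded sub-networks,
    finds their attractors and tabulates the proportion of each
    multistability scenario.  Returns a tidy frame with columns
    ``fraction``, ``scenario``, ``proportion``.
    """
    if n_subnets < 1:
        raise ValueError("n_subnets must be >= 1")
    rows = []
    base = np.random.default_rng(seed)
    for frac in fractions:
        counts = dict.fromkeys(SCENARIO_CODES, 0)
        for _ in range(n_subnets):
            sub_seed = int(base.integers(0, 2**31 - 1))
            sub = remove_pollinators(net, frac, seed=sub_seed)
            aset = find_attractors(sub, params, seed=sub_seed, **attractor_kw)
            counts[aset.scenario] += 1
        for code, c in counts.items():
            rows.append(
                {"fraction": frac, "scenario": code, "proportion": c / n_subnets}
            )
    return pd.DataFrame(rows)


def phase_diagram(
    net: BipartiteNetwork,
    params: ModelParameters,
    kappa_grid,
    gamma0_grid,
    **attractor_kw,
) -> pd.DataFrame:
    """Multistability scenario on a (kappa, gamma0) parameter grid.

    Returns a frame indexed by kappa with one column per gamma0 holding the
    scenario code of each cell.
    """
    kappa_grid = np.asarray(kappa_grid, dtype=float)
    gamma0_grid = np.asarray(gamma0_grid, dtype=float)
    if np.any(np.diff(kappa_grid) < 0) or np.any(np.diff(gamma0_grid) < 0):
        raise ValueError("parameter grids must be monotone increasing")
    codes = np.empty((len(kappa_grid), len(gamma0_grid)), dtype=object)
    for i, k in enumerate(kappa_grid):
        for j, g0 in enumerate(gamma0_grid):
            p = params.replace(kappa=k, gamma0=g0)
            aset = find_attractors(net, p, **attractor_kw)
            codes[i, j] = aset.scenario
    return pd.DataFrame(codes, index=kappa_grid, columns=gamma0_grid)
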