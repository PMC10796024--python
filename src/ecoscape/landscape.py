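"""Energy landscape via a truncated moment equation (TME) approximation.

For weak noise (diffusion ``d << 1``) the stationary density of the Langevin
dynamics around each attractor is approximated by a Gaussian whose mean is
the fixed point and whose covariance solves the stationary covariance ODE,
i.e. the continuous Lyapunov equation ``A Sigma + Sigma A^T + 2 d I = 0``
with ``A`` the Jacobian at the fixed point (third and higher moments are
truncated).  The global stationary density is a basin-weighted mixture of
these Gaussians and the potential is ``U = -ln p_ss``.

For visualisation and barrier measurement the N-dimensional mixture is
projected onto two biologically interpretable coordinates: the first
principal component of the plant-block mixture covariance (z1) and of the
pollinator-block mixture covariance (z2).  Barrier heights between basins
are read off the reduced 2-D landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .dynamics import AttractorSet, Attractor, GLVSystem
from .networks import BipartiteNetwork, ModelParameters


class StabilityError(ValueError):
    """Raised when a stationary covariance is requested at an unstable point."""


@dataclass
class GaussianComponent:
    """One Gaussian basin: mean, covariance and mixture weight."""

    mean: np.ndarray
    covariance: np.ndarray
    weight: float = 1.0
    label: str = "other"


@dataclass
class GaussianMixtureLandscape:
    """Weighted Gaussian mixture approximation of the stationary density."""

    components: list
    diffusion: float

    def __post_init__(self):
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"mixture weights must sum to 1 (got {total!r}); "
                "normalize before assembly"
            )

    @property
    def n_dim(self) -> int:
        return len(self.components[0].mean)

    def density(self, x: np.ndarray) -> float:
        """Stationary density p_ss(x) = sum_j phi_j N(x; mu_j, Sigma_j)."""
        x = np.asarray(x, dtype=float)
        p = 0.0
        for c in self.components:
            p += c.weight * _gauss_pdf(x, c.mean, c.covariance)
        return p

    def potential(self, x: np.ndarray) -> float:
        """U(x) = -ln p_ss(x)."""
        return -np.log(self.density(x))


def _gauss_pdf(x, mean, cov):
    n = len(mean)
    dx = x - mean
    L = linalg.cholesky(cov, lower=True)
    y = linalg.solve_triangular(L, dx, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(
        np.exp(-0.5 * (y @ y) - 0.5 * (n * np.log(2 * np.pi) + logdet))
    )


def stationary_moments(
    attractor,
    net: BipartiteNetwork = None,
    params: ModelParameters = None,
    d: float = 0.01,
    jacobian: np.ndarray = None,
) -> GaussianComponent:
    """Gaussian stationary moments of one basin.

    The mean is the fixed point itself; the covariance is the unique
    symmetric solution of ``A Sigma + Sigma A^T + 2 d I = 0``.  Either a
    (net, params) pair or a precomputed ``jacobian`` must be supplied.

    Raises
    ------
    StabilityError
        If the Jacobian has a non-negative spectral abscissa (no positive
        semidefinite stationary covariance exists).
    """
    if d <= 0:
        raise ValueError("diffusion d must be positive")
    state = attractor.state if isinstance(attractor, Attractor) else np.asarray(attractor, float)
    if jacobian is None:
        jacobian = GLVSystem(net, params).jacobian(state)
    eigs = np.linalg.eigvals(jacobian)
    if np.max(eigs.real) >= 0:
        raise StabilityError(
            "Jacobian spectral abscissa is non-negative "
            f"({np.max(eigs.real):.3g}); stationary covariance undefined"
        )
    sigma = linalg.solve_continuous_lyapunov(
        jacobian, -2.0 * d * np.eye(len(state))
    )
    sigma = 0.5 * (sigma + sigma.T)
    label = getattr(attractor, "label", "other")
    return GaussianComponent(mean=np.asarray(state, float), covariance=sigma,
                             weight=np.nan, label=label)


def assemble_mixture(components, weights, d: float = 0.01) -> GaussianMixtureLandscape:
    """Attach basin weights and build the mixture landscape.

    ``weights`` are the basin frequencies phi_j from the attractor search and
    must sum to 1 within 1e-12.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(components):
        raise ValueError("one weight per component required")
    comps = [
        GaussianComponent(c.mean, c.covariance, float(w), c.label)
        for c, w in zip(components, weights)
    ]
    return GaussianMixtureLandscape(components=comps, diffusion=d)


def mixture_from_attractors(
    aset: AttractorSet,
    net: BipartiteNetwork,
    params: ModelParameters,
    d: float = 0.01,
) -> GaussianMixtureLandscape:
    """Convenience: TME moments for every attractor + basin weights."""
    system = GLVSystem(net, params)
    comps = [
        stationary_moments(a, d=d, jacobian=system.jacobian(a.state))
        for a in aset
    ]
    return assemble_mixture(comps, [a.weight for a in aset], d=d)


# -- bipartite dimension reduction ---------------------------------------

@dataclass
class BipartiteProjection:
    """Two-coordinate projection: plant PC1 (z1) and pollinator PC1 (z2)."""

    w1_P: np.ndarray
    w1_A: np.ndarray

    @property
    def W(self) -> np.ndarray:
        """Block-diagonal (N, 2) projection matrix."""
        nP, nA = len(self.w1_P), len(self.w1_A)
        W = np.zeros((nP + nA, 2))
        W[:nP, 0] = self.w1_P
        W[nP:, 1] = self.w1_A
        return W

    def project(self, x: np.ndarray) -> np.ndarray:
        """Project full states (last axis N) to (z1, z2)."""
        return np.asarray(x, dtype=float) @ self.W


def mixture_marginal_moments(mix: GaussianMixtureLandscape, sl: slice):
    """Exact mean/covariance of a coordinate block of the mixture.

    Uses ``Sigma = sum_j phi_j (Sigma_j + mu_j mu_j^T) - mu mu^T`` on the
    block marginal of each component.
    """
    mu = sum(c.weight * c.mean[sl] for c in mix.components)
    cov = sum(
        c.weight
        * (c.covariance[sl, sl] + np.outer(c.mean[sl], c.mean[sl]))
        for c in mix.components
    ) - np.outer(mu, mu)
    return mu, 0.5 * (cov + cov.T)


def reduce_bipartite(
    mix: GaussianMixtureLandscape, net: BipartiteNetwork
) -> BipartiteProjection:
    """Leading principal component of each block of the mixture covariance.

    The sign of each PC is fixed so that the highest-total-abundance
    component mean projects to the largest coordinate, placing the high
    state in the upper-right corner of the reduced landscape.
    """
    nP = net.n_plants
    out = []
    for name, sl in (("plant", slice(0, nP)), ("pollinator", slice(nP, mix.n_dim))):
        _, cov = mixture_marginal_moments(mix, sl)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] <= 1e-300:
            raise ValueError(f"degenerate {name}-block covariance (zero leading eigenvalue)")
        out.append(evecs[:, -1])
    w1_P, w1_A = out
    top = max(mix.components, key=lambda c: c.mean.sum())
    rest = [c for c in mix.components if c is not top]
    ref = rest[0].mean if rest else np.zeros(mix.n_dim)
    if (top.mean[:nP] - ref[:nP]) @ w1_P < 0:
        w1_P = -w1_P
    if (top.mean[nP:] - ref[nP:]) @ w1_A < 0:
        w1_A = -w1_A
    return BipartiteProjection(w1_P=w1_P, w1_A=w1_A)


@dataclass
class ReducedLandscape:
    """Potential on a (z1, z2) grid with projected component means."""

    z1: np.ndarray
    z2: np.ndarray
    U: np.ndarray  # shape (len(z2), len(z1)); row = z2, col = z1
    means_2d: np.ndarray  # (M, 2) projected component means
    labels: list
    projection: BipartiteProjection = None

    def minima_indices(self) -> list[tuple[int, int]]:
        """Grid index (i2, i1) of the local minimum nearest each mean."""
        out = []
        for m in self.means_2d:
            i1 = int(np.argmin(np.abs(self.z1 - m[0])))
            i2 = int(np.argmin(np.abs(self.z2 - m[1])))
            # descend to the bottom of the local basin
            moved = True
            while moved:
                moved = False
                best = self.U[i2, i1]
                for d2, d1 in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    j2, j1 = i2 + d2, i1 + d1
                    if 0 <= j2 < len(self.z2) and 0 <= j1 < len(self.z1):
                        if self.U[j2, j1] < best:
                            best, i2, i1, moved = self.U[j2, j1], j2, j1, True
            out.append((i2, i1))
        return out


def reduced_potential(
    mix: GaussianMixtureLandscape,
    proj: BipartiteProjection,
    grid_size: int = 200,
    margin_sd: float = 4.0,
    bounds=None,
) -> ReducedLandscape:
    """Reduced 2-D landscape ``U(z1, z2) = -ln p_z``.

    Each component projects exactly to ``N(W^T mu_j, W^T Sigma_j W)``; the
    grid spans the projected means +- ``margin_sd`` projected standard
    deviations unless explicit ``bounds = ((z1lo, z1hi), (z2lo, z2hi))``
    are given.
    """
    W = proj.W
    mus = np.array([c.mean @ W for c in mix.components])
    covs = np.array([W.T @ c.covariance @ W for c in mix.components])
    sds = np.sqrt(np.maximum(covs[:, [0, 1], [0, 1]], 0.0))
    if bounds is None:
        lo = (mus - margin_sd * sds).min(axis=0)
        hi = (mus + margin_sd * sds).max(axis=0)
    else:
        (lo1, hi1), (lo2, hi2) = bounds
        lo, hi = np.array([lo1, lo2]), np.array([hi1, hi2])
    z1 = np.linspace(lo[0], hi[0], grid_size)
    z2 = np.linspace(lo[1], hi[1], grid_size)
    Z1, Z2 = np.meshgrid(z1, z2)
    pts = np.stack([Z1, Z2], axis=-1)
    p = np.zeros(Z1.shape)
    for c, m, S in zip(mix.components, mus, covs):
        Sinv = np.linalg.inv(S)
        det = np.linalg.det(S)
        dx = pts - m
        q = np.einsum("...i,ij,...j->...", dx, Sinv, dx)
        p += c.weight * np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))
    with np.errstate(divide="ignore"):
        U = -np.log(p)
    return ReducedLandscape(
        z1=z1, z2=z2, U=U, means_2d=mus,
        labels=[c.label for c in mix.components], projection=proj,
    )


# -- saddles and barriers --------------------------------------------------

@dataclass
class SaddleResult:
    saddle_index: tuple
    U_saddle: float
    merged: bool = False


def _connected(mask: np.ndarray, a: tuple, b: tuple) -> bool:
    """4-connectivity flood fill on a boolean grid."""
    from collections import deque

    if not (mask[a] and mask[b]):
        return False
    seen = np.zeros_like(mask, dtype=bool)
    dq = deque([a])
    seen[a] = True
    while dq:
        i2, i1 = dq.popleft()
        if (i2, i1) == b:
            return True
        for d2, d1 in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j2, j1 = i2 + d2, i1 + d1
            if (
                0 <= j2 < mask.shape[0]
                and 0 <= j1 < mask.shape[1]
                and mask[j2, j1]
                and not seen[j2, j1]
            ):
                seen[j2, j1] = True
                dq.append((j2, j1))
    return False


def find_saddle(
    reduced: ReducedLandscape, basin_i: int, basin_j: int
) -> SaddleResult:
    """Lowest crossing level between two basins (grid minimax).

    Threshold bisection on sub-level-set connectivity: the saddle level is
    the smallest ``c`` such that the two minima lie in one connected
    component of ``{U <= c}``.  If the minima already coincide the basins
    are merged and a zero barrier is flagged.
    """
    mins = reduced.minima_indices()
    a, b = mins[basin_i], mins[basin_j]
    if a == b:
        return SaddleResult(saddle_index=a, U_saddle=float(reduced.U[a]), merged=True)
    levels = np.unique(reduced.U[np.isfinite(reduced.U)])
    floor = max(reduced.U[a], reduced.U[b])
    levels = levels[levels >= floor - 1e-12]
    lo, hi = 0, len(levels) - 1
    if not _connected(reduced.U <= levels[hi], a, b):
        raise ValueError("basins not connected even at the maximum level")
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected(reduced.U <= levels[mid], a, b):
            hi = mid
        else:
            lo = mid + 1
    c = levels[lo]
    on_level = np.argwhere(np.abs(reduced.U - c) < 1e-12)
    idx = tuple(on_level[0]) if len(on_level) else a
    return SaddleResult(saddle_index=idx, U_saddle=float(c))


@dataclass
class BarrierReport:
    """Barrier heights BH and relative barrier heights RBH per basin pair."""

    labels: list
    U_min: dict
    BH: dict = field(default_factory=dict)       # (i, j) -> BH from basin i
    U_saddle: dict = field(default_factory=dict)  # frozenset({i, j}) -> level
    merged: dict = field(default_factory=dict)

    def rbh(self, i, j) -> float:
        """RBH_ij = BH_sj - BH_si (positive: basin j is the deeper one)."""
        return self.BH[(j, i)] - self.BH[(i, j)]


def barrier_report(reduced: ReducedLandscape, pairs=None) -> BarrierReport:
    """BH and RBH for the requested basin pairs (default: all pairs).

    Basins may be addressed by index or by state label.  RBH antisymmetry
    holds exactly by construction.
    """
    M = len(reduced.means_2d)
    if M < 2:
        raise ValueError("barrier report needs at least two basins")
    if pairs is None:
        pairs = [(i, j) for i in range(M) for j in range(i + 1, M)]
    mins = reduced.minima_indices()
    U_min = {i: float(reduced.U[mins[i]]) for i in range(M)}
    rep = BarrierReport(labels=list(reduced.labels), U_min=U_min)
    for i, j in pairs:
        i, j = _resolve(reduced.labels, i), _resolve(reduced.labels, j)
        s = find_saddle(reduced, i, j)
        rep.U_saddle[frozenset((i, j))] = s.U_saddle
        rep.merged[frozenset((i, j))] = s.merged
        rep.BH[(i, j)] = max(s.U_saddle - U_min[i], 0.0)
        rep.BH[(j, i)] = max(s.U_saddle - U_min[j], 0.0)
    return rep


def _resolve(labels, key):
    if isinstance(key, str):
        return labels.index(key)
    return int(key)
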