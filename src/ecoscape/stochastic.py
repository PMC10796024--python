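"""Langevin simulation, mean first passage times and ramped-parameter runs.

Abundance fluctuations follow ``dx/dt = f(x) + zeta(t)`` with additive noise
of intensity ``d`` (covariance ``2 d delta_ij delta(t - t')`` for white
noise), integrated by the Euler-Maruyama scheme with truncation at zero
(the non-negative orthant acts as a reflecting boundary).  Colored noise is
generated as a variance-matched AR(1) innovation sequence: positive lag-1
autocorrelation (red) reinforces excursions and promotes barrier crossing,
negative (blue) suppresses them.

The module also simulates collapse/recovery experiments in which the
pollinator decay rate ``kappa`` is ramped linearly (or fluctuates) in time,
classifies the instantaneous state against the attractors of the
frozen-parameter system, and extracts hysteresis thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import GLVSystem, find_attractors
from .networks import BipartiteNetwork, ModelParameters


@dataclass
class NoiseSpec:
    """Additive noise: intensity ``d`` and spectral color.

    ``rho`` is the lag-1 autocorrelation of the innovation sequence;
    it defaults to +0.5 for red, -0.5 for blue and 0 for white noise.
    """

    d: float = 0.01
    kind: str = "white"
    rho: float = None

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("noise intensity d must be >= 0")
        if self.kind not in ("white", "red", "blue"):
            raise ValueError("noise kind must be white, red or blue")
        if self.rho is None:
            self.rho = {"white": 0.0, "red": 0.5, "blue": -0.5}[self.kind]
        if self.kind == "white" and self.rho != 0.0:
            raise ValueError("white noise requires rho = 0")
        if self.kind == "red" and not 0 < self.rho < 1:
            raise ValueError("red noise requires 0 < rho < 1")
        if self.kind == "blue" and not -1 < self.rho < 0:
            raise ValueError("blue noise requires -1 < rho < 0")


def _innovations(rng, shape, rho, zeta_prev):
    """Unit-variance AR(1) innovations; returns (zeta, new_state)."""
    eta = rng.standard_normal(shape)
    if rho == 0.0:
        return eta, eta
    zeta = rho * zeta_prev + np.sqrt(1.0 - rho**2) * eta
    return zeta, zeta


def euler_maruyama(
    x0,
    net: BipartiteNetwork,
    params: ModelParameters,
    noise: NoiseSpec,
    dt: float = 0.01,
    t_end: float = 100.0,
    seed: int = 0,
    record_every: int = 10,
):
    """Single-trajectory Euler-Maruyama integration.

    Returns ``(times, X)`` with ``X`` of shape (n_records, N).  With
    ``d = 0`` the scheme reduces to the deterministic Euler stepper.
    Abundances are truncated at zero after each step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    system = GLVSystem(net, params)
    ts, X = _em_ensemble(
        system.drift_many, np.asarray(x0, float)[None, :], noise, dt,
        int(round(t_end / dt)), np.random.default_rng(seed),
        record_every=record_every,
    )
    return ts, X[:, 0, :]


def _em_ensemble(drift_many, X0, noise, dt, n_steps, rng, record_every=0,
                 stop_fn=None, kappa_of_step=None, n_pollinators=None):
    """Core vectorized stepper for an ensemble of trajectories.

    ``drift_many`` maps (R, N) -> (R, N).  If ``kappa_of_step`` is given it
    must return the scalar decay rate at a step index, and ``drift_many``
    must then be the kappa = 0 field; the ``-kappa A`` term is applied
    explicitly (kappa enters the model linearly).  ``stop_fn(X)`` may return
    a boolean (R,) mask of trajectories that have arrived; arrival steps are
    collected and frozen trajectories stop moving.
    """
    X = np.clip(np.array(X0, dtype=float), 0.0, None)
    R, N = X.shape
    amp = np.sqrt(2.0 * noise.d * dt)
    zeta = rng.standard_normal((R, N))
    records = []
    rec_times = []
    arrival = np.full(R, -1, dtype=np.int64)
    active = np.ones(R, dtype=bool)
    if record_every:
        records.append(X.copy())
        rec_times.append(0.0)
    for k in range(n_steps):
        dX = drift_many(X) * dt
        if kappa_of_step is not None:
            dX[:, N - n_pollinators:] -= (
                kappa_of_step(k) * X[:, N - n_pollinators:] * dt
            )
        if noise.d > 0:
            zeta, _ = _innovations(rng, (R, N), noise.rho, zeta)
            dX += amp * zeta
        X = np.where(active[:, None], np.clip(X + dX, 0.0, None), X)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError(f"trajectory overflow at step {k}")
        if stop_fn is not None:
            hit = stop_fn(X) & active
            arrival[hit] = k + 1
            active &= ~hit
            if not active.any():
                if record_every:
                    records.append(X.copy())
                    rec_times.append((k + 1) * dt)
                break
        if record_every and (k + 1) % record_every == 0:
            records.append(X.copy())
            rec_times.append((k + 1) * dt)
    if record_every:
        return np.array(rec_times), np.stack(records)
    return arrival, X


@dataclass
class MfptResult:
    mfpt: float
    se: float
    n_arrived: int
    n_censored: int
    passage_times: np.ndarray


def mfpt(
    x_from,
    x_to,
    net: BipartiteNetwork,
    params: ModelParameters,
    noise: NoiseSpec,
    n_reps: int = 20,
    seed: int = 0,
    dt: float = 0.01,
    t_max: float = 5000.0,
    projection=None,
    radius_frac: float = 0.25,
) -> MfptResult:
    """Mean first passage time between attractors by direct simulation.

    ``n_reps`` trajectories start at ``x_from``; first passage is the first
    entry into a ball around ``x_to`` of radius ``radius_frac`` times the
    inter-attractor distance, measured in the reduced (z1, z2) coordinates
    when a ``projection`` is given and in full abundance space otherwise.
    Censored runs (no arrival by ``t_max``) are reported separately and not
    averaged in; an all-censored ensemble yields ``mfpt = nan``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    a = np.asarray(getattr(x_from, "state", x_from), dtype=float)
    b = np.asarray(getattr(x_to, "state", x_to), dtype=float)
    system = GLVSystem(net, params)
    if projection is not None:
        W = projection.W
        target = b @ W
        radius = radius_frac * np.linalg.norm((b - a) @ W)
        stop = lambda X: np.linalg.norm(X @ W - target, axis=1) < radius
    else:
        radius = radius_frac * np.linalg.norm(b - a)
        stop = lambda X: np.linalg.norm(X - b, axis=1) < radius
    rng = np.random.default_rng(seed)
    X0 = np.tile(a, (n_reps, 1))
    arrival, _ = _em_ensemble(
        system.drift_many, X0, noise, dt, int(round(t_max / dt)), rng,
        stop_fn=stop,
    )
    times = arrival[arrival > 0] * dt
    n_cens = int(np.sum(arrival < 0))
    if len(times) == 0:
        warnings.warn("all first-passage runs censored; MFPT undefined",
                      stacklevel=2)
        return MfptResult(np.nan, np.nan, 0, n_cens, times)
    se = float(times.std(ddof=1) / np.sqrt(len(times))) if len(times) > 1 else np.nan
    return MfptResult(float(times.mean()), se, len(times), n_cens, times)


# -- ramped-parameter simulation ------------------------------------------

@dataclass
class RampSpec:
    """Linear ramp (or stationary fluctuation) of the decay rate kappa."""

    start: float
    end: float
    rate: float = 0.0002   # |d kappa / dt|
    parameter: str = "kappa"
    fluctuation: tuple = None   # (sigma, rho): AR(1) fluctuations around start
    t_end: float = None        # explicit duration (required if start == end)

    @property
    def direction(self) -> str:
        return "collapse" if self.end >= self.start else "recovery"

    @property
    def duration(self) -> float:
        if self.t_end is not None:
            return self.t_end
        if self.rate <= 0 or self.end == self.start:
            raise ValueError("a stationary ramp needs an explicit t_end")
        return abs(self.end - self.start) / self.rate


@dataclass
class HysteresisReport:
    """Collapse (kappa1-, kappa2-) and recovery (kappa1+, kappa2+) thresholds.

    kappa1 refers to the high <-> intermediate transition and kappa2 to the
    intermediate <-> low transition; per-replicate values plus the ensemble
    median.  Replicates without a given transition hold nan.
    """

    direction: str
    per_replicate: dict = field(default_factory=dict)

    def median(self, key: str) -> float:
        v = np.asarray(self.per_replicate.get(key, []), dtype=float)
        v = v[np.isfinite(v)]
        return float(np.median(v)) if len(v) else np.nan

    @property
    def no_transition(self) -> bool:
        return all(
            not np.any(np.isfinite(np.asarray(v, dtype=float)))
            for v in self.per_replicate.values()
        )


def attractor_branches(
    net, params, kappa_grid, n_starts=40, seed=0, **kw
) -> dict:
    """Attractor sets of the frozen-parameter system along a kappa grid."""
    out = {}
    for k in kappa_grid:
        out[float(k)] = find_attractors(
            net, params.replace(kappa=float(k)), n_starts=n_starts,
            seed=seed, **kw
        )
    return out


def _classify_by_nearest(x, aset, W):
    z = x @ W if W is not None else x
    best, lab = np.inf, "other"
    for a in aset:
        za = a.state @ W if W is not None else a.state
        dist = np.linalg.norm(z - za)
        if dist < best:
            best, lab = dist, a.label
    return lab


def ramp_simulation(
    spec: RampSpec,
    net: BipartiteNetwork,
    params: ModelParameters,
    noise: NoiseSpec,
    seed: int = 0,
    n_reps: int = 1,
    dt: float = 0.02,
    record_every: int = 25,
    dwell: float = 50.0,
    projection=None,
    branches: dict = None,
    branch_step: float = 0.01,
):
    """Collapse/recovery simulation under a kappa ramp.

    Integrates ``n_reps`` Langevin replicates while kappa moves linearly
    from ``spec.start`` to ``spec.end`` at ``spec.rate`` (or fluctuates as
    AR(1) around ``spec.start`` when ``spec.fluctuation`` is set).  Recorded
    states are classified by the nearest attractor (projected coordinates
    when ``projection`` is given) of the frozen-parameter system at the
    nearest kappa on a precomputed branch grid.  A state change counts when
    the new label persists for at least ``dwell`` time units; the threshold
    kappa is the ramp value at its first appearance.

    Returns ``(times, kappas, trajectories, labels, report)``.
    """
    if spec.parameter != "kappa":
        raise NotImplementedError("only kappa ramps are supported")
    rng = np.random.default_rng(seed)
    n_steps = int(round(spec.duration / dt))
    if n_steps < 1:
        raise ValueError("ramp duration too short for the time step")
    sgn = 1.0 if spec.end >= spec.start else -1.0
    if spec.fluctuation is not None:
        sigma, rho = spec.fluctuation
        eps = np.empty(n_steps + 1)
        eps[0] = rng.standard_normal() * sigma
        innov = rng.standard_normal(n_steps) * sigma * np.sqrt(1 - rho**2)
        for k in range(n_steps):
            eps[k + 1] = rho * eps[k] + innov[k]
        kappa_t = spec.start + eps
    else:
        kappa_t = spec.start + sgn * spec.rate * dt * np.arange(n_steps + 1)
    system0 = GLVSystem(net, params.replace(kappa=0.0))

    if branches is None:
        lo, hi = min(spec.start, spec.end), max(spec.start, spec.end)
        grid = np.arange(lo, hi + branch_step / 2, branch_step)
        branches = attractor_branches(net, params, grid, seed=seed)
    grid_k = np.array(sorted(branches))
    W = projection.W if projection is not None else None

    # start every replicate on the attractor the ramp begins from
    aset0 = branches[float(grid_k[np.argmin(np.abs(grid_k - kappa_t[0]))])]
    order = {"collapse": ("high", "intermediate", "low"),
             "recovery": ("low", "intermediate", "high")}[spec.direction]
    try:
        x0 = aset0.by_label(order[0]).state
    except KeyError:
        x0 = max(aset0, key=lambda a: a.weight).state
    X0 = np.tile(x0, (n_reps, 1))
    ts, traj = _em_ensemble(
        system0.drift_many, X0, noise, dt, n_steps, rng,
        record_every=record_every,
        kappa_of_step=lambda k: kappa_t[k],
        n_pollinators=net.n_pollinators,
    )
    kap_rec = np.interp(ts, np.arange(n_steps + 1) * dt, kappa_t)
    labels = np.empty((len(ts), n_reps), dtype=object)
    for i, k in enumerate(kap_rec):
        aset = branches[float(grid_k[np.argmin(np.abs(grid_k - k))])]
        for r in range(n_reps):
            labels[i, r] = _classify_by_nearest(traj[i, r], aset, W)

    report = HysteresisReport(direction=spec.direction)
    key12 = {"collapse": ("kappa1_minus", "kappa2_minus"),
             "recovery": ("kappa2_plus", "kappa1_plus")}[spec.direction]
    dwell_pts = max(1, int(round(dwell / (ts[1] - ts[0])))) if len(ts) > 1 else 1
    for key in key12:
        report.per_replicate[key] = []
    for r in range(n_reps):
        seq = labels[:, r]
        thresholds = {key12[0]: np.nan, key12[1]: np.nan}
        stage = 0  # 0: waiting to leave order[0]; 1: waiting to reach order[2]
        for i in range(len(seq)):
            run_end = min(len(seq), i + dwell_pts)
            window = seq[i:run_end]
            if stage == 0 and all(s in (order[1], order[2]) for s in window):
                thresholds[key12[0]] = kap_rec[i]
                stage = 1
                if all(s == order[2] for s in window):
                    thresholds[key12[1]] = kap_rec[i]
                    break
            elif stage == 1 and all(s == order[2] for s in window):
                thresholds[key12[1]] = kap_rec[i]
                break
        for key in key12:
            report.per_replicate[key].append(thresholds[key])
    return ts, kap_rec, traj, labels, report
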