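"""One-at-a-time global sensitivity of transition actions.

Each model parameter is perturbed by +-10% around a tristable baseline and
the minimum transition actions between state pairs are recomputed; the
report holds relative changes ``(S_pert - S_base) / S_base``.  Collapse-
direction perturbations (growth rates or mutualistic strength down;
competition, decay, handling time or trade-off up) are scored on the
intermediate <-> low pair, recovery-direction perturbations on the
high <-> intermediate pair.

Starred parameters (``alpha*``, ``beta*``, ``kappa*``, ``gamma0*``) perturb
only the focal pollinator — by default the one that survives alone in the
intermediate state — quantifying how much managing that single species
buys relative to managing all of them.

When a perturbation destroys a state, the action toward the vanished state
is zero and away from it infinite; relative changes are encoded as -1 and a
display cap (2.5) respectively, with the raw flag preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import GLVSystem, find_attractors
from .networks import BipartiteNetwork, ModelParameters, build_gamma, _per_species
from .paths import minimize_action

INFINITY_CAP = 2.5

GLOBAL_PARAMS = ("alpha_P", "alpha_A", "beta_P", "beta_A",
                 "kappa", "gamma0", "h", "delta")
FOCAL_PARAMS = ("alpha*", "beta*", "kappa*", "gamma0*")

#: perturbation direction pushing the system toward collapse
COLLAPSE_DIRECTION = {
    "alpha_P": -1, "alpha_A": -1, "gamma0": -1,
    "beta_P": +1, "beta_A": +1, "kappa": +1, "h": +1, "delta": +1,
    "alpha*": -1, "gamma0*": -1, "beta*": +1, "kappa*": +1,
}


@dataclass
class PerturbationSpec:
    """One perturbation: parameter, sign (+1/-1 for +-10%), focal index."""

    parameter: str
    direction: int
    focal: int = None
    magnitude: float = 0.1

    def __post_init__(self):
        if self.parameter not in GLOBAL_PARAMS + FOCAL_PARAMS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.parameter in FOCAL_PARAMS and self.focal is None:
            raise ValueError(f"{self.parameter} requires a focal pollinator index")
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")


def apply_perturbation(
    net: BipartiteNetwork, params: ModelParameters, spec: PerturbationSpec
):
    """Perturbed (params, gammas) pair; gammas carry focal gamma0 scaling."""
    factor = 1.0 + spec.direction * spec.magnitude
    nA = net.n_pollinators
    p = params
    name = spec.parameter
    if name == "alpha_P":
        p = p.replace(alpha_P=np.asarray(p.alpha_P) * factor)
    elif name == "alpha_A":
        p = p.replace(alpha_A=np.asarray(p.alpha_A) * factor)
    elif name == "beta_P":
        p = p.replace(beta_intra_P=np.asarray(p.beta_intra_P) * factor)
    elif name == "beta_A":
        p = p.replace(beta_intra_A=np.asarray(p.beta_intra_A) * factor)
    elif name == "kappa":
        p = p.replace(kappa=np.asarray(p.kappa) * factor)
    elif name in ("gamma0", "h", "delta"):
        p = p.replace(**{name: getattr(p, name) * factor})
    elif name == "alpha*":
        v = _per_species(p.alpha_A, nA, "alpha_A")
        v[spec.focal] *= factor
        p = p.replace(alpha_A=v)
    elif name == "beta*":
        v = _per_species(p.beta_intra_A, nA, "beta_intra_A")
        v[spec.focal] *= factor
        p = p.replace(beta_intra_A=v)
    elif name == "kappa*":
        v = _per_species(p.kappa, nA, "kappa")
        v[spec.focal] *= factor
        p = p.replace(kappa=v)
    gammas = build_gamma(net, p)
    if name == "gamma0*":
        # scale the focal pollinator's per-capita strength in both directions
        gammas.gamma_PA[:, spec.focal] *= factor
        gammas.gamma_AP[spec.focal, :] *= factor
    return p, gammas


def focal_pollinator(aset, n_plants: int, net: BipartiteNetwork) -> int:
    """Pollinator surviving in the intermediate state (max degree breaks ties)."""
    inter = aset.by_label("intermediate")
    pol = inter.state[n_plants:]
    alive = np.where(pol > 1e-3)[0]
    if len(alive) == 0:
        raise ValueError("intermediate state has no surviving pollinator")
    degrees = net.pollinator_degrees[alive]
    return int(alive[np.argmax(degrees)])


@dataclass
class SensitivityReport:
    baseline_actions: dict
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _pair_actions(aset, system, L, T_schedule, seed):
    """Minimum actions for both directions of the available state pairs."""
    out = {}
    labs = {a.label: a.state for a in aset}
    for i, j in (("intermediate", "low"), ("low", "intermediate"),
                 ("high", "intermediate"), ("intermediate", "high")):
        if i in labs and j in labs:
            via = [labs[k] for k in labs if k not in (i, j)]
            p = minimize_action(labs[i], labs[j], system.drift,
                                system.jacobian, L=L,
                                T_schedule=T_schedule, seed=seed,
                                via=via or None)
            out[(i, j)] = p.action
    return out


def run_sensitivity(
    net: BipartiteNetwork,
    params: ModelParameters,
    specs=None,
    L: int = 20,
    T_schedule=(20.0, 50.0),
    n_starts: int = 60,
    seed: int = 0,
) -> SensitivityReport:
    """Relative change of transition actions under +-10% perturbations.

    The baseline must be tristable.  ``specs`` defaults to the
    collapse-direction perturbation of every global and focal parameter.
    For each spec the attractors and the relevant pair actions are
    recomputed; vanished states are encoded as described in the module
    docstring.
    """
    base_aset = find_attractors(net, params, n_starts=n_starts, seed=seed)
    if base_aset.scenario != "HIL":
        raise ValueError(
            f"baseline must be tristable (got scenario {base_aset.scenario})"
        )
    focal = focal_pollinator(base_aset, net.n_plants, net)
    if specs is None:
        specs = [
            PerturbationSpec(p, COLLAPSE_DIRECTION[p],
                             focal if p in FOCAL_PARAMS else None)
            for p in GLOBAL_PARAMS + FOCAL_PARAMS
        ]
    system = GLVSystem(net, params)
    S_base = _pair_actions(base_aset, system, L, T_schedule, seed)
    report = SensitivityReport(baseline_actions=dict(S_base))
    for spec in specs:
        p_new, g_new = apply_perturbation(net, params, spec)
        aset = find_attractors(net, p_new, n_starts=n_starts, seed=seed,
                               gammas=g_new)
        sys_new = GLVSystem(net, p_new, g_new)
        labs = {a.label for a in aset}
        collapse_pair = spec.direction == COLLAPSE_DIRECTION.get(spec.parameter)
        pairs = ((("intermediate", "low"), ("low", "intermediate"))
                 if collapse_pair else
                 (("high", "intermediate"), ("intermediate", "high")))
        S_new = _pair_actions(aset, sys_new, L, T_schedule, seed)
        for pair in pairs:
            if pair not in S_base:
                continue
            flag = ""
            if pair[0] in labs and pair[1] in labs:
                rel = (S_new[pair] - S_base[pair]) / S_base[pair] \
                    if S_base[pair] > 0 else np.nan
            elif pair[1] not in labs:
                # the destination no longer exists: the transition never
                # completes, S -> infinity (displayed capped)
                rel, flag = INFINITY_CAP, "target state vanished (action -> inf)"
            else:
                # the origin no longer exists: the system falls freely into
                # the surviving state, S -> 0
                rel, flag = -1.0, "source state vanished (action -> 0)"
            report.rows.append({
                "parameter": spec.parameter,
                "direction": spec.direction * spec.magnitude,
                "pair": f"{pair[0]}->{pair[1]}",
                "relative_change": rel,
                "flag": flag,
                "scenario": aset.scenario,
            })
    return report
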