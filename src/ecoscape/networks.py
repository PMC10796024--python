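"""Bipartite mutualistic networks: incidence structure, degree-dependent
mutualistic strengths, Web-of-Life style I/O and synthetic network generation.

A plant-pollinator network is a binary incidence matrix ``epsilon`` with plants
on the rows and pollinators on the columns; ``epsilon[i, l] == 1`` iff plant
``i`` and pollinator ``l`` interact.  The per-link mutualistic strength a
species receives decays with its degree ``g`` as ``gamma0 / g**delta``, where
``delta`` in [0, 1] trades off per-partner intensity against number of
partners (``delta = 0``: all links equally strong; ``delta = 1``: total gain
independent of degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NetworkParseError(ValueError):
    """Raised when a delimited incidence matrix cannot be parsed."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Binary bipartite incidence structure.

    Parameters
    ----------
    incidence : ndarray of shape (n_plants, n_pollinators)
        Binary matrix; entry ``(i, l)`` is 1 iff plant ``i`` and pollinator
        ``l`` interact.
    plant_labels, pollinator_labels : list of str, optional
        Species identifiers; defaults to ``P1..`` / ``A1..``.
    """

    incidence: np.ndarray
    plant_labels: list[str] = field(default=None)
    pollinator_labels: list[str] = field(default=None)

    def __post_init__(self):
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise ValueError("incidence must be a 2-D matrix")
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        object.__setattr__(self, "incidence", inc.astype(float))
        if self.plant_labels is None:
            object.__setattr__(
                self, "plant_labels", [f"P{i+1}" for i in range(inc.shape[0])]
            )
        if self.pollinator_labels is None:
            object.__setattr__(
                self, "pollinator_labels", [f"A{j+1}" for j in range(inc.shape[1])]
            )
        if len(self.plant_labels) != inc.shape[0]:
            raise ValueError("plant_labels length must equal n_plants")
        if len(self.pollinator_labels) != inc.shape[1]:
            raise ValueError("pollinator_labels length must equal n_pollinators")

    @property
    def n_plants(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_species(self) -> int:
        return self.n_plants + self.n_pollinators

    @property
    def plant_degrees(self) -> np.ndarray:
        """Row sums g_i^(P)."""
        return self.incidence.sum(axis=1)

    @property
    def pollinator_degrees(self) -> np.ndarray:
        """Column sums g_j^(A)."""
        return self.incidence.sum(axis=0)

    @property
    def connectance(self) -> float:
        return float(self.incidence.mean()) if self.incidence.size else 0.0


@dataclass
class ModelParameters:
    """Rate constants of the mutualistic generalized Lotka-Volterra model.

    All parameters are non-negative.  ``alpha_P``, ``alpha_A``,
    ``beta_intra_P``, ``beta_intra_A`` and ``kappa`` may be scalars or
    per-species vectors (vectors must conform to the network when the model is
    assembled); the remaining parameters are scalars.

    Attributes
    ----------
    alpha_P, alpha_A : intrinsic growth rates (default 0.3).
    beta_intra_P, beta_intra_A : intraspecific competition (default 1).
    beta_inter_P, beta_inter_A : interspecific competition (default 0.01).
    kappa : pollinator decay rate from environmental degradation (default 1.07).
    gamma0 : per-capita mutualistic strength (default 1).
    delta : degree trade-off exponent in [0, 1] (default 0.5).
    h : half-saturation (handling-time) constant of the Holling type II
        response (default 0.2).
    mu_P, mu_A : immigration rates (default 0, i.e. neglected; with
        immigration switched on, "extinct" species settle at a small positive
        floor ~ mu / net-decay-rate, which must be kept below the extinction
        threshold used for state classification).
    """

    alpha_P: float | np.ndarray = 0.3
    alpha_A: float | np.ndarray = 0.3
    beta_intra_P: float | np.ndarray = 1.0
    beta_intra_A: float | np.ndarray = 1.0
    beta_inter_P: float = 0.01
    beta_inter_A: float = 0.01
    kappa: float | np.ndarray = 1.07
    gamma0: float = 1.0
    delta: float = 0.5
    h: float = 0.2
    mu_P: float = 0.0
    mu_A: float = 0.0

    def __post_init__(self):
        for name in (
            "alpha_P", "alpha_A", "beta_intra_P", "beta_intra_A",
            "beta_inter_P", "beta_inter_A", "kappa", "gamma0",
            "delta", "h", "mu_P", "mu_A",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= float(np.max(np.asarray(self.delta))) <= 1.0:
            raise ValueError("delta must lie in [0, 1]")

    def replace(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class GammaMatrices:
    """Directed mutualistic strength matrices.

    ``gamma_PA[i, l]`` is the strength plant ``i`` receives from pollinator
    ``l``; ``gamma_AP[j, n]`` the strength pollinator ``j`` receives from
    plant ``n``.  Entries are zero wherever no link exists.
    """

    gamma_PA: np.ndarray
    gamma_AP: np.ndarray


def _per_species(value, n: int, name: str) -> np.ndarray:
    v = np.asarray(value, dtype=float)
    if v.ndim == 0:
        return np.full(n, float(v))
    if v.shape != (n,):
        raise ValueError(
            f"parameter {name} has shape {v.shape}, expected scalar or ({n},)"
        )
    return v.copy()


def build_gamma(net: BipartiteNetwork, params: ModelParameters) -> GammaMatrices:
    """Degree-dependent mutualistic strengths for both directions.

    The strength plant ``i`` receives on each of its links is
    ``gamma0 / g_i^(P) ** delta`` and similarly for pollinators, so
    generalists receive weaker per-link benefit when ``delta > 0``.  Species
    with degree zero get all-zero strengths.
    """
    eps = net.incidence
    gP = net.plant_degrees
    gA = net.pollinator_degrees
    # guard degree-0 species against division by zero; their rows are zero anyway
    with np.errstate(divide="ignore", invalid="ignore"):
        wP = np.where(gP > 0, params.gamma0 / np.maximum(gP, 1) ** params.delta, 0.0)
        wA = np.where(gA > 0, params.gamma0 / np.maximum(gA, 1) ** params.delta, 0.0)
    gamma_PA = eps * wP[:, None]
    gamma_AP = eps.T * wA[:, None]
    return GammaMatrices(gamma_PA=gamma_PA, gamma_AP=gamma_AP)


def read_weboflife_matrix(path) -> BipartiteNetwork:
    """Read a Web-of-Life style delimited incidence matrix.

    Plants are rows, pollinators columns.  Cells may be visit counts; any
    value > 0 is binarized to a link.  If the first row/column is
    non-numeric it is treated as labels.  Comma and tab delimiters are
    auto-detected.
    """
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh if line.strip() != ""]
    if not raw:
        raise NetworkParseError(f"{path}: empty matrix file")
    delim = "\t" if "\t" in raw[0] else ","
    rows = [line.split(delim) for line in raw]
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise NetworkParseError(
                f"{path}: ragged row at line {k + 1} "
                f"({len(r)} cells, expected {width})"
            )

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(c) for c in rows[0][1:])
    has_index = not all(_numeric(r[0]) for r in rows[1 if has_header else 0:])
    pollinator_labels = None
    plant_labels = None
    if has_header:
        pollinator_labels = [c.strip() for c in rows[0][1 if has_index else 0:]]
        rows = rows[1:]
    if has_index:
        plant_labels = [r[0].strip() for r in rows]
        rows = [r[1:] for r in rows]
    if not rows or not rows[0]:
        raise NetworkParseError(f"{path}: no numeric cells found")
    try:
        mat = np.array([[float(c) for c in r] for r in rows])
    except ValueError as exc:
        raise NetworkParseError(f"{path}: non-numeric cell ({exc})") from exc
    return BipartiteNetwork(
        incidence=(mat > 0).astype(float),
        plant_labels=plant_labels,
        pollinator_labels=pollinator_labels,
    )


def write_network(net: BipartiteNetwork, path) -> None:
    """Serialize as a labelled comma-delimited incidence matrix.

    Round-trips exactly through :func:`read_weboflife_matrix`.
    """
    with open(path, "w") as fh:
        fh.write("," + ",".join(net.pollinator_labels) + "\n")
        for lab, row in zip(net.plant_labels, net.incidence):
            fh.write(lab + "," + ",".join(str(int(v)) for v in row) + "\n")


def remove_pollinators(
    net: BipartiteNetwork, fraction: float, seed: int
) -> BipartiteNetwork:
    """Random pollinator removal emulating pollinator extinction risk.

    Removes ``floor(fraction * n_pollinators)`` pollinator columns uniformly
    at random together with their links (so removing 80% of 61 pollinators
    retains 13).  Plant rows are retained even if left without any link.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n_remove = int(np.floor(fraction * net.n_pollinators))
    rng = np.random.default_rng(seed)
    removed = rng.choice(net.n_pollinators, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(net.n_pollinators), removed)
    return BipartiteNetwork(
        incidence=net.incidence[:, keep],
        plant_labels=list(net.plant_labels),
        pollinator_labels=[net.pollinator_labels[j] for j in keep],
    )


def generate_random_network(
    n_plants: int,
    n_pollinators: int,
    connectance: float,
    heterogeneity: float = 0.0,
    seed: int = 0,
) -> BipartiteNetwork:
    """Generate a random bipartite network with target link density.

    With ``heterogeneity == 0`` every link is i.i.d. Bernoulli(connectance).
    With ``heterogeneity > 0`` species are given latent propensities drawn
    from a Gamma(1/heterogeneity, heterogeneity) distribution (mean 1,
    variance ``heterogeneity``); link probabilities are proportional to the
    product of the endpoint propensities, rescaled to keep the expected
    connectance, which skews the degree distribution towards a
    generalist/specialist mix.  Deterministic for a fixed seed.
    """
    if n_plants < 1 or n_pollinators < 1:
        raise ValueError("network sizes must be >= 1")
    if not 0.0 < connectance <= 1.0:
        raise ValueError("connectance must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if heterogeneity > 0:
        shape = 1.0 / heterogeneity
        wp = rng.gamma(shape, heterogeneity, size=n_plants)
        wa = rng.gamma(shape, heterogeneity, size=n_pollinators)
        prob = np.outer(wp, wa)
        prob *= connectance / prob.mean()
        prob = np.clip(prob, 0.0, 1.0)
    else:
        prob = np.full((n_plants, n_pollinators), connectance)
    inc = (rng.random((n_plants, n_pollinators)) < prob).astype(float)
    return BipartiteNetwork(incidence=inc)
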