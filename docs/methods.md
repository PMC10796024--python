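# Methods

## Model

The package studies bipartite plant–pollinator communities under a
generalized Lotka–Volterra model with saturating mutualism.  With plants
$P_i$ ($i = 1..N_P$) and pollinators $A_j$ ($j = 1..N_A$):

$$\dot P_i = \alpha_i P_i - \sum_k \beta_{ik} P_i P_k
  + \frac{P_i \sum_l \gamma^{(A)}_{il} A_l}{1 + h \sum_l \gamma^{(A)}_{il} A_l} + \mu,$$

$$\dot A_j = (\alpha_j - \kappa_j) A_j - \sum_m \beta_{jm} A_j A_m
  + \frac{A_j \sum_n \gamma^{(P)}_{jn} P_n}{1 + h \sum_n \gamma^{(P)}_{jn} P_n} + \mu.$$

Links come from a binary incidence matrix; the per-link strength a species
receives decays with its degree $g$ as $\gamma_0 / g^\delta$.  Defaults:
$\alpha = 0.3$, intraspecific competition $\beta = 1$, interspecific
$\beta' = 0.01$, $\gamma_0 = 1$, $\delta = 0.5$, $h = 0.2$, $\kappa = 1.07$.
Immigration is neglected ($\mu = 0$): species can go extinct exactly, which
is what makes the extinction threshold of $10^{-3}$ (used everywhere for
alive/extinct calls) unambiguous.  With $\mu > 0$ every "extinct" species
would sit at a floor near $\mu / r$ (decay rate $r$), typically above
$10^{-3}$ for the parameter ranges used here, so immigration and the
threshold cannot be combined carelessly; the parameter remains available
but defaults to zero.

`kappa`, the pollinator decay rate, models environmental degradation and is
the main control parameter; it is scalar by default (shared by all
pollinators) and per-species capable only for the sensitivity analysis.

## Attractors, state classification and scenarios

Stable states are located by multi-start relaxation: a batch of initial
conditions is integrated with fixed-step RK4 (dt = 0.05, clipping at zero;
the orthant is forward-invariant for the exact flow), clustered (infinity
norm, radius $10^{-3}$), polished by a Newton solve and verified (residual
drift below $10^{-8}$, Jacobian spectral abscissa negative).  Basin weights
are occupation frequencies of the starts.

The sampler draws, per start, independent plant/pollinator block amplitudes
$r_P, r_A \sim U(0, x_{hi})$ and then species values uniformly inside the
blocks.  A plain uniform sampler on $[0, x_{hi}]^N$ is available but
systematically misses the low and intermediate basins on realistic
networks (those basins require abundant plants with scarce pollinators, a
corner the uniform box rarely produces); the block sampler covers all
mixture corners.  The same seed is reused across parameter sweeps (common
random numbers), so basin weights vary smoothly along a sweep.

Classification: a state is **low** when every pollinator is extinct;
**intermediate** when some but fewer than half of the pollinators survive
(typically only the generalists); among states with at least half the
pollinators alive, the one of largest total abundance in its coexisting set
is **high**, any other is "other".  Scenario codes combine the labels (H,
HI, HL, HIL, I, IL, L; T for two or more intermediates).  The rank-based
alternative ("top state = high" regardless of survivors) would make the
IL phase unrepresentable, although it plainly occurs once the high state
folds; the majority rule avoids that.

## Landscape (truncated moment equations)

For weak additive noise ($d \ll 1$) each attractor's stationary density is
approximated as a Gaussian: mean at the fixed point, covariance the
solution of the Lyapunov equation $A\Sigma + \Sigma A^T + 2dI = 0$ (third
and higher moments truncated).  The global density is the basin-weighted
mixture and the potential is $U = -\ln p_{ss}$.  Covariances are obtained
with a direct Lyapunov solver; tests verify the residual ($<10^{-8}$) and
agreement with covariance-ODE integration and with Langevin ensembles.

Dimension reduction respects the bipartite structure: the exact mixture
moments of the plant block and the pollinator block are computed
separately, and the leading eigenvector of each block covariance defines
the coordinates $z_1$ (plant PC1) and $z_2$ (pollinator PC1).  Signs are
fixed so the high state projects to the upper right.  Components project
exactly ($z \sim N(W^T\mu, W^T\Sigma W)$), giving a cheap closed-form 2-D
landscape on a grid (default 200×200 spanning projected means ±4 SD).
Projections computed at one reference parameter set may be reused across a
sweep for comparability; they are stable under small parameter changes.

Saddles between basins are found by threshold bisection on sub-level-set
connectivity (flood fill): the saddle level is the smallest $c$ for which
both minima belong to one component of $\{U \le c\}$.  Barrier height
BH$_{si} = U_{saddle} - U_i$; relative barrier height
RBH$_{ij}$ = BH$_{sj}$ − BH$_{si}$ (antisymmetric by construction; its sign
says which basin is deeper, hence which transition is more feasible).
Note that with these conventions RBH$_{ij}$ and the action difference
$\Delta S_{ij} = S_{i\to j} - S_{j\to i}$ carry opposite signs for the same
physical asymmetry.

The noise intensity enters $U$ only through the component covariances; RBH
is essentially $d$-independent because $U_i - U_j$ is dominated by weight
and log-determinant differences.  Default $d = 0.01$.

## Minimum-action transition paths

Transition feasibility is quantified by the Freidlin–Wentzell action
$S = \tfrac12\int \|\dot x - f(x)\|^2\,dt$, minimized over $L$-node
discretized paths (default $L = 20$) with fixed endpoints, node-wise
non-negativity bounds, analytic gradients, and L-BFGS-B.  The total time
$T$ is swept over a geometric schedule (default 20, 50, 100, 200) and the
time grid is re-meshed once by arc-length equidistribution.  Initial paths:
straight line, a seeded perturbed restart, and optionally bent paths
through supplied way-states (coexisting attractors); without the bent
initializations the optimizer can miss indirect corridors, e.g. the
high→low route through the intermediate state.

Coarse time grids admit a spurious solution in which one long segment hops
a barrier at near-zero midpoint-quadrature cost; candidates are therefore
ranked (and reported) by the action of the piecewise-linear path evaluated
on a 4× refined grid, which restores the barrier cost.  On gradient
systems the minimized uphill action reproduces $2\Delta V$ to better than
2% at $L = 40$.

Indirect paths concatenate two minimized legs through a waypoint and are
resampled to $L$ nodes; their action is evaluated on the resampled path so
that direct and indirect figures share one functional.  The path distance
PD $= \sum_i \|y_i^{dir} - y_i^{ind}\|_2^2$ uses the full abundance space.

## Stochastic simulation

Euler–Maruyama with truncation at zero (matching a reflecting boundary).
Colored noise uses AR(1) innovations (red $\rho = +0.5$, blue $-0.5$),
variance-matched to white per step; red noise effectively triples the
low-frequency diffusivity ($(1+\rho)/(1-\rho)$), promoting barrier
crossings, blue suppresses them.

MFPT: ensembles of trajectories started on one attractor; arrival is entry
into a ball around the target (radius 25% of the inter-attractor distance,
in reduced coordinates when a projection is supplied, else in full space);
censored runs are excluded and reported.  On the 1×1 bistable module
($\gamma_0 = 2$, $\kappa \in [1.10, 1.20]$, $d = 0.04$, 20 replicates)
log MFPT regresses on RBH and on $\Delta S$ with $R^2 > 0.9$.

Ramped experiments move $\kappa$ linearly (default rate $5\times10^{-5}$
per unit time, dt = 0.02) or let it fluctuate (AR(1)).  Recorded states are
classified by the nearest attractor (projected coordinates) of the
frozen-parameter system on a precomputed $\kappa$ grid (step 0.01); a
transition counts after a 50-time-unit dwell.  Ramp noise defaults to
$d = 5\times10^{-4}$: weak enough that transitions are fold-dominated
(at $d \gtrsim 5\times10^{-3}$ the shallow residual barrier near a fold
lets noise anticipate the transition and the hysteresis loop closes).

## Early-warning signals

The landscape signal is the RBH between the low and intermediate basins
along an increasing $\kappa$ grid (the pair that exists all the way to
final collapse).  Each growing prefix is linearly detrended and tested for
non-i.i.d. structure with the BDS statistic (embedding dimensions 2 and 3,
proximity radius 0.5×SD, minimum prefix length 15; warning at the first
$\kappa$ whose minimum-over-$m$ p-value crosses the significance level).

BDS p-values come from a seeded Monte-Carlo null table of the statistic
(2000 i.i.d.-normal simulations per series length, cached) rather than the
asymptotic normal approximation: at these settings the asymptotic test is
badly oversized (8–12% rejection at nominal 5% for n = 500, worse at the
short prefix lengths used here), while the Monte-Carlo null is exactly
sized by construction and passes the 1000-replicate calibration check.
The statistic itself is computed by statsmodels.

Trajectory comparators (AR(1), variance, CV, Fano factor) are computed per
species on a ramped Langevin run ($d = 0.01$ so fluctuations are
informative), Gaussian-detrended (bandwidth 10% of the series), in rolling
windows (200 samples); a metric warns at the smallest $\kappa$ from which
its lightly smoothed sequence is non-decreasing through the tipping point.
RBH precision is limited by Monte-Carlo noise in the basin weights
($\mathrm{sd}(\mathrm{RBH}) \sim \sqrt{2/(n_{starts}\varphi)}$), so the
warning analyses use 600 starts per grid point.

A false-positive protocol evaluates the same machinery under fluctuating
$\kappa$ with no approaching transition; RBH values are cached per rounded
$\kappa$ so many seeds can be screened cheaply.

## Two-dimensional mean-field model

Aggregating each guild into one variable (mean-field strengths
$\langle\gamma_P\rangle, \langle\gamma_A\rangle$ taken as the
species-averaged row sums of the strength matrices) yields a planar system
whose fixed points are closed-form at $\mu \approx 0$: the origin and the
plant-free point (always unstable), the pollinator-free "low" point
(stable iff $\kappa > \alpha + \langle\gamma_A\rangle(\alpha/\beta) /
(1 + h\langle\gamma_A\rangle\alpha/\beta)$), and up to two interior points
from a quadratic in $A'$, the upper root stable and the lower unstable
whenever both are positive.  The saddle-node $\kappa$ solves the
discriminant (quadratic in $\kappa$; the larger root is discarded as it
corresponds to negative $A'$).  Closed-form stability is cross-checked
against numeric eigenvalues on every call; randomized scans confirm the
model never exhibits three stable states — the intermediate state is a
genuinely multidimensional phenomenon, which motivates the full network
model.

## Sensitivity analysis

One-at-a-time ±10% perturbations of the global parameters and of the focal
pollinator's parameters ($\alpha^*, \beta^*, \kappa^*, \gamma_0^*$; focal =
the pollinator surviving in the intermediate state, ties broken by degree).
Collapse-direction perturbations are scored by the relative change of the
minimum actions between intermediate and low; recovery-direction ones
between high and intermediate.  If a perturbation destroys a state,
transitions into it cost infinity (reported capped at 2.5) and transitions
out of it toward the survivor cost 0 (relative change −1); raw flags are
preserved.

## Synthetic networks and the packaged fixture

The generator draws links i.i.d. Bernoulli at a target connectance;
heterogeneity > 0 multiplies link probabilities by Gamma-distributed
species propensities (mean 1, variance = heterogeneity), producing
generalist/specialist degree mixtures.  It emulates the degree
heterogeneity and sparsity of empirical pollination webs but not their
nestedness, modularity, phylogenetic signal or visit weights — so passing
tests demonstrate the method's behavior on plausibly structured random
networks, not on any particular empirical community.

The packaged fixture (`ecoscape/data/tristable_17x13.csv`) is a 17×13
sub-network obtained by removing 80% of the pollinators of a synthetic
17×61 network (connectance 0.13, heterogeneity 2.0, generation seed 10147,
removal seed 11147), found by a seeded search for tristability and
regenerable bit-for-bit from `ecoscape.fixture.regenerate_tristable`.  At
$\kappa = 1.09$ it has three stable states — high (9/13 pollinators),
intermediate (only the degree-9 generalist) and low (all extinct).  Its
tristable window is $\kappa \in [1.06, 1.11]$; the high state folds near
1.115 and the intermediate near 1.145, so slow ramps produce a two-stage
collapse with hysteresis (median thresholds
$\kappa_1^- \approx 1.115 > \kappa_1^+ \approx 1.07$,
$\kappa_2^- = 1.145 > \kappa_2^+ \approx 1.10$ at ramp noise
$5\times10^{-4}$).

Tristability requires one dominant generalist pollinator whose mutualistic
feedback sustains it alone, while every other pollinator is too weakly
connected to invade the generalist-only state yet survives in the full
community — which is why random subnetworks are tristable only rarely and
the fixture was found by search.

## Problem sizes and runtime choices

Default experiment sizes are chosen so the full test suite and the
acceptance script each run in minutes on one core: 30-species fixture,
1×1 bistable module for passage-time ensembles (20 replicates per point),
1000-replicate BDS calibration, 20-replicate ramp ensembles, 600-start
basin weights for warning sequences, 150×150 landscape grids (200×200 in
the library default).  All experiments are seeded and deterministic.

## Known limitations

- The Gaussian-mixture landscape is a weak-noise approximation; it ignores
  skewness near folds and anharmonicity of basins, and the basin weights
  depend on the initial-condition sampler (documented above).
- Barriers are measured on the reduced 2-D landscape, not in the full
  30-dimensional space.
- The action minimizer is local; way-state initializations mitigate but do
  not guarantee global optimality, and the reported PD values depend on the
  $T$ schedule and node count.
- Colored noise is an AR(1) construction at the integration step scale;
  other colored-noise spectra with the same lag-1 correlation would differ.
- Limit cycles are not handled; non-convergent trajectories are flagged and
  excluded from basin weights.
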