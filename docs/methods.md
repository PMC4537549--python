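# Methods

## Model

The package implements a compartmental kinetic model of human sphingolipid
metabolism.  Six lipid classes — ceramide (CER), sphingomyelin (SM),
sphingosine (Sph), sphingosine-1-phosphate (S1P), ceramide-1-phosphate
(C1P) and a pooled glycosphingolipid class (GSL) — are tracked across nine
subcellular compartments: the outer and inner plasma-membrane leaflets,
cytoplasm, endoplasmic reticulum (ER), the cytoplasmic and lumenal faces of
the Golgi apparatus, nucleus, mitochondrion and lysosome.  The state vector
holds 39 species concentrations; 69 reactions connect them; 37 localized
enzyme and carrier entities catalyze the enzymatic and protein/vesicle-
mediated steps; 129 rate and inhibition constants parameterize the kinetics;
38 of the 39 species carry explicit initial concentrations (the Golgi
cytoplasmic-face GSL pool receives a class default).

Deterministic dynamics follow `dS/dt = M v(S)` with `M` the species ×
reaction net-stoichiometry matrix and `v` the flux vector.  Kinetic forms:

- **Mass action** for free transport (membrane flips, ER–nucleus lateral
  diffusion), boundary inflows and outflows: flux `k_j * prod [S]^nu`.
- **Michaelis–Menten** for enzymatic conversions and for protein- or
  vesicle-mediated transfer (CERT, vesicular ER→Golgi traffic, exo- and
  endocytosis, scramblase, CPTP, membrane-contact-site monomer exchange):
  flux `Vmax [S]/(Km + [S])` on a single rate-limiting substrate.
- **Non-competitive inhibition** multiplying any base law by
  `1/(1 + [I]/Ki)` per inhibitor.  A Michaelis–Menten law with inhibitors is
  the `MM_INHIBITED` form.  Allowing inhibitors on mass-action laws too is a
  deliberate extension: the de novo ceramide input is a constant
  (zeroth-order) inflow into the ER standing in for serine
  palmitoyltransferase, and S1P/C1P feedback acts on it.  Five inhibition
  constants are used: S1P(ER) and C1P(cytosol) on the de novo inflow,
  S1P(outer membrane) on plasma-membrane acid SMase, and S1P/C1P (cytosol)
  on lysosomal acid SMase.

Enzymes are modeled as constant modifier species (their abundance is
absorbed into `Vmax`); they do not enter the state vector.  All compartments
have unit volume, so concentrations and copy numbers share one scale and
stochastic propensities equal macroscopic fluxes.  This convention matters
for the noise analysis: absolute variance magnitudes depend on it, the flag
pattern does not.

### Species inventory

The per-compartment inventory (8 CER, 6 SM, 8 Sph, 7 S1P, 5 C1P, 5 GSL
pools) is the package's own reconstruction of the published pathway
topology; it reproduces every printed total (39/69/9/37/129/38) and the
routes described in the source material: three ceramide-synthesis routes
(de novo inflow, SM hydrolysis by compartment-specific SMases, and the
lysosomal salvage pathway through acid SMase → acid ceramidase →
re-acylation by ceramide synthases), CERT-dependent ER→Golgi ceramide
delivery feeding SM synthase and a vesicular route feeding
glucosylceramide synthase, phosphorylation/dephosphorylation cycles (SK1/2,
SPP1/2, PAP2 family, CERK), irreversible S1P degradation by S1P lyase in
the ER, exogenous inflows of CER/SM/Sph/S1P/C1P at the outer membrane, and
outer-membrane outflows of the hydrophilic monomers.

### Stationary-by-construction parameterization

The published parameter tables are not machine-readable from the available
text, so the builder derives placeholder kinetics that make the packaged
initial state an exact stationary point:

1. A strictly positive stationary flux distribution `v*` with `M v* = 0` is
   found by linear programming (HiGHS): inflow rates are pinned, every other
   flux is pulled toward a preferred pathway magnitude (L1 deviation
   objective) with a floor of 0.02 so no reaction is dead.
2. Each rate constant is solved from its reaction's flux at the operating
   point: for mass action `k = v*/prod [S]0^nu`; for Michaelis–Menten the
   family saturation `sigma = [S]0/(Km+[S]0)` fixes `Km = [S]0 (1-sigma)/sigma`
   and `Vmax = v*/sigma`; inhibition factors at the operating point are
   compensated into `k` or `Vmax` so stationarity is exact.

Saturation headroom is a *family property* and is the main modeling lever:

| family | saturation at operating point | spare capacity |
|---|---|---|
| sphingomyelinases | 0.90 (lysosomal acid SMase 0.95–0.98) | 1.0–1.1× |
| endocytic SM/GSL uptake, scramblase | 0.8–0.9 | 1.1–1.25× |
| ceramidases | 0.20 (plasma-membrane nCDase 0.35) | 2.9–5× |
| everything else | 0.50 | 2× |

SM hydrolysis running close to capacity while ceramidases retain large
reserves is what produces the disease phenotype below; it is a designed
property of the placeholder parameterization, stated here so that readers
know the qualitative results characterize this operating regime, not
measured human kinetics.

### Disease scenario

The Alzheimer's-disease patch multiplies parameters by round placeholder
factors encoding the published directions of change.  Core set: all
ceramidase `Vmax` ×0.5, all sphingosine-kinase and ceramide-kinase `Vmax`
×0.5, CERT transport ×0.1, de novo ceramide inflow ×1.15.  Corrections
(present only in the corrected scenario): vesicular ER→Golgi ceramide
transport ×0.8, all sphingomyelinase `Vmax` ×2, scramblase ×0.8.  Without
the corrections the constant SM input exceeds the saturable hydrolysis
capacity and SM grows without bound in the ER, lysosome and outer membrane
(operationally: crossing a divergence threshold of 800 concentration units,
4× the largest initial pool, within a horizon of 4000 time units); with
them every species stays bounded and the scenario shows ceramide
accumulation in the ER and lysosome, reduced S1P in all compartments, and a
sphingosine dip (ceramidase slow-down) followed by accumulation (recovering
ceramidase flux from the enlarged ceramide pools).

## Deterministic and stochastic simulation

Time courses use LSODA with analytic Jacobians, relative tolerance 1e-8 and
absolute tolerance 1e-12 — stationarity residuals feed the LNA and Fisher
matrices and must be clean.  Stationary states are found by windowed
integration with a plateau criterion (`||dx/dt||_inf < 1e-9 (1+||x||_inf)`
across a window of 10 % of the horizon) and polished by Newton
root-finding when that reduces the residual.  Divergence detection reports
every species crossing a threshold, with its first crossing time.

The stochastic oracle is a direct-method Gillespie simulation of the jump
process defined by the same stoichiometry columns and propensities; each
path draws an independent generator spawned from the root seed, so
ensembles are reproducible and order-independent.

## Sensitivity analysis

Forward sensitivities `dS_n(t)/dtheta_i` solve the variational system
derived by symbolic differentiation of the rate laws (finite differencing
is kept only as a test oracle).  Three solution paths:

- **`lti`** — from a stationary start the variational system has constant
  coefficients and is evaluated exactly through one matrix exponential per
  output time.
- **`ode`** — the joint state+sensitivity ODE, used for small systems.
- **`expm`** — for large systems away from stationarity: the state is
  solved first, then the variational system is propagated with coefficients
  frozen at each grid interval's midpoint state (exact at stationarity, a
  grid-refined approximation elsewhere).

The per-pair index is the trapezoidal integral of `|dS_n/dtheta_i|` over
the horizon (default: the stabilization horizon, 2000 time units).  Raw
derivatives are the formula-faithful default; a log-parameter normalization
(`theta_i * dS/dtheta_i`) is applied before cross-parameter *ranking*,
because comparing raw derivatives across parameters with different units is
not meaningful.  Both variants are emitted.

## Noise decomposition

At a stationary point `Phi` the Linear Noise Approximation gives the
covariance as the solution of `A Sigma + Sigma A^T + D = 0` with drift
`A_ik = sum_j m_ij df_j/dPhi_k` and diffusion `D = sum_j f_j(Phi) m_j m_j^T`.
Because the Lyapunov equation is linear in `D`, solving it once per
reaction with `D^(j) = f_j m_j m_j^T` yields per-reaction components that
sum to the total covariance exactly (enforced to 1e-8 relative).  The
stationary Lyapunov solve is the default (the analysis targets the
stabilized state); each component is PSD, being the stationary covariance
of a sub-process.  A species' component is flagged when it exceeds 110 % of
the mean of that species' components over all reactions.

## Identifiability and parameter clustering

The Fisher information matrix is `FIM = sum_t S(t)^T S(t)` over the design
grid with unit observation noise, observing all 39 non-enzyme species, in
log-parameter scale, normalized by its largest diagonal entry so thresholds
are scale-free.

**Design.** From a stationary start the variational system is linear
time-invariant, so every sensitivity matrix factors through the constant
input matrix `B = d(Mv)/dtheta` and the FIM rank cannot exceed the species
count (39).  With 129 parameters that makes *every* parameter perfectly
compensable — the strict identifiability question degenerates.  The package
therefore probes identifiability with a relaxation design: all species are
displaced to 1.5× the operating point and observed returning on 50
log-spaced times over horizon 2000.  The time-varying coefficients lift the
numerical rank to ~98 and give the filter a meaningful spectrum of multiple
correlations.

A parameter is (delta, zeta)-identifiable when `FIM_ii > zeta` and the
single canonical correlation between it and all remaining parameters stays
below `1 - delta`.  Functional redundancy between two disjoint blocks is
`-1/2 sum ln(1 - rho_j^2)` (natural log; for Gaussian parameters with
covariance `FIM^{-1}` this equals the block mutual information in nats,
which the test suite verifies).  Rank-deficient blocks are handled by
eigenvalue-clipped pseudo-inversion (relative cutoff 1e-12); a canonical
correlation within 1e-12 of 1 maps to an infinite redundancy sentinel that
orders above every finite height.

Clustering starts from identifiable singletons; each turn merges the two
sets with the largest redundancy and re-applies the identifiability filter
to the remaining parameters (per-iteration removal is the default; a
filter-once mode exists).  The dendrogram is cut at the largest relative
gap between consecutive merge heights, `(h_k - h_{k+1})/h_k` over the
sorted finite heights.

**Calibrated thresholds.**  The defaults `(delta, zeta) = (1.5e-9, 1e-6)`
for homeostasis and `(5.6e-7, 1e-6)` for the disease scenario come from a
documented sweep (delta over 1e-10..1e-3, zeta over 1e-12..1e-4): they are
the points where the filter removes 37 and 36 parameters respectively,
with the homeostasis dendrogram separating into four clusters at the gap
cut.  The disease dendrogram separates into nine clusters under the same
cut rule — its merge heights decay smoothly, with no two-branch gap — and
that computed value is reported as-is.  No single `(delta, zeta)` pair
reproduces both scenario counts, so the calibration is per scenario.

## Synthetic fixtures and what passing tests show

The toy generators provide networks with closed-form behavior: the linear
birth–death process (stationary Poisson law — mean and LNA variance both
`k1/k2`, variance split equally between the two reactions), the open linear
chain (product-Poisson stationary law, diagonal covariance), a structurally
non-identifiable pair (a flux proportional to `ka*kb`, giving a rank-1
log-FIM block and canonical correlation exactly 1), and seeded random
mass-action/Michaelis–Menten networks with an inflow→chain→outflow backbone
(non-Hurwitz draws are rejected and resampled, with the rejection count
recorded).  These fixtures exercise every pipeline stage against
independent oracles — closed forms, finite differences, exact stochastic
simulation, and the Gaussian mutual-information identity.  They emulate the
*statistical structure* the analyses assume (stationarity, intrinsic
copy-number noise, mass-action/MM propensities); they do not emulate
measured sphingolipid kinetics, so green tests validate the machinery and
the qualitative regime of the placeholder model, not quantitative human
lipid dynamics.

## Numerical choices and limitations

- Problem sizes: disease-scenario simulations use a horizon of 4000 time
  units on 400-point grids; sensitivity and FIM designs use horizon 2000
  with 201 and 50 points; SSA oracles use 10^4 paths in the acceptance
  checks and smaller ensembles (1500–3000 paths) in unit tests.
- The flux-balance program and every analysis stage are deterministic;
  stochastic stages consume one explicit root seed.
- Concentrations may undershoot zero by at most ten times the absolute
  solver tolerance; trajectories are clipped at that level.
- The LNA is exact for the first-order fixtures and an approximation for
  the saturated full model; only the flag pattern, not absolute variance
  magnitudes, should be read from it.
- The inhibition form (non-competitive, single constant per inhibitor) is
  the simplest choice consistent with a "simplified kinetics" reading;
  competitive alternatives would change the disinhibition headroom and
  hence quantitative (not directional) disease-scenario behavior.
- GSL subspecies are pooled; Aβ feedback on sphingolipid metabolism is not
  modeled; no thermodynamic (Haldane) constraints are imposed on the
  irreversible reaction pairs.
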