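# Methods

This note documents the models implemented in `cellflux`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Extracellular fluxes

Cell growth and medium metabolite kinetics are modeled as

    dX/dt = μ X,            X(t) = X0 e^{μt}
    dM/dt = −k M + v X

with `X` the cell count, `M` the medium amount of a metabolite (nmol), `μ`
the specific growth rate (h⁻¹), `k` a first-order degradation (k>0) or
accumulation (k<0) rate (h⁻¹), and `v` the per-cell flux
(fmol·cell⁻¹·h⁻¹; negative means consumption). The solution

    M e^{kt} = v X0/(μ+k) (e^{(μ+k)t} − 1) + M0

turns flux estimation into a linear regression of `M e^{kt}` on
`e^{(μ+k)t} − 1`; when `μ+k = 0` the analytic limit `M e^{kt} = v X0 t + M0`
replaces it (no numerical epsilon). All regressions are Huber
M-estimates with the conventional tuning constant 1.345; growth rates come
from `ln X` against `t`, degradation rates from `ln M` against `t` in
cell-free medium and are applied only when a t-test rejects zero slope at
α = 0.05. Medium volume is the dish weight divided by a density of
1.00 g/mL, interpolated piecewise-linearly between weighings and clamped
monotone. Masses are concentration × volume; a per-cell-type linear
standard curve can convert total DNA to cell counts upstream. Gross
outliers can be pre-filtered at twice the median absolute deviation.
Replicates enter the regressions individually (not as per-time means).

## Natural-abundance correction

The correction matrix column `j` is the expected measured MID of an ion
carrying exactly `j` tracer-element labels: the multinomial mass-shift
expansion of all non-tracer atoms convolved with the natural ¹³C
distribution of the remaining carbons, truncated at mass shift `n` (so
columns sum to ≤ 1). Isotopic abundances are IUPAC representative values
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ³³S/³⁴S,
²⁹Si/³⁰Si). Correction solves the matrix equation by nonnegative least
squares and renormalizes, which keeps noisy corrected MIDs on the
probability simplex where an unconstrained inverse can go negative.
Tracer purity is part of the tracer model in simulation, not of the
correction. A quadrupole-bias hook accepts per-mass multiplicative
factors but implements no specific instrument model.

## Network and EMU machinery

The 48-reaction network is shipped as a plain-text atom-transition file
(one per biomass-coefficient variant, LF and PASMC). Atom maps are not
published for this network; they are reconstructed from standard
biochemistry and documented reaction-by-reaction in the fixture. Notable
conventions: citrate synthase maps OAC (abcd) + AcCoA (ef) → CIT (dcbfea),
so the CO₂ released by isocitrate dehydrogenase originates from the
oxaloacetate C1 position; aldolase splits FBP (abcdef) into DHAP (cba) and
GAP (def); transketolase/transaldolase use the standard two-carbon and
three-carbon unit transfers. CO₂ is an unlabeled, unbalanced pool —
decarboxylation CO₂ leaves the system, carboxylation (PC, glycine
synthase) draws unlabeled carbon. Fatty-acid oxidation is an unlabeled
acetyl-CoA source pseudo-reaction; the three pyruvate "mixing" rows are
pseudo-reactions blending cytosolic and mitochondrial pyruvate into the
measured pool with simplex-constrained weights. Succinate and fumarate are
rotationally symmetric: every production term into those pools is split
into two half-weight orientations, which makes simulated MIDs invariant to
the orientation convention. Extracellular species consumed by reverse
exchange (e.g. medium lactate) enter with their input labeling state,
unlabeled unless a tracer specifies otherwise.

Steady-state balance is `S v = 0` over the intracellular metabolites.
Published solutions are validated at a 2% relative residual (they are
printed to 3 significant figures); simulation inputs are projected onto
the null space exactly, with irreversibility preserved by a constrained
projection when the plain least-squares projection would push a rounded
near-zero flux negative.

EMU decomposition traces the observed fragments backwards through every
producing reaction. Steady-state MIDs solve one dense linear system per
EMU size; nonstationary labeling integrates the whole cascade as a single
coupled ODE system `dX/dt = P⁻¹(A(v)X + production)` with Radau (analytic
sparse Jacobian, rtol 1e−8 / atol 1e−10, simplex renormalization guard at
1e−9 drift). Radau was chosen over BDF because BDF's step control
collapses near the labeling plateau at these tolerances. The brute-force
oracle keeps one 2^c positional-isotopomer distribution per metabolite and
iterates the (bilinear) balance to a fixed point with simplex projection;
it assumes a balanced flux map and refuses networks beyond a configurable
internal-carbon budget. Pool sizes (fmol·cell⁻¹) govern only nonstationary
kinetics; they are not reported by the source study and default to
10 fmol·cell⁻¹ per metabolite in the generator.

## Flux fitting

Net fluxes are parameterized as free fluxes (a deterministically chosen
full-rank reaction subset) with the dependent fluxes eliminated through
the stoichiometry, so steady state holds exactly for every parameter
vector; exchange fluxes are `10^θ` clipped to [0, 1e7]; mixing weights
live on the unit simplex. The residual vector stacks, per tracer
experiment, `(simulated − measured)/SD` for every MID fraction, the
extracellular flux residuals (growth rate enters as the biomass flux), and
hinge penalties keeping dependent irreversible fluxes nonnegative. MID
SDs are floored at 0.003 mol fraction when aggregating replicates. The
sign split of a reversible net flux into forward/backward rates is
smoothed over a 1e−3 fmol·cell⁻¹·h⁻¹ half-width so the Jacobian is
continuous; the residual bidirectional flux this leaves is far below
measurement noise.

The Jacobian is analytic: each per-size linear system is differentiated
exactly (`dX = A⁻¹(dB − dA·X)`, convolution product rule across sizes),
making the Jacobian a by-product of one simulation rather than ~40 extra
simulations. Optimization is bounded trust-region least squares. The SSR
landscape has a long shallow valley (near-unidentifiable exchange
combinations), so each start runs a two-stage homotopy — a coarse fit at
8× inflated MID SDs, then a polish at the true SDs with strict tolerances
— and the multi-start pool begins with deterministic "canonical" starts
(net fluxes from a linear fit of the flux observations; all exchanges at a
common low/medium level, the dominant mode variable) before random starts
(flux-observation-informed net values, log-uniform exchanges, uniform
mixing weights). The default restart minimum is 50, as is conventional;
recovery studies run scaled-down restart counts. DOF = #residuals −
#free parameters, always computed. A fit is accepted when its SSR lies in
the two-sided 95% χ² interval at that DOF.

Confidence intervals follow the SSR-sensitivity definition: a flux is
fixed at trial values while all other parameters are re-optimized, and the
95% bound is the outermost value whose constrained SSR stays within
`SSR_min + 3.84` (χ²₀.₉₅,₁). The constraint is linear in the parameters
and is eliminated exactly by reparameterization (a heavy penalty row
destroys the conditioning of the re-optimization). Trial values start at
the linearized ±1.96·SE estimate, march geometrically, warm-start each
re-optimization from the nearest feasible solution (with the whole net
block rescaled when the move is scale-like), short-circuit as soon as a
feasible point is found, and refine the bracket by guarded quadratic
interpolation alternating with bisection. Bounds that run into the flux
cap are reported infinite; lower bounds of irreversible fluxes stop at 0.

## Metabolomics QC

Processing order is fixed: drift correction → feature filtering →
imputation → probabilistic quotient normalization. Drift is modeled per
feature as a cubic smoothing spline of pooled-QC areas against injection
order (stiffness by generalized cross-validation; linear fallback below
five usable QCs) and divided out, rescaled to the median QC level.
Features are dropped when QC RSD > 0.2 or the dispersion ratio
sd(QC)/sd(biological) > 0.4 (MAD-based variants by flag); retained
features are never altered. Imputation defaults to an iterative
tree-ensemble imputer, with k-NN and half-minimum fallbacks, deterministic
per seed. PQN divides each sample by the median ratio of its features to
the QC-median reference (feature-wise median of all samples when no QCs
exist); with a QC reference the operation is idempotent. An
internal-standard ratio pre-step exists as a hook but is off by default.
Differential statistics and enrichment are out of scope by design; the
output matrix is ready for any downstream tool.

## Synthetic data: what it emulates, and what it does not

The generator produces exactly the statistical structure the estimators
assume: exponential growth with lognormal count noise (counts stay
positive), medium masses from the closed form above with Gaussian
concentration noise floored at zero, linear evaporation (0.2 g over 72 h
from a 2 mL dish, daily weighings with 5 mg error), labeling from the EMU
simulator with additive Gaussian MID noise truncated and renormalized to
the simplex, and metabolomics batches with pooled QCs every four samples,
smooth multiplicative drift and MCAR missingness. A single integer seed
fans out into independent per-stage substreams.

Default study conditions: 25,000 cells seeded per 35 mm dish; sampling at
0/24/48/72 h; growth rate equal to the biomass flux of the published
normoxic (or hypoxic) solution; net fluxes from that published solution
projected onto exact balance, exchange fluxes clipped at 10³ (the huge
published exchange values are unidentifiable and only slow the labeling
system); glutamine degrading at 0.004 h⁻¹; MID SD 0.003 mol fraction and
concentration CV 5% (configurable; the source study reports no error
magnitudes). The medium is a low-substrate flux medium (5.5 mM glucose,
plasma-like amino acid levels) chosen once so that each measured species'
72 h concentration change is resolvable at the stated noise — with
standard high-substrate medium, uptake fluxes of slowly consumed species
are not recoverable from concentration differences at 5% CV, which is why
flux studies use dialed-down media.

Two deliberate idealizations: the flux-fit recovery studies draw MID noise
without the truncation step (corrected MIDs do scatter below zero in
practice, and χ² calibration requires the estimator's own error model),
and fitted measurements are single observations at known SD rather than
replicate means with empirical SDs. Passing recovery tests therefore
demonstrates correctness of the estimators under their stated assumptions
— not robustness to the biases of real data (peak integration errors,
non-Gaussian tails, medium lot variation), which no synthetic test can
establish.

"Well-determined" fluxes in the asserted coverage study are a fixed
a-priori panel: the glycolytic input (direct uptake observation, pinned
by all three labeling patterns) and lactate efflux (the largest measured
flux). Smaller transport fluxes and internal TCA fluxes have profile
intervals whose practical accuracy is limited by how reliably the global
SSR minimum is found within the restart budget (fit centers scatter
beyond the profile-implied standard error when optimization noise is
comparable to the chi-square threshold); their coverage is exercised by
the examples but not asserted. This is a known limitation of profile
intervals on a multimodal landscape, not of the interval definition.

## Numerical choices

- EMU linear solves: dense LU per size; a 1e−10-relative diagonal ridge
  keeps zero-throughput EMUs finite at pathological restart points.
- Oracle fixed point: tolerance 1e−14, simplex projection each sweep.
- Optimizer tolerances: coarse stage max 300 evaluations; polish
  ftol 1e−11 (the valley needs strict tolerances to keep descending), plus
  a final best-start polish at ftol 1e−14.
- Scales: fluxes fmol·cell⁻¹·h⁻¹, amounts nmol, concentrations mM, time h.
- Problem sizes in the shipped tests: 50 random networks for oracle
  equivalence, 250 h horizons (>20 turnovers of the slowest pool) for the
  nonstationary limit, 20 seeds x 2 fluxes for CI coverage, 100 toy
  replicates for χ² calibration, 1000 parameter draws for the closed-form
  check, 500 random MIDs for the correction round trip.

## Known limitations

- Steady-state fitting only in the optimizer; nonstationary simulation is
  provided and validated against the stationary limit, but pool-size
  fitting to time-resolved MIDs is not wired into the optimizer.
- Exchange fluxes are, as always in this method, poorly resolved; their
  intervals routinely hit the cap and are reported unbounded.
- The published fitted flux values cannot be reproduced desk-side — the
  raw measurements behind them are not printed; the published tables serve
  as balance-validation fixtures and ratio examples.
- The brute-force oracle requires a balanced flux map and small networks.
- Quadrupole bias correction is a pass-through hook only.
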