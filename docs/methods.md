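# Methods

This note records the models, conventions, and numerical choices behind
each stage of the inference chain, what the synthetic generator does and
does not emulate, and the design decisions taken where the underlying
protocol left the choice open.

## Physical setting and units

The reaction coordinate ξ is the membrane-normal position of a solute's
center of mass, running from the unglycosylated (phospholipid) side at
−35 Å to the glycosylated (LPS) side at +65 Å in the standard protocol.
Internally: lengths in Å, times in ps, energies in kcal/mol,
diffusivities in Å²/ns. Permeabilities are reported in cm/s
(1 Å/ns = 10 cm/s exactly), fluxes in fmol/s and molecules/s. Constants
live in `ompermeate.constants`: k_B = 0.0019872041 kcal mol⁻¹ K⁻¹,
N_A = 6.02214076 × 10²³ mol⁻¹. The default temperature is 310 K, where
RT ln 10 = 1.4184 kcal/mol.

## Synthetic data generator

The generator replaces the MD engine with overdamped Langevin dynamics
on a `LandscapeSpec` holding ground-truth G(ξ) and D(ξ). The update is
Euler–Maruyama in the Itô convention,

    ξ' = ξ + [−β D(ξ) G_tot′(ξ) + D′(ξ)] dt + sqrt(2 D(ξ) dt) η,

with G_tot including the harmonic umbrella bias ½k(ξ−ξ₀)². The
spurious-drift term D′(ξ) is essential: without it the stationary law
with position-dependent D is not Boltzmann and every recovery test
would be biased (the test suite checks this by verifying uniform
occupancy across a 4× diffusivity dip under flat G). Derivatives are
analytic for the analytic landscape forms and centered finite
differences (step 10⁻⁴ Å) for tabulated ones; piecewise diffusivities
are blended with tanh ramps so D′ exists everywhere. Boundaries are
reflecting by default, periodic when the landscape is flagged periodic.

Defaults: dt = 0.01 ps (the integrator warns when
dt·D_max/feature² > 0.05), collective-variable output stride 0.1 ps so
that ten samples fall in each exchange interval — the output stride of
the production protocol is not specified anywhere, so this is a package
choice, surfaced in `RunConfig`. Random streams: each window's dynamics
use an independent substream keyed by (seed, window_id), so adding
windows never perturbs existing ones; exchange decisions use a separate
substream. All generators are bit-reproducible under a fixed seed.

Replica exchange attempts configuration swaps between alternating
neighbour pairs (even pairs, then odd) every 1 ps, accepting with
min(1, exp(−β ΔU)) where ΔU is the cross-evaluation of the two harmonic
biases. The standard umbrella geometry is 180 intervals (181 centers)
over −35…65 Å with k = 4 kcal mol⁻¹ Å⁻²; the exact spacing is
100/180 ≈ 0.556 Å (the commonly quoted 0.55 Å does not divide the
100 Å span). Mean acceptance below 0.05 triggers a poor-overlap
warning.

What the generator does *not* emulate: atomistic degrees of freedom,
leaflet chemistry, orthogonal slow modes (the 1-D dynamics relax much
more cleanly than a real solute in LPS), and correlated noise between
windows. Passing recovery tests therefore demonstrates correctness of
the estimators, not the adequacy of sampling in any particular real
system.

## Free-energy reconstruction (WHAM)

The point estimate is standard binned WHAM, iterating the unbiased bin
probabilities and window free-energy constants until the constants move
by less than 10⁻⁷ kcal/mol between sweeps (the protocol states no
tolerance; this is far below statistical error). Defaults: 0.25 Å bins
over the reaction-coordinate range — finer than the umbrella spacing,
coarse enough to populate — and a 10% equilibration discard at the head
of each window (no discard policy is stated; configurable). Bins
receiving no samples are masked, never imputed, and interior gaps emit
a non-overlap warning. With a periodic coordinate the bias distances
use the minimal image and the first bin's value is replicated at the
far edge, making G exactly equal at the two ends. The solution zero
point is applied by `set_reference` (mean over a stated aqueous range
→ 0); `symmetrize` averages a profile with its mirror image about a
center, the standard mitigation for poorly sampled charged species.

Uncertainty: the Bayesian layer resamples each window's binned counts
from a Dirichlet posterior restricted to that window's occupied bins
(the Bayesian-bootstrap limit of a Dirichlet prior) and re-solves WHAM
warm-started from the point estimate; `sd` is the pointwise standard
deviation across draws. This follows the Dirichlet/Gibbs mechanism of
Bayesian WHAM while making no claim to replicate any particular
implementation; the point estimate remains the plain WHAM profile. The
layer passes the expected checks: sd → 0 under huge counts, sd shrinks
by ≈1/√2 when the data are duplicated, and a fixed seed reproduces the
sd vector exactly. Posterior draws can be pushed through the whole
permeability chain to propagate uncertainty onto log Pm.

An independent multistate-reweighting oracle (a log-sum-exp likelihood
maximized with L-BFGS, a different algorithm and parameterization) is
kept in the test suite and agrees with the fixed-point WHAM to better
than 0.05 kcal/mol on small instances.

## Diffusivity estimation

Biased-window route: within a harmonic window the restrained coordinate
is approximately Ornstein–Uhlenbeck, so D = var(ξ)/τ. The variance is
taken over all post-equilibration samples of the window (segments
between exchanges are too short for a stable variance); τ comes from a
least-squares exponential fit to the log of the normalized
autocorrelation function, using lags where the ACF exceeds 0.05,
weighted by the number of contributing pairs.

The ACF is computed strictly *within the intervals between exchange
attempts* (deviations from the whole-window mean, pooled across
intervals). Cutting only at accepted swaps is subtly wrong: a segment
that merely survived several attempts is conditioned on those
rejections — acceptance depends on position — and its apparent
correlation time is biased low by tens of percent at typical acceptance
ratios. Intervals between attempts carry no such conditioning, and the
estimator then recovers the OU closed forms (var = k_BT/k,
τ = k_BT/(kD)) to a few percent. A non-decaying ACF falls back to the
integrated autocorrelation time with a warning; an ACF already below
the floor at the first lag reports τ at the sampling resolution bound.
Whether the production analysis took the variance per segment or per
window is not stated; per window is the choice here, for stability.

Equilibrium route: the Einstein relation on displacements at a fixed
lag (default 20 ps), binned by the displacement's starting
membrane-normal position; dims=1 uses the membrane-normal component,
dims=2 the two lateral components. Drift removal (subtracting the
per-bin mean displacement) is off by default and available as a flag —
a rigid drift v contaminates the estimate by v²·lag/(2·dims) otherwise.

## Permeability

Spline fits: smoothing = 0 gives the interpolating cubic spline
(not-a-knot; reproduces cubic polynomials exactly), positive values a
FITPACK smoothing spline with that residual budget. Masked bins are
excluded from fitting. The solubility-diffusion integral is evaluated
by composite Simpson on a 0.05 Å grid of the fits ("numerically
integrate" is all the protocol states); it agrees with a dense
brute-force trapezoid to better than 0.1% on smooth profiles.

The regional decomposition finds the free-energy minima of the fitted
profile over the unglycosylated-side search range (−22, −5) Å and
glycosylated-side range (5, 22) Å (ties break to the leftmost point,
with a warning; monotone intervals return the edge-adjacent minimum
with a warning). Each regional integral re-references G to the minimum
within its own integration range — the regional minimum, not the global
one, because the recombination then needs exactly the partition
coefficient logP = (G_aq − G_mem)/(RT ln 10), with G_mem the lower of
the two boundary minima, to restore the solution reference:

    log Pm = logP + log₁₀[(Pm_u⁻¹ + Pm_c⁻¹ + Pm_g⁻¹)⁻¹].

This identity is enforced to 10⁻⁹ on every `PermeabilityBreakdown`.
Components of −∞ propagate as exact zeros in the linear domain.

O-antigen extrapolation: the incremental resistance per Å of added
glycan is taken at ξ_max, the free-energy maximum within the LPS search
range, as exp(βG(ξ_max))/D(ξ_max). For a target of multiplying the
total resistance R = 1/Pm by `factor`, the added thickness is
L = (factor − 1)·R·D(ξ_max)·exp(−βG(ξ_max)). The printed form of this
relation can also be read as *added* resistance = factor·R (an
(factor+1)-fold total); that reading is available via
`added_resistance_multiple`, but the default follows the strict
"factor-fold total" semantics, which is also what the worked closed
forms imply (unit profile, factor 10 → L = 9 Å). A flat profile over
the search range falls back to its midpoint with a warning.

Stitching of overlapping profile segments (e.g. 15 windows of 13 Å
with 2 Å overlap from a multi-segment free-energy calculation): each
segment is shifted by the constant minimizing the squared disagreement
with its already-shifted predecessor over the overlap, the first
segment unshifted; overlapping points are averaged. Per-join RMS
residuals above 0.25 kcal/mol (an injected discontinuity, not mere
noise) raise a warning. Cutting a profile into such segments and
stitching reconstructs it exactly up to a global constant.

## Transport

Serial permeability Pm_t = Pm_o·Pm_i/(Pm_o+Pm_i) (harmonic
combination: half of either when equal, limited by the smaller
otherwise) and steady-state flux J = Pm_t·A·Δc with the unit chain
fixed internally (1 mM = 10⁻⁶ mol/cm³, 1 μm² = 10⁻⁸ cm²). The
rod-shaped cell surface area uses the lateral-cylinder convention
π·d·L (1.257 μm² for a 1 μm × 0.4 μm cell, printed as 1.25);
spherocylinder and capped alternatives are available behind a flag.
Classification tags a compound OM-limited when log Pm_o < log Pm_i and
builds per-class empirical CDFs of the difference.

## Observables

Compartment labelling uses three ordered boundaries (inner solution |
core | glycan | outer solution) with a hysteresis band, default 2 Å: a
molecule must penetrate that far past a boundary before its label
switches, suppressing flicker counting. No event-counting rule is
published for such traces, only the traces themselves — the hysteresis
value is a package choice. A full crossing is a
solution-to-opposite-solution traversal that visited both core and
glycan; a leaflet exchange is a core-midplane crossing with the same
margin; a glycan entry is an entry into the glycan region from the
outer solution. Unwrapping accumulates minimal-image increments and
warns when any step approaches half the box (undersampling). Order
parameters: −S_CD = −⟨3cos²θ_CH − 1⟩/2 against the stored membrane
normal, bounded by [−1, 0.5].

## Validation experiments and problem sizes

`ompermeate.validation.reus_recovery` runs the chain end-to-end on an
asymmetric two-barrier landscape (22 Å span, barriers 3 and
2 kcal/mol flanking a −2 kcal/mol well, constant D = 50 Å²/ns, 310 K)
with 40 windows at the standard force constant and exchange interval
and 10 ns per window — a deliberate scale-down of the production
protocol (180 intervals × 40 ns over 100 Å) that keeps the experiment
at about one CPU-minute while preserving the umbrella spacing and
exchange physics. Typical results (seed 1): free-energy RMSE
≈ 0.08 kcal/mol, interior-window diffusivity error ≈ 5%, log Pm within
≈ 0.03 log units of the analytic integral — comfortably inside the
0.2-log-unit uncertainty regarded as typical for such calculations.
The error budget is dominated by the random-walk accumulation of
window-to-window matching errors in WHAM, which shrinks as
1/√(window length); the suite checks this monotone convergence
explicitly.

## Known limitations

- The 1-D generator cannot expose errors that arise from orthogonal
  slow degrees of freedom or hidden barriers in real systems.
- The variance/ACF diffusivity estimator assumes locally harmonic,
  memoryless dynamics; strongly anharmonic wells or non-Markovian
  friction would bias it.
- The Bayesian uncertainty layer resamples within windows only; it
  does not model correlation between windows induced by exchanges.
- The regional decomposition identity is exact by construction, but the
  decomposed total equals the full-span integral only approximately
  when the two interfacial minima differ in depth (the re-referencing
  argument above).
- Peptidoglycan resistance and solute metabolism kinetics are outside
  the transport model; concentrations are boundary conditions.
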