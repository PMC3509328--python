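# Methods

## Model

One strand of the actin double helix carries N = 700 monomers at 5.5 nm
axial spacing (3.85 µm), a regulatory TnI site on every seventh monomer
starting from the third (I = 100), and one continuous flexible chain (CFC):
the overlapping tropomyosin–troponin assembly treated as an elastically
homogeneous beam confined in an azimuthal harmonic well,

    E{φ} = ∫₀ᴸ [ κ/2 φ''(s)² + α/2 φ(s)² ] ds .

The two strands of a filament are independent subsystems; inter-chain
coupling through troponin is not modelled.

Because E is a positive-definite quadratic form, the thermal ensemble of
chain shapes is Gaussian: the constrained energy minimum equals the
conditional mean given the pin values, and the per-site variance is k_BT
times the diagonal of the inverse stiffness operator restricted to unpinned
degrees of freedom. Pins are point value-constraints: bound TnI at
φ₋ = −25°, strongly bound myosin-S1 at φ₊ = +10° (the "attracted to the
head" convention; a purely steric φ ≥ φ₊ treatment would behave similarly
because configurations beyond φ₊ are rare when the kink energy 4κξ³φ₊²
exceeds k_BT). Weakly bound myosin does not pin the chain; its only direct
chain-side effect in this implementation is that TnI cannot rebind to a
monomer carrying any bound myosin.

Kinetics are gated by the fraction of time the fast-equilibrating chain
spends past an angular threshold, Gaussian tail weights evaluated at each
site's (φ̄ᵢ, σᵢ):

    r_I  = ½ erfc[(φ̄ᵢ − φ₋)/(√2 σᵢ)]        TnI rebinding (φ ≤ φ₋)
    r_M1 = ½ erfc[(φₒ − φ̄ᵢ)/(√2 σᵢ)]        weak binding (φ ≥ φₒ)
    r_M2 = ½ erfc[(φ₊ − φ̄ᵢ)/(√2 σᵢ)]        isomerisation (φ ≥ φ₊)

each normalised once by its free-chain value (r_I° = 0.2, r_M1° = ½,
r_M2° ≈ 0.368), so the closed state reproduces the unregulated constants.
TnI detachment (k₋I, the only calcium-dependent rate), myosin detachment
and reverse isomerisation are unregulated. Weak binding is additionally
scaled by the empirical crowding factor δ = 1 − 0.82 (n_AM/n_A) and by the
depleting free-myosin pool [M] = [M_tot] − f[A_tot], both tracked over the
whole ensemble (well-mixed solution). Strong myosin cannot detach directly;
it must first reverse-isomerise (FREE ↔ WEAK ↔ STRONG).

## Default parameters

| quantity | default | units | origin |
|---|---|---|---|
| φ₋, φₒ, φ₊ | −25, 0, +10 | deg | cryo-EM blocked/closed/open orientations |
| κ | 2.0×10⁴ | pN nm⁴ | κ_TmTn·R², L_p(TmTn) = 250 nm, R = 4.5 nm |
| σₒ | 29.7 | deg | 20% blocked fraction: σₒ = 25°/0.84162 |
| 1/ξ | 22.0 (printed 22.2) | nm | inversion of σₒ = (k_BT/8κξ³)^½ |
| α | 0.342 (printed 0.341) | pN | identity α = 4κξ⁴ |
| k_BT | 4.045 | pN nm | 293 K; the source table's derived values imply ≈3.95, which accounts for the ~1% gaps above |
| k_M1°, k₋M1 | 4.2×10⁶, 20 | M⁻¹s⁻¹, s⁻¹ | unregulated weak binding |
| k_M2°, k₋M2 | 500, 5 | s⁻¹ | isomerisation (K_M2 = 100) |
| k_I°, k₋I | 100, ~1200 (high Ca) | s⁻¹ | TnI–actin; K_B = k₋I/k_I° |
| Δt | 10⁻⁵ | s | published step; configurable |
| N, I | 700, 100 | — | strand geometry |
| ensemble | 2000 strands (excess actin), 200 (excess myosin) | — | published counts |
| burn-in | 0.5 | s | TnI-only pre-equilibration before mixing |

φₒ is fixed at zero; no angular offset is supported.

## Numerics

**Chain solver** (`chainmech`). Central finite differences for φ'' on a
uniform grid, default h = 5.5/4 nm (ξh ≈ 0.06); omitting the end-node
curvature terms yields natural (free) boundary conditions. The stiffness is
pentadiagonal; means come from a banded Cholesky solve with pinned nodes
eliminated, variances from selected columns of the inverse via the same
factorisation. Single-pin solutions match the closed form
e^(−ξs)(cos ξs + sin ξs) to <0.5%, and variance converges to σₒ² at
second order in h. Two caveats are physical, not bugs: (i) at a *free end*
the thermal SD rises to ≈1.94 σₒ (clamping is absent on one side), so
"σ ≤ σₒ" holds only away from the ends; (ii) between two nearby pins at
equal angles the mean can overshoot the pin angle by a few percent — the
oscillatory Green's function of the fourth-order operator permits it.

`segment_update` re-solves only windows of ±~38/ξ around changed pins,
clamping a node *pair* at each window edge (which decouples the
pentadiagonal system exactly); it agrees with a full re-solve to 1e-8.

**Engine chain evaluation** (`ChainConditioner`). During simulation, chain
state at a site is the Gaussian conditional mean/SD given the nearest ≤6
pins on each side within a 10/ξ window, computed from the exact site
covariance G = k_BT K⁻¹ precomputed once by the banded solver. This is
mathematically the whole-chain constrained solve restricted to the pins
that matter (correlations decay as e^(−ξd)); agreement with the global
solve is <0.2% in φ̄ and far better in σ. A literal nearest-pair
approximation with free chain beyond the two pins is *not* used: under
dense TnI pinning it errs by tens of percent, because value-only pins do
not screen the fourth-order field. The piecewise segment method with
matched slope and curvature at shared pins is equivalent to the global
solve, which is what the conditioner reproduces.

**Monte Carlo step** (`engine`, `_kernel`). Fixed Δt, two drawings per step
(regulatory sites first, then actin sites), both evaluated against the
start-of-step state; a TnI that rebinds in a step blocks weak binding on
its monomer within that step. Per-site Bernoulli transitions are sampled by
thinning: per pool of same-state sites, a Binomial(n, p_max) count of
candidates at a per-pool bound (e.g. p_max = 2δk_M1°[M]Δt for binding,
since r_M1 ≤ 1 = 2 r_M1°), uniform distinct candidate sites, acceptance
with pᵢ/p_max. Marginals and independence are identical to one uniform
draw per site; a test verifies this against a naive per-site sampler. The
same process is implemented twice: a vectorised numpy reference and a numba
kernel with O(1) pool bookkeeping (~15× faster); the two backends use
different random streams but are each bit-reproducible for a fixed seed and
are statistically cross-validated. A step-probability bound >1 raises an
error, >0.05 warns (the published Δt = 10⁻⁵ s already puts k₋IΔt at 0.012;
a Δt-halving test confirms the transient is converged at default
parameters).

Initialisation is a cold start (all TnI bound, no myosin) followed by
TnI-only burn-in at the target calcium; at t = 0 myosin becomes available,
mimicking stopped-flow mixing. `chain_coupling=False` disables all pinning
feedback, reducing the engine to two-step mass action with depletion and
crowding — the limit used to validate it against an ODE solution.

## Observables and fitting

The comparison quantity is g(t) = 1 − n_STRONG/n_A, the fraction of sites
not in the R-state (pyrene fluorescence is quenched only by strong
binding). Fitting k₋I to an observed normalised trace minimises SSE over
log₁₀k₋I (coarse grid + bounded Brent) with common random numbers across
candidates; affine scale/offset nuisance parameters are profiled out in
closed form per candidate because the experimental normalisation convention
(min–max vs initial-value) is instrument-specific and unknowable. A
flat-objective diagnostic (SSE spread < 5% of the trace's total variation)
flags the calcium-insensitive regime: above K_B ≈ 10 the transient barely
depends on k₋I, so high-calcium estimates constrain K_B only weakly — an
intrinsic property of the model, not of the optimiser. The K_B–pCa summary
uses a four-parameter log-logistic (Hill) fit in [Ca²⁺]; the functional
form is this package's choice.

## Synthetic data

The published stopped-flow dataset is not deposited, so recovery studies
use `make_synthetic_transient`: a simulator run at a known K_B with i.i.d.
Gaussian noise of SD 0.01 added to the not-R fraction (≈1% of full scale,
a typical stopped-flow noise floor), at the published concentration pairs
([actin]/[S1] = 2.5/0.25 µM and 0.5/5.0 µM). This emulates the amplitude
statistics of a normalised pyrene trace but not instrument artefacts
(mixing dead time, photobleaching drift, correlated shot noise), so
passing recovery tests demonstrates identifiability under the model's own
noise assumptions, not robustness to instrument systematics. Recovery at
500 strands and 1% noise is ~2% (K_B = 0.12), ~9% (K_B = 0.47), and weakly
constrained in the flat regime (K_B ≈ 12), with excess-actin and
excess-myosin estimates of a common K_B agreeing within ~8%.

## Problem sizes used in the test suite

Unit tests use small strands (7–200 sites) and ensembles (≤400). The
end-to-end checks use: mass-action limit at 2000 strands, 0.12 s, Δt 10⁻⁵ s;
recovery fits at 500 strands (excess actin; 200 for excess myosin),
durations 0.4–1.0 s covering ≥90% of each decay, Δt 2×10⁻⁵ s (convergence
at this step verified separately); qualitative regulation checks at 100–200
strands. These sizes are the package's default trade-off between Monte
Carlo error and turnaround; all are configurable.

## Known limitations

* TnI detachment is calcium-only; strain-dependent TnI kinetics are not
  modelled. Detailed balance is not strictly satisfied by the weighted
  rates (inherited from the model's kinetic closure).
* The crowding factor δ is an empirical linear formula, not a mechanistic
  steric model.
* No allosteric TnC–calcium scheme: K_B(pCa) is estimated pointwise and
  summarised by a Hill fit rather than predicted from calcium binding.
* Chains on the two strands of one filament do not interact.
* The fixed-Δt scheme admits O((kΔt)²) multi-event effects per subsystem
  per step; no exact-SSA variant is provided.
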