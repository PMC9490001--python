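# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## ¹⁵N relaxation and model-free analysis

Amide ¹⁵N relaxation is modelled with the standard dipolar + chemical-shift-
anisotropy expressions evaluated on the Lipari–Szabo spectral density

    J(ω) = (2/5) [ S² τ_m / (1 + (ω τ_m)²) + (1 − S²) τ / (1 + (ω τ)²) ],
    1/τ = 1/τ_m + 1/τ_e,

with isotropic overall tumbling (no axially symmetric diffusion tensor — the
analyses this package targets report none). Physical constants follow common
model-free practice: effective N–H bond length 1.02 Å, ¹⁵N CSA Δσ = −160 ppm,
CODATA gyromagnetic ratios; the default field is a 700 MHz proton frequency.
An exchange term R_ex adds to R₂ only.

**Exponential fitting.** R₁/R₂ (and HX) decays are fit as `I(t) = A·e^(−Rt)`
by Levenberg–Marquardt with a log-linear initial guess; parameter errors come
from the fit covariance (scaled by per-point errors when present). The fitted
rate is invariant under rescaling all intensities, which the property tests
assert. At 2% amplitude noise on the canonical 7-delay grid the estimator
bias is below 0.1%; the scatter of a single fit is ≈4%, so averages over 100
replicates carry a ≈0.4% Monte-Carlo standard error.

**Exchange flagging.** Residues whose R₂/R₁ exceeds the 10%-trimmed mean plus
k = 1.5 trimmed standard deviations are flagged as candidate slow-exchange
sites (both constants configurable; no published threshold exists for this
step, so a robust-statistics default was chosen).

**τ_m estimation.** The rigid isotropic R₂/R₁ ratio is strictly increasing in
τ_m, so the mean ratio of non-flagged residues is inverted by bracketed
root-finding; errors by seeded bootstrap (200 resamples). Because real
residues have S² < 1 and τ_e > 0, this classical estimator carries a small
(≈2–3%) downward bias that the recovery tests quantify.

**Model selection.** Each residue is fit with the four nested models {S²},
{S², τ_e}, {S², R_ex}, {S², τ_e, R_ex} and scored by the plain Akaike
criterion χ² + 2k. The small-sample AICc correction is *undefined* here: with
n = 3 observations the correction term divides by n − k − 1 ≤ 0 for the two-
and three-parameter models, so the uncorrected penalty is used; it is
deterministic and monotone in k, which is what the selection needs. Residues
whose best model still exceeds a configurable χ² threshold are flagged, never
silently dropped.

**What single-field data can and cannot identify.** With three observables
per residue, S² is strongly determined (mean-S² recovery within 0.02 at 3%
noise in the 50-residue study), but τ_e sits on a flat likelihood ridge for
high-S² residues: noise can trade a smaller (1 − S²) against a much larger
τ_e at essentially unchanged χ². The per-residue τ_e distribution therefore
has a fat right tail, and the *mean* τ_e recovery error fluctuates between
roughly 3% and 30% across noise realizations (the median-based error is more
stable). This is an identifiability property of single-field model-free
analysis, not an optimizer artefact; the acceptance script reports both the
mean- and the median-based error.

## Residual dipolar couplings

A coupling for unit internuclear vector **v** under Saupe order matrix S is
`D = D_max · vᵀS v`, with `D_max = −(μ₀/4π)·γ₁γ₂ħ/(2π²r³)` the pair-specific
static dipolar constant (N–H with r = 1.02 Å; C′–N with r = 1.329 Å; under
this normalisation typical protein alignments correspond to Saupe magnitudes
of order 10⁻³–10⁻⁴ and couplings of a few Hz). N–H and C′–N couplings are
kept in native Hz and weighted by 1/σ² when errors are present — they are not
rescaled onto a common scale, since the mixing normalisation is a free
convention and the weighting already accounts for the different magnitudes.

The Saupe matrix is linear in five independent components, so the
**SVD fit** is a weighted linear least-squares solve; a design-matrix
condition number above 10⁸ (collinear bond vectors) is rejected explicitly.
Agreement is scored with the Cornilescu convention
`Q = rms(D_calc − D_exp)/rms(D_exp)`.

**Steric tensor.** The shape-based predictor takes the principal frame of the
heavy-atom gyration tensor and scales its traceless anisotropy so the largest
principal component equals a configurable magnitude (default 10⁻³). It is an
approximate surrogate capturing orientation and rhombicity of shape-induced
alignment, not absolute strength, and models no charge effects.

**Replica-averaged restraint.** `E_RDC = α Σᵢ wᵢ (D̄_calc,i − D_exp,i)²` with
`D̄_calc` the average over M replicas; one tensor per alignment medium (and
per replica in the per-replica modes). Tensors are held fixed within an
energy evaluation and refit at a configurable stride (default every 100
accepted moves), so the analytic coordinate gradients ignore tensor
derivatives — the standard fitted-tensor restraint approximation. The
gradients are verified against central finite differences to better than
1 part in 10⁵.

## Restrained simulated-annealing refinement

The production protocol is mirrored structurally: equilibration stages that
ramp α linearly to its target (default 10 stages), then annealing cycles
whose temperature runs T_low → T_high → T_low as a triangular profile
(defaults 310 K → 500 K, 50 cycles, the first 20 discarded as burn-in), with
conformations extracted from the final eighth of each post-burn-in cycle,
where the system sits at the low temperature. The extracted ensemble size is
`(n_cycles − burn_in) × M × frames_per_window` — 480 conformations at the
default 50/20/M = 16/1-frame settings.

Sampling is Metropolis Monte Carlo instead of molecular dynamics: Gaussian
all-atom jitter and torsion-pivot moves over a toy force field (harmonic
bonds and angles, cosine torsions, soft excluded volume, optional position
restraints; analytic gradients verified against finite differences). There
is no physical timestep, so the production protocol's 8 ns/cycle maps to a
configurable `steps_per_cycle` (default 10,000). Thermostats, barostats and
Ewald electrostatics belong to the force-field level that the toy potential
replaces and are deliberately absent. With the restraint off and a harmonic
tether at fixed temperature, the sampled coordinate variance reproduces the
analytic Boltzmann variance k_BT/2k within 5% — the detailed-balance check.

**Shipped toy systems.**
* *Harmonic dimer* — two tethered atoms; the Boltzmann-variance benchmark.
* *Hinged chain* — 12 residues × (N, H, CA, C) with stiff bonds/angles and
  geometry-restraining torsions everywhere except one free hinge torsion;
  residues 1–2 are position-restrained to pin the molecular frame, and amide
  H directions advance around the chain so the N–H vectors are
  well-conditioned for tensor fitting. Its single soft degree of freedom
  makes a clean two-state system.
* *β-hairpin* — an idealized antiparallel two-strand geometry for
  shape/geometry tests.

**The replica-necessity experiment.** The canonical target averages the
couplings of the closed chain and its 120°-rotated open state 50:50 under
one fixed generic tensor, noiseless. No rigid single structure reproduces
this average (the best rigid-hinge Q over a full sweep exceeds 0.2, which the
tests assert), while the generating two-state ensemble fits it essentially
exactly. The study conditions — α = 40 kJ mol⁻¹ Hz⁻², 8 annealing cycles of
1,000 MC steps with 3 burn-in cycles, 5-stage ramp, tensor refits every 25
accepted moves, shared-SVD tensor mode — were chosen once as the smallest
protocol whose restrained sampling converges on this system, and are the
conditions at which the acceptance experiment runs its three arms
(M = 8 restrained, M = 1 restrained, M = 8 unrestrained) over five seeds.

## Hydrogen exchange

The two-state opening model gives `k_obs = k_op·k_int/(k_cl + k_int)`; the
EX2 limit `k_obs = k_op·k_int/k_cl` deviates by exactly k_int/k_cl in
relative terms, i.e. ≤1% whenever k_cl/k_int ≥ 100 (equality at the
boundary). Protection factors are `logP = log₁₀(k_int/k_obs)`, invariant
under a common change of time units; negative values (k_obs > k_int) are
flagged as nonphysical under EX2 but reported. EX1/EX2 discrimination is
modelled only through these rate expressions; mass-spectrometric verification
workflows are out of scope.

**CLEANEX initial slopes.** Fast exchangers are quantified from the weighted
through-origin slope of I/I₀ against mixing time on the canonical
0/10/15/20/25 ms grid. On a saturating buildup `1 − e^(−kτ)` this estimator
is biased low by a fixed, grid-determined amount — 18% at k = 20 s⁻¹
(closed form `Σt(1 − e^(−kt))/Σt²`) — which the tests freeze exactly; mixing
times beyond 50 ms trigger an out-of-regime warning.

**Intrinsic rates.** Random-coil rates use the poly-DL-alanine reference
formalism: acid-, base- and water-catalysed terms with log₁₀-additive
nearest-neighbour side-chain corrections (the amide's own residue and its
predecessor), N-/C-terminal corrections, the D₂O autoionisation constant
pK_D = 15.05, and per-term Arrhenius activation energies (14/17/19 kcal/mol)
from the 293 K reference. Side-chain entries use the ionisation forms
appropriate near neutral pD; pD is taken as the direct reading with no
glass-electrode correction (configurable convention). The first residue has
no amide proton and prolines are skipped. Dead-time handling: synthetic
amides whose k_obs would complete exchange before the first spectrum are
routed to the CLEANEX path rather than emitted as unusable decays.

## Free-energy surfaces and RMSF

Surfaces are Boltzmann inversions `G(bin) = −k_BT ln(n_bin/n_max)` of 2-D
histograms over a global coordinate (mass-weighted radius of gyration) and a
local one (side-chain heavy-atom centroid distance by default; minimum-
distance, Cα and named-atom modes available). Defaults: 40 × 40 bins, data
extents padded by 5%, k_B = 0.0083145 kJ mol⁻¹ K⁻¹. Empty bins carry an
infinite sentinel and are never interpolated; Gaussian smoothing (σ = 1 bin)
exists only inside basin detection and is off by default, so barrier heights
are never fabricated. G is exactly linear in T, and re-exponentiating G
recovers the bin populations exactly — both asserted as identities. With
n = 10⁵ samples the basin ΔG of a 70:30 two-Gaussian ensemble matches
−k_BT ln(p₂/p₁) within 0.2 kJ/mol; the statistical error decays as n^(−1/2).

RMSF superposes all models onto the evolving mean structure (Kabsch on
backbone N/CA/C, iterated to convergence) and reports per-residue Cα
fluctuations. Rigid-body motion is removed entirely — rotated/translated
copies of one structure give zero — and a residue displaced ±d in half the
models has RMSF exactly d without superposition (with superposition the fit
redistributes a small O(1/n_atoms) share, which the tests bound).

## Synthetic data: what it does and does not emulate

Generators draw from the exact statistical model each analysis stage assumes:
Lipari–Szabo-consistent (R₁, R₂, NOE) triples with relative Gaussian noise
(default 3%); ensemble-averaged RDCs from known tensors with additive noise
(default 1 Hz, with a separate noiseless two-conformer refinement target);
exponential HX decays and CLEANEX buildups from EX2 kinetic parameters
(default 5% noise); and a two-state conformational ensemble whose compact
well is the hinged chain bent 70° at its hinge and whose open well is the
extended chain, Gaussian in the (R_g, pair-distance) plane around the two
reference structures' actual coordinates. Coordinate samples are drawn
directly in that plane (cheap at n = 10⁵), while full structures are
materialised for a bounded subset by jittering the bend angle — the surface
closed forms need only the samples, and 10⁵ all-atom models would be
hundreds of megabytes for no extra information.

A single user seed fans out to independent per-generator streams via
`numpy.random.default_rng([seed, kind_id])`, so outputs are reproducible and
adding one kind of data never perturbs another's stream.

What passing the recovery tests shows is that every inversion in the package
is correct and well-conditioned *under its own model assumptions*. Real
spectra add what the generators deliberately omit: peak overlap and
lineshape distortions, anisotropic tumbling, variable per-residue CSA,
dynamic averaging of bond lengths, multi-state exchange beyond two wells,
and systematic (non-Gaussian) errors. Recovery here is necessary, not
sufficient, evidence for accuracy on experimental data.

## Numerical choices and degenerate inputs

Fits use multi-start bounded least squares (S² ∈ [0, 1], τ_e ∈ [0, 5000] ps,
R_ex ∈ [0, 100] s⁻¹) with tight (1e-14) convergence tolerances; records
without declared errors fall back to a 2% relative weight. Flat decay curves
are rejected as unidentifiable (relaxation) or flagged near-zero-rate (HX);
rising HX intensities get a best-effort fit plus flag; HX fits whose time
grid covers less than half of 1/k_obs are flagged poorly-constrained.
Tabular output uses 17 significant digits and round-trip-exact float parsing,
so write→read is bit-identical for finite values; tables are sorted by
residue index and duplicate residues are rejected. Q is undefined for
all-zero reference couplings and raises. Monte-Carlo trajectories are
bit-reproducible for a given seed.

## Known limitations

* Single-field relaxation data: τ_e weakly identified at high S² (see
  above); no reduced spectral-density mapping; isotropic tumbling only.
* The toy force field preserves the refinement protocol's logic, not protein
  energetics; refined ensembles demonstrate the restraint machinery, they do
  not predict real structures.
* The steric alignment predictor omits electrostatics and absolute scale.
* Intrinsic-rate side-chain corrections are the standard reference set as
  transcribed here; applications needing certified values should verify the
  table against the primary source.
* CLEANEX rates inherit the documented initial-slope curvature bias.
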