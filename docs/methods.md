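# Methods

This note documents the models, defaults, numerical choices and known
limitations of `shellopt`, module by module.

## Shell-mean extraction (`shellopt.io`)

The unit of analysis is the per-shell, per-voxel mean DW signal. Under
uniform, sufficiently dense angular sampling this mean is rotationally
invariant and independent of fibre configuration, so it isolates the
b-value dependence of the signal from the angular dependence; the two are
optimised separately throughout the package.

* Shell grouping clusters per-volume b-values with a tolerance of
  50 s/mm² (scanner-reported effective b-values jitter around nominals).
  Clusters are connected components of the "within tolerance" relation; a
  component whose members span more than the tolerance (chained overlap),
  or two cluster centres closer than twice the tolerance, abort with an
  "ambiguous shell structure" error rather than guessing.
* Voxels enter the matrix in row-major scan order of the mask, recorded in
  provenance, so per-voxel weights can be re-embedded into image space.
* b = 0 volumes form an ordinary shell and are averaged like any other.
* No Rician-bias correction is applied to shell means. At shell-mean SNR
  levels typical of pilot data (tens of volumes averaged) the magnitude
  bias is small relative to the effect sizes of interest, but it exists;
  the phantom generator's Rician mode exists precisely to exhibit it.
* Multi-subject pooling concatenates voxel columns; all subjects must
  share one shell scheme.

## Signal basis (`shellopt.basis`)

The compact SVD is used deliberately *without* positivity or smoothness
constraints: the basis should reflect the measured signal, not a tissue
model. Effect sizes `ε_c = S_c/√N_v` equal the RMS weight of component `c`
across voxels (asserted at runtime).

* SVD sign ambiguity is resolved by flipping each basis column so its
  largest-magnitude entry is positive; the paired weight row flips with
  it. This makes output deterministic across BLAS implementations except
  for exactly degenerate singular values, where the underlying solver's
  ordering is preserved (documented nondeterminism; never observed on
  noisy data).
* An optional b=0 normalisation flag exists but defaults to off — the
  basis is taken over raw means.

## Noise propagation (`shellopt.sensitivity`)

Noise is modelled as i.i.d. Gaussian with one σ per measurement,
independent of b-value: echo time is constant across shells in a
constant-TE multi-shell acquisition, so thermal noise is too. T2-driven
SNR differences between candidate protocols enter through the *effect
sizes* (see timing), never through σ. σ may be specified directly or
derived as `S(b=0)/SNR_b0`.

The number of retained components defaults to all `N_s` components of the
compact SVD; truncation is available where trailing components are known
to be noise. A component with ε = 0 has infinite CV and is flagged rather
than silently dropped — the caller must truncate explicitly.

CNR tables are quoted at the `N_total = 100`, SNR 30 convention and
rescaled exactly by `CNR × (SNR ratio) × √(N_total/100)`.

## Volume allocation (`shellopt.allocation`)

SSCV separates over shells, `SSCV = σ² Σ_s q_s/n_s` with
`q_s = Σ_c (H_sc/ε_c)²`, so the Lagrange stationarity condition gives
`n_s ∝ √q_s` in closed form; the multiplier itself is never computed —
normalising to the budget is equivalent.

Integerisation uses largest-remainder rounding (ties to the lower shell
index), then repairs any shell below its minimum (1 by default; the
angular module's minimum direction counts can be injected as hard minima)
by taking volumes from the donors with the smallest SSCV penalty, and
finally applies a deterministic pairwise-exchange polish: single volumes
move between shells while that strictly lowers SSCV. The polish was added
because plain largest-remainder rounding is not guaranteed near-optimal
for strongly skewed spectra at small budgets; with it, the result cannot
be improved by any one-volume move, and on random instances it matches
exhaustive enumeration within 1% SSCV (usually exactly). The exhaustive
enumerator itself is part of the public API as a validation oracle,
guarded to 10⁶ compositions.

## Sequence timing (`shellopt.timing`)

The PGSE model keeps four lumped constants: 5 ms from excitation to the
first gradient, a 5 ms refocusing window (pulse + crushers), 15 ms from
the second gradient to the echo, and 80 mT/m gradient strength; square
gradients of duration δ are packed tightly around the refocusing window so
`Δ = δ + t_refocus` and `TE = t_pre + 2δ + t_refocus + t_post` (25 ms at
b = 0). δ is recovered from a target b by monotone bracketing root-finding
(`brentq`, 1e-6 ms). γ is the standard proton value 2.6752219 × 10⁸
rad s⁻¹ T⁻¹. T2 presets of 100/150/200 ms (typical neonatal brain at 3 T)
and ∞ (ignore relaxation) are exposed.

Limitations, stated plainly: spin-echo symmetry (excitation→180° centre =
TE/2) is *not* enforced by this minimal assembly; slew rates, slice
selection and EPI readout are outside the model. Reported TEs are
model-dependent lower bounds, and are labelled as such in reports; the
attenuation *ordering* across candidate b_max values, which is what the
optimisation consumes, is robust to these simplifications.

## b-value search (`shellopt.search`)

Per-voxel PCHIP interpolation over the measured b-values predicts shell
means for arbitrary candidates (interpolation only — no extrapolation).
PCHIP preserves monotone decay between sample points; its accuracy on
mono-exponential decay over the 0–4000 s/mm² grid is better than 0.5% of
the b = 0 signal at every shell midpoint, degrading in *relative* terms
only where the signal itself has decayed to a few percent.

The search runs Nelder–Mead over the log-b coordinates of the nonzero
shells (b = 0 is always fixed), with 8 stratified, seeded multi-starts
(the first unjittered), convergence at a simplex diameter of roughly
1 s/mm² (log-b tolerance 1e-4) or 500 iterations, and a final
tight-tolerance polish from the winning start. Candidates below
50 s/mm² — which would collide with the fixed b = 0 shell — above the
measured maximum, or with shells closer than 1 s/mm² receive a large
*finite* penalty growing with the violation, so the simplex can recover
from degenerate corners instead of raising. Each cost evaluation
re-interpolates, re-decomposes, attenuates ε by the candidate's implied
TE, and evaluates SSCV at the closed-form continuous allocation; results
are cached keyed by b-values rounded to 0.1 s/mm². Reports are
byte-identical JSON for a fixed seed.

Minimum-direction constraints are applied *after* the b-value search, as
an integerisation repair — a verification/repair step rather than a
search constraint, matching the intended protocol-design workflow.

## Angular analysis (`shellopt.angular`)

The real, even-order SH basis is built from the complex harmonics with
Condon–Shortley phase, ordered `l = 0, 2, …` with `m = −l…l` within each
order, orthonormal over the sphere (a constant `a` fits to
`c₀₀ = a√4π`). Per-order power `Σ_m c_lm²` is rotation invariant.

Detectability of order `l` is decided against a simulated noise floor:
pure-Gaussian shells at the dataset's σ, direction set and voxel count are
fitted repeatedly (500 trials by default, seeded) and the 95th percentile
of each order's power is the floor. A relative numerical guard
(10⁻¹⁰ × the l = 0 power) prevents float-epsilon residuals from counting
as detectable on noiseless inputs, where the simulated floor is zero. The
95% level and the guard are both package choices; detectability output
always records the σ it assumed.

Direction sets minimise the antipodal electrostatic energy
`Σ 1/‖u_i−u_j‖ + 1/‖u_i+u_j‖` by projected gradient descent with
backtracking (energy never increases), deterministic per (n, seed). The
50-direction set reaches a minimum pairwise angle above 19°.

Single-fibre voxel selection: weighted least-squares log-linear tensor fit
on the b ≤ 1000 s/mm² volumes (weights = squared observed signals), FA
threshold 0.25 (chosen for low-anisotropy neonatal-like tissue; exposed),
then a peak test on the top shell — the ADC profile is fitted with
lightly Laplace–Beltrami-regularised SH (λ = 5e-3) and local maxima are
extracted on a dense sphere grid with antipodal deduplication; voxels
whose second peak exceeds half the first are rejected (a single prolate
tensor has one ADC maximum axis; crossings have several). Surviving
profiles are rotated so the principal eigenvector maps to +z before
averaging. At realistic noise levels this test is conservative: it rejects
some genuinely single-fibre voxels rather than admitting crossings.

## Synthetic phantoms (`shellopt.phantom`)

Phantoms mix isotropic (`exp(−bD)`) and axially symmetric tensor
compartments; anisotropic shell means use the exact orientation average
`exp(−b·RD)·(√π/2)·erf(√α)/√α` with `α = b(AD−RD)`. Volume-fraction maps
are either explicit (for labelled tests) or smoothed random fields passed
through a softmax (smoothness 2 voxels, sharpness 6), giving smooth
anatomy-like regions. Noise is added to each of the `n_s` simulated
measurements *before* averaging, so the shell-mean variance σ²/n_s that
the sensitivity analysis assumes holds by construction — this closes the
loop on the core noise model. The Rician option (magnitude of a complex
Gaussian) exists to demonstrate magnitude bias and is never used where
the Gaussian analytics are being validated.

The `neonatal_like_preset` uses four isotropic compartments spanning MD
1.0–1.8 × 10⁻³ mm²/s (neonatal tissue diffuses faster and far less
anisotropically than adult, which is also why an isotropic-compartment
phantom is an acceptable stand-in for the b-value pipeline), the dense
pilot grid b = 0/500/1000/2000/3000/4000 s/mm² with 5 + 5×50 volumes, and
Gaussian noise at b=0 SNR 30. `fibre_phantom_preset` adds a coherent
single-fibre population at neonatal anisotropy (AD 1.9, RD 0.7 × 10⁻³
mm²/s) for the angular pipeline. What these phantoms do *not* emulate:
motion, eddy currents, distortion, spatially varying noise, kurtosis-type
non-Gaussian diffusion, or realistic orientation dispersion — passing
tests demonstrate the correctness of the optimisation machinery on the
assumed signal class, not robustness to acquisition artefacts.

## Problem sizes

Defaults are chosen so the full test suite and the acceptance script run
comfortably on a single CPU: phantom grids of ~10²–10³ voxels, 20 000-draw
Monte-Carlo checks, exhaustive allocation at a 30-volume budget, and a
1 s/mm² grid oracle for the single-shell search. The machinery itself is
vectorised and runs on pooled multi-subject matrices of ~10⁵ voxels
without modification.

## Known limitations

* The TE(b_max) mapping depends on the minimal PGSE assembly above;
  absolute TEs (and so absolute attenuations) are model-dependent.
* The b-value optimisation ignores angular information beyond the
  minimum-sampling safeguard; for strongly anisotropic (adult) data a
  joint q-space treatment would be needed.
* Whether a brain mask should exclude CSF-only voxels is left to the
  user; the basis and effect sizes are mask-dependent.
* Exactly degenerate singular-value spectra leave component order (not
  the subspace) solver-dependent.
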