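# Methods

This note documents the models, conventions and numerical choices behind
`ispgr`, and what the synthetic experiments do and do not demonstrate.

## Signal model

One I-SPGR shot is: T1 relaxation over the fat-suppression-plus-gap duration
T_FS (the SPIR pulse only excites off-resonance fat, so on-resonance spins
see pure T1 recovery), multiplication of the longitudinal magnetization by
E_BS = exp(−T_BS/T2) for the iMSDE blood-suppression block (the
magnetization spends T_BS in the transverse plane, book-kept as an
attenuation of Mz since the block returns it longitudinal), T1 relaxation
over the spoiling interval T_Sp, then k excitations at flip angle α and
repetition TR with perfect spoiling between pulses.  Within the readout the
longitudinal magnetization follows the linear recursion
M_{n+1} = M_n E1 cos α + M0 (1 − E1); imposing shot periodicity on the
composed prep-plus-readout map yields the closed-form semi-steady-state
start-of-shot magnetization and hence the signal S_n after every pulse
(see the README for the expression).  Assumptions inherited from this
derivation:

* perfect spoiling — no transverse coherence pathways in the closed form;
* instantaneous RF pulses, no slice profile, no off-resonance for water;
* fat is not modeled at all (SPIR assumed perfect);
* flowing spins are not modeled — the iMSDE acts on static tissue only as
  T2 decay.

All times are in milliseconds internally; flip angles are degrees at
interfaces and radians internally.  Geometric-sum denominators of the form
1 − E1 cos α are floored at 1e−12; the floor only activates in the
degenerate corner α → 0, TR/T1 → 0, where the numerator vanishes at the
same rate, so the evaluation returns the analytic limit instead of 0/0
during optimizer exploration.

Downstream code evaluates the model at readout index n = 1: the
phase-encode ordering is center-out, so the first readout of each shot
determines image contrast.  `n` is exposed everywhere for other orderings.

## Bloch simulator (the oracle)

The simulator is event-driven: rotations are applied instantaneously and
relaxation between events in exact exponential form, so there is no
time-step discretization error and agreement with the closed form is
limited only by round-off.  In perfect-spoiling mode the simulated final
shot matches the analytic signal at every readout index to ~1e−13 relative
after 30 shots; the test suite asserts 1e−6.

Burn-in convention: comparisons against the closed form run 30 shots and
use the final shot.  (The shot-to-shot deviation contracts by the factor
E_Sp E_BS E_FS (E1 cos α)^k ≈ 0.23–0.35 for the validation tissues, so 30
shots leave a residual below 1e−10; comparing "one shot after reaching a
1e−3 criterion" would still carry ~3e−4 of transient.)

Convergence to the semi-steady state is quantified by
`time_to_steady_state`: the time of the first sample of the maximal suffix
whose per-readout relative deviation from a reference shot stays below
`rel_tol`.  At `rel_tol = 1e−3` the four validation tissues (T1 500/1500 ×
T2 25/50 ms, TR 5 ms, α 15°, k 20, T_FS 50, T_BS 12, T_Sp 6 ms) converge in
0.94–1.51 s of sequence time; at a ~2% tolerance — the level at which
plotted curves visually overlap — all four converge within 1 s.  Both
numbers follow from the contraction factor above; the package reports the
strict-tolerance value.

The RF/gradient-spoiling mode propagates an ensemble of isochromats
(default 500; deviations change by far less than one percentage point on
doubling) with full 3D rotations, quadratic RF phase cycling
(φ_p − φ_{p−1} = p·Δφ, default increment 117° — a common scanner choice,
kept as configuration), receiver demodulation by the RF phase, and a
uniform intra-voxel spoiler phase spread of one cycle per TR.  During the
preparation the residual transverse magnetization decays through the gap
and is then crushed by the iMSDE block's own gradients; this dissipation of
spoiling history is why the prepared sequence shows weaker dependence on
the RF phase increment than plain SPGR in the deviation sweeps, and why
deviations grow with flip angle (5° vs 15°).  Motion sensitivity of iMSDE
and B0 effects are not simulated.

## Phase-encode ordering

Arms are the curve r = −x² + 2x, φ = 2πx + i·137° sampled at 30 uniform x
values, scaled anisotropically so r = 1 touches both extents of the
178 × 30 (ky, kz) grid, rounded to the nearest index (0-based, DC at
⌊n/2⌋) and clipped.  Uniform-in-x sampling is the simplest reading of "30
sampled points" on a curve given parametrically in x; the scanner's actual
polar-to-Cartesian mapping and rounding are not public.  Two consequences
worth knowing: arms start exactly at DC (r(0) = 0, supporting the
contrast-from-first-readout argument), and samples cluster on the r ≈ 1 rim
because dr/dx → 0 at the edge, so the thin ring just inside the unit circle
is itself relatively well covered.  "Peripheral undersampling" therefore
means (a) the grid periphery as a whole — corners included, which the
unit-radius spiral never reaches — has lower unique coverage than the
central disc, and (b) visit density is strongly center-dominated (the DC
neighborhood is re-acquired every shot).  Duplicate indices within an arm
are kept as repeated acquisitions: the sequence plays all k readouts
regardless.

## Digital phantom and noise

The standard preset places eight non-overlapping vials on a ring, with T1
log-spaced over 236–2013 ms and T2 log-spaced over 15–328 ms, paired in
increasing order (a decreasing MnCl2 concentration series raises both).
Only the range endpoints are published for the physical phantom the preset
emulates; the intermediate values are synthetic by construction.  Default
geometry is a reduced 48 × 48 × 3 matrix at 0.98 × 0.98 × 4 mm³ voxels so
forward-simulate-then-fit loops run in seconds; tests use single-slice
40 × 40 variants.

Noise convention: SNR = (mean noiseless reference-measurement signal over
nonzero-M0 voxels) / (SD of the added noise), with the reference
measurement defaulting to the near-Ernst acquisition (α 10°, shortest
T_BS).  Default noise is additive Gaussian on the magnitude; a Rician
option exists.  The simulator works in image space: undersampling
artifacts, streaking, respiratory motion and fat are deliberately absent.
Passing tests therefore demonstrate correctness of the signal model,
fitting and statistics chain — not robustness to reconstruction artifacts
or motion in real scans.

## Fitting

Per voxel, bounded nonlinear least squares (scipy `least_squares`, trust
region reflective) under a Gaussian residual assumption (magnitude data,
no Rician correction — signals sit well above the noise floor in the
intended regime).  The joint (T1, T2) surface has local minima at short T2,
so the fit is a deterministic multi-start: a log-spaced 12 × 10 (T1, T2)
grid on which M0 is profiled analytically (the model is linear in M0), the
best three nodes refined locally, lowest cost kept.  On a noiseless
16-point grid spanning T1 300–2500 × T2 25–250 ms the in-vivo preset is
recovered to ≪ 0.5%; no random state is involved, so volume fits are
bit-reproducible.

Default bounds are T1 ∈ [100, 3000] ms and T2 ∈ [20, 300] ms.  M0's upper
bound defaults to 10× the largest profiled M0 from the start grid; a rule
tied to the raw signal level (a small multiple of the maximum observed
signal) fails here because prepared-shot signals are only ~2–8% of M0.
Estimates on a bound are flagged `converged-at-bound` (flag 1) and kept in
summaries; optimizer failures and all-zero inputs are flagged 2 and
excluded.  Note the standard phantom's extreme vials (T2 15 and 328 ms)
lie outside the default T2 box — closure experiments on the full phantom
must pass enclosing bounds (e.g. T1 [50, 4000], T2 [5, 500]), as the README
example does.

B1+ correction is the linear AFI-map convention α_actual = ratio ×
α_nominal, applied after 3D Gaussian smoothing of the ratio map (default
σ = 1 voxel; σ = 0 disables).  Both fitting paths from the literature are
provided: per-voxel fits averaged per region (`fit_volume` + `bias_table`)
and one fit of each region's mean signal (`fit_regions`).

## Evaluation statistics

* Bias tables: error = fitted − reference per region, per model
  ("ispgr" vs the deliberately misspecified "spgr" Ernst fit), with a
  grand-mean row.  On noiseless phantom data the Ernst misfit biases T1
  negative on every vial (mean ≈ −0.8 s) while the prepared model's bias
  is numerically zero — the qualitative signature the model exists for.
* Monte-Carlo sensitivity maps: per (T1, T2) cell, the median absolute
  relative error of each parameter over seeded noisy repetitions (median
  rather than mean to be robust to bound pile-up; mean is available).
  The noise SD is shared across the map — mean reference signal over the
  grid divided by SNR, consistent with the stack-level SNR convention —
  so weak-signal cells (long T1, short T2) see proportionally more noise;
  a per-cell mode exists.  Precision degrades sharply at short T2, where
  the blood-suppression attenuation destroys signal: at SNR 30 with the
  in-vivo preset the worst T2 < 40 ms cell reaches ~50% median T1 error
  (seed-dependent by a few points).  Repetitions whose optimizer stops on
  the feasible boundary count as boundary-value estimates; dropping them
  would flatter the precision.
* Repeatability: Bland–Altman mean difference and ±1.96 SD limits, plus
  wCV = sqrt(mean(d²)/2) / grand mean from paired replicates.
* ROI summaries: median and IQR per parameter over converged voxels,
  linear-interpolation quantile rule (conventions matter for IQRs).
* Correlation gate: Shapiro–Wilk on *both* variables; Pearson only if both
  pass at p ≥ 0.05, Spearman otherwise ("both-must-pass" is the adopted
  reading of distribution-dependent test selection).

## Known limitations

* No image reconstruction, registration, motion correction or
  segmentation; the B1+ ratio map is an input, never computed from raw
  dual-TR data.
* The ensemble spoiling mode does not model the iMSDE's internal refocusing
  or flow dephasing, only its net T2 attenuation and crushing.
* Magnitude noise is handled by ordinary least squares; at very low SNR a
  Rician likelihood would be preferable.
* Reported in-vivo cohort values (patient medians, correlations with
  aneurysm diameter) require clinical data and are outside what the
  synthetic experiments can or should reproduce.
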