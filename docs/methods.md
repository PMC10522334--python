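# Methods

## The gain-control model

The core of the package is a single-stage binocular contrast gain-control
model. Writing L and R for the two eyes' temporal Michelson contrasts (in
%, 0–100), the channel responses are

    Resp_L = L² / (Z + L + w·R)
    Resp_R = R² / (Z + R + w·L)

and the binocular response is their sum, scaled and offset:

    Resp_B = Rmax · (Resp_L + Resp_R) + n.

Assumptions baked into this form: suppression acts *before* binocular
summation (which is what makes intermodulation terms possible); the
numerator exponent is fixed at 2 (a free exponent trades off against w and
makes the two unidentifiable together); there is no second gain-control
stage after summation. Parameters, units and defaults:

| parameter | meaning | units | constraint |
| --- | --- | --- | --- |
| Z | saturation constant; shifts the contrast-response function laterally | % contrast | > 0 |
| w | interocular suppression weight | — | ≥ 0; 0 = independent eyes, 1 = full normalisation |
| n | noise parameter: additive response floor, and the likelihood scale / decision-noise SD | response units | ≥ 0 |
| Rmax | output scaling | response units per model unit | > 0; omitted in matching mode |

In matching mode (`Rmax=None`) the additive `n` term cancels in every
response difference, so `n` is reinterpreted as the SD of the probit
decision rule; `binocular_response` then returns the bare channel sum.

### Waveform mode

For time-varying inputs the equations are applied at each sample. Signed
sinusoidal contrast must first be mapped into the non-negative domain of
the equations; the package half-wave rectifies each eye's signal into an
on-channel (negative lobes → 0). Pure squaring of a signed sinusoid would
generate only even harmonics, which contradicts the strong first-harmonic
responses this class of experiment measures; rectification followed by
the divisive nonlinearity yields both odd and even harmonics and, when
w > 0, intermodulation components at f1 ± f2. Whether an off-channel
(rectifying the negative lobe) also exists is left open; only the
on-channel is implemented. Constant (DC) inputs reproduce scalar mode
exactly, which is the regression anchor for the pointwise implementation.

`n` is added after `Rmax` scaling, as the summation equation is written.

### Per-frequency scalar predictions

Fitting uses scalar contrasts for tractability. For conditions where the
two eyes carry different frequencies, the response at each frequency is
the sum of the channels driven at that frequency, with each channel
suppressed by the *total* contrast in the other eye, plus the noise floor
(`predicted_amplitudes`). This is the scalar shadow of the waveform model:
suppression is frequency-unselective in the denominator, drive is
frequency-specific in the numerator.

### Matching contours

A target with interocular ratio r matches the binocular standard S when
Resp_B(c, r·c) = Resp_B(S, S). The response is strictly increasing in c,
so the match is found by bracketed root finding (Brent, relative
tolerance 1e-9, search ceiling 10× the contrast ceiling; an impossible
match raises). Canonical references: linear summation (cL + cR = 2S) and
winner-take-all (max(cL, cR) = S).

## Steady-state spectral analysis

Trials are epoched to a 10-s steady-state window after skipping the first
2 s (onset transient), giving 0.1 Hz spectral resolution so that 2, 1.6,
0.4 and 3.6 Hz all sit exactly on bins. Spectra are one-sided, scaled 2/N
(DC and Nyquist 1/N) so a sinusoid of amplitude A reads A at its bin; with
this convention the summed |bin|²/2 over non-DC bins equals the
time-domain variance, which is asserted as a Parseval check.

Averaging is always coherent (complex). At each averaging stage — trials
to participant, participants to group — one Mahalanobis pass excludes
points with D > 3 from the complex mean under the sample covariance of
the (real, imaginary) plane. The pass is never iterated; groups smaller
than 5 are passed through (covariance too unstable), and a singular
covariance falls back to pooled isotropic variance. Pupil trials are
pooled across the two eyes before averaging (the consensual response
makes both eyes' records measurements of the same signal); EEG trials are
averaged per electrode and then across the four occipital electrodes
(POz, Oz, O1, O2).

The zero-mean test for M complex values is

    T²circ = M(M−1)|mean|² / Σ|xᵢ − mean|²  ~  F(2, 2M−2) under H0,

valid under isotropic complex Gaussian noise. The factorial extension
(`anova2circ`) treats the real/imaginary pair as a bivariate response
with equal variance: effect sums of squares are computed on complex cell
means and tested against pooled within-cell variability, with numerator
and denominator degrees of freedom doubled relative to the univariate
ANOVA. Participants enter as within-cell replicates, so the error df is
2·(n_obs − n_cells) — e.g. (8, 580) for the contrast effect of a
2 × 5 × N=30 design. Both statistics are validated by Monte Carlo
calibration (type-I error 5% ± 1.5% under the null) rather than against
printed formulas.

Summation ratios are reported as 20·log10(binocular/monocular), computed
per participant before averaging; non-positive amplitudes drop that
participant's cell. Standard errors across participants come from a
1000-iteration bootstrap, resampling participants with replacement at the
top level only.

The 5 Hz zero-phase Butterworth low-pass (4th order) exists solely for
waveform display; the analysis path never touches it (a test feeds a
20 Hz component through the pipeline and asserts it survives).

## Contrast matching

Target levels move on a 1-up/1-down staircase in dB of contrast
(level = 20·log10(c%)). The step size is 3 dB, halved to 1.5 dB after two
reversals — placement only affects efficiency because the PSE is
re-estimated by maximum likelihood over all pooled trials, not from
reversals. The simulated observer chooses the target with probability
Φ((Resp_target − Resp_standard)/n) using matching-mode responses; any
interval-comparison √2 factor is absorbed into n. Lapse rate is fixed at
0. Psychometric functions are cumulative normals fitted by ML
(Nelder–Mead on (PSE, log slope), multi-start); one-sided or perfectly
separated response sets are flagged degenerate, and fits with responses
*decreasing* in level are rejected as miscoded. PSEs may extrapolate
beyond the 100% contrast ceiling. Contours are assembled per ratio and
side, averaging across participants (and optionally across the two
mirror-symmetric sides) in dB.

## Bayesian estimation

A single group-level parameter set is estimated from the pooled
individual data of all participants — a flat structure with a data-level
likelihood, no per-participant parameters. This is the structure under
which the group-noise correction n/√N (applied when fitting coherently
averaged group data) is coherent.

Likelihoods: Student-t (ν = 5, fixed — heavy-tailed robustness without an
extra free parameter) centred on the predicted amplitude with scale n for
steady-state amplitudes; Bernoulli with probit link for single-trial
matching choices (probabilities clipped to [1e-9, 1−1e-9]). Priors are
zero-truncated Gaussians: mean 1, SD 0.5 for w and Rmax; mean 5, SD 2 for
Z and n. Rmax is omitted for matching data, where it has no effect.

Sampling uses the affine-invariant ensemble sampler (emcee): 32 walkers,
2000 warmup and 4000 retained steps by default, initialised at prior
draws with finite posterior. Walkers are treated as chains for split
R-hat and ESS (arviz); the convergence contract is R-hat < 1.05 and
ESS > 400 for every parameter, and results failing it are returned but
flagged. Point estimates are posterior medians with central 95% intervals.

Checks implemented as tests: likelihoods agree with independent
brute-force density evaluations to 1e-9; a posterior fitted to
uninformative data reproduces the prior (KS < 0.1 on w); posterior error
in w shrinks monotonically as generating noise falls; and
simulation-based calibration of w (150 replicates at reduced draws,
χ² uniformity of rank statistics at α = 0.01) passes. Z is only weakly
identified when all tested contrasts are well above Z, so its posterior
can be broad while w, n and Rmax are sharp; this mirrors the lateral-shift
role of Z in the equations.

## Synthetic data

The generators emulate the study design: 6 ocular configurations
(monocular, binocular, dichoptic, and their cross-frequency variants)
× 5 contrasts (6, 12, 24, 48, 96%), mask fixed at 48%, target 2 Hz, mask
1.6 Hz, N = 30 participants, 6 repetitions per condition; matching
sessions of 54 blocks (3 repetitions × 2 standards × 9 ratio/side
conditions) × 50 trials. Default parameter sets per modality are the
group-median values (`REFERENCE_PARAMS`).

Noise structure, chosen to match the analysis assumptions:

* isotropic complex Gaussian trial noise (per-axis SD 0.01 mm pupil,
  0.3 µV EEG — tuning constants at realistic single-trial SNR; the true
  magnitudes are only recoverable from recorded data);
* a log-normal participant amplitude scale (log10 SD 0.2), producing
  bootstrap SEs of plausible relative size;
* a participant-level response phase, common to all of a participant's
  trials and stimulus-locked across participants (Gaussian jitter,
  SD 0.3 rad) — without cross-participant phase consistency, group-level
  coherent averaging would destroy the signal, contrary to what
  steady-state recordings show;
* raw pupil trials add a 5 mm baseline, an exponential onset constriction
  (1 s time constant) that reaches its plateau within the 2 s the epoch
  skips — exercising the epoching rule without leaking into the analysis
  window — and 1% dropped frames (NaN) for the gap-interpolation path.
  Interpolation is performed on diameter in mm.

What the generators deliberately do not emulate: 1/f EEG background
spectra, ocular artifacts, blinks beyond missing-sample gaps, interval-
order effects in matching, and any pupil-to-cortex interaction. Passing
tests therefore demonstrate correctness of the *computations* under the
assumed noise model, not robustness to every artifact of real recordings.

All generators are pure functions of (config, seed); the CLI derives
per-stage seeds from the top-level seed with a fixed counter scheme so
each stage reproduces independently.

## Problem sizes

Test and example runs use desk-scale sizes chosen to keep the full suite
fast while preserving the study geometry: calibration uses 10⁴ (T²circ)
and 2×10³ (ANOVA²circ) replicates; posterior recovery fits use the full
N=30 × 30-condition design with 32 walkers × 6000 total steps;
simulation-based calibration uses 150 replicates at reduced draws;
matching recovery uses 3 repetitions of each 50-trial block.

## Known limitations

* The one-factor ANOVA²circ error term treats participants as replicates
  (no subject effect is removed); repeated-measures designs with strong
  participant offsets will be conservative or anticonservative depending
  on the offset structure.
* The flat hierarchy cannot separate participant-level parameter
  variability from trial noise; multiplicative participant scatter is
  absorbed by the heavy-tailed likelihood and inflates n.
* The rectification convention (on-channel only) is one of several
  physiologically defensible choices; off-channel variants would alter
  harmonic amplitude ratios but not the presence/absence structure of
  intermodulation terms.
* Matching-mode fits jointly across both standards assume a single
  parameter set governs both; standard-specific parameters are not
  supported.
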