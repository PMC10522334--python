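# binoflick

How does the brain combine luminance signals from the two eyes? For
spatial patterns the answer is well known — interocular suppression
normalises the two inputs so that a grating looks the same through one eye
or two ("ocularity invariance"). For spatially uniform *flicker* the
answer turns out to be different: cortical responses and perception show
near-linear binocular facilitation, while the subcortical pathway that
drives the pupil shows much stronger interocular suppression.

`binoflick` is a Python library for studying this question computationally.
It provides:

* a **binocular contrast gain-control model** for scalar contrasts and
  time-varying waveforms,
* the **steady-state Fourier analysis** used for flicker-entrained
  pupillometry and EEG (epoching, coherent averaging, Mahalanobis outlier
  exclusion, T²circ and ANOVA²circ complex-domain statistics, bootstrap
  errors),
* **dichoptic contrast-matching machinery** (1-up/1-down dB staircases, a
  stochastic observer, cumulative-normal psychometric fits, PSE contours),
* **hierarchical Bayesian estimation** of the model parameters by MCMC,
* **synthetic-data generators** so the entire pipeline runs end to end
  with no recorded data.

## The model

Each eye's channel responds to its own temporal (Michelson) contrast,
divisively normalised by the other eye's contrast:

```
Resp_L = L² / (Z + L + w·R)
Resp_R = R² / (Z + R + w·L)
Resp_B = Rmax · (Resp_L + Resp_R) + n
```

`Z` is a saturation constant, `n` a noise parameter, `Rmax` an output
scaling, and `w` — the parameter of scientific interest — is the weight of
interocular suppression. `w ≈ 1` abolishes the binocular advantage at high
contrast (ocularity invariance); `w ≈ 0` produces near-linear binocular
facilitation. The numerator exponent is fixed at 2 because it trades off
with `w` when left free.

Applied sample-by-sample to half-wave-rectified contrast waveforms, the
same equations predict the full response spectrum: harmonics of each
input frequency and — whenever `w > 0` — intermodulation components at the
sums and differences of the two eyes' frequencies.

## Worked example

```python
>>> from binoflick import binocular_ratio
>>> from binoflick.synth import REFERENCE_PARAMS
>>> pupil = REFERENCE_PARAMS["pupil"]    # strong suppression, w = 0.61
>>> eeg = REFERENCE_PARAMS["eeg_1f"]     # near-linear, w = 0.02
>>> for c in (6, 24, 96):
...     print(c, round(binocular_ratio(c, pupil), 3), round(binocular_ratio(c, eeg), 3))
6 1.441 1.973
24 1.304 1.965
96 1.259 1.962
```

The printed values are the noise-free binocular:monocular response ratios:
2 would mean perfect linear summation, 1 complete suppression of the
second eye's contribution. The weakly suppressed cortical parameters stay
near 2 across contrast, while the pupil parameters fall toward 1 — the
signature difference between the two pathways.

The `examples/` directory contains one narrative script per capability:

| script | what it shows |
| --- | --- |
| `examples/gain_control_model.py` | scalar responses, summation ratios, harmonic/intermodulation spectra |
| `examples/spectral_pipeline.py` | raw trials → coherent averages, bootstrap SEs, dB ratio tables |
| `examples/contrast_matching.py` | staircase simulation, psychometric fits, PSE contour vs canonical rules |
| `examples/bayesian_fit.py` | MCMC recovery of the suppression weight from synthetic group data |

A thin CLI wraps the same library calls
(`binoflick simulate / analyze / fit / report`, see `binoflick --help`).

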