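"""Raw trials to group statistics: the steady-state analysis pipeline.

Generates a small synthetic pupillometry session, then runs gap
interpolation, epoching, Fourier analysis, eye pooling, coherent
averaging with Mahalanobis exclusion, bootstrap errors, and dB summation
ratios.
"""

from binoflick import GeneratorConfig, default_conditions, generate_raw_trials
from binoflick.pipeline import (
    binocular_ratio_table,
    group_summary,
    participant_amplitudes,
    trial_amplitudes,
)
from binoflick.synth import REFERENCE_PARAMS

cfg = GeneratorConfig(
    params=REFERENCE_PARAMS["pupil"],
    conditions=tuple(default_conditions(contrasts=(24, 48, 96),
                                        configs=("monocular", "binocular"))),
    n_participants=8,
    n_trials=4,
    seed=42,
)
rec = generate_raw_trials(cfg)
print(f"generated {len(rec.trials)} traces "
      f"({cfg.n_participants} participants x 6 conditions x {cfg.n_trials} trials x 2 eyes)")

tdf = trial_amplitudes(rec, freqs=[2.0])
pdf = participant_amplitudes(tdf, modality="pupil")
summary = group_summary(pdf, bootstrap_seed=1)
print("\nGroup coherent averages at 2 Hz (amplitude in mm, with bootstrap SE")
print("and the zero-mean test on the complex values):")
cols = ["condition", "amplitude", "se", "stat", "p", "n_participants"]
print(summary[cols].round(4).to_string(index=False))

print("\nBinocular:monocular ratio in dB (6.02 dB would be perfect doubling):")
print(binocular_ratio_table(pdf).round(3).to_string(index=False))
print("With the pupil pathway's strong suppression the ratio falls well")
print("short of 6 dB at high contrast.")
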