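"""Posterior estimation of the interocular suppression weight.

Generates a synthetic group dataset at the strong-suppression (pupil
pathway) parameter set, fits the hierarchical model by MCMC, and prints
posterior medians, 95% intervals and convergence diagnostics.
"""

import warnings

warnings.filterwarnings("ignore", category=FutureWarning)

from binoflick import FitConfig, GeneratorConfig, default_conditions, sample_posterior
from binoflick.pipeline import amplitude_points, participant_amplitudes
from binoflick.synth import REFERENCE_PARAMS, generate_amplitude_dataset

truth = REFERENCE_PARAMS["pupil"]
conds = tuple(default_conditions())
cfg = GeneratorConfig(params=truth, modality="pupil", conditions=conds,
                      n_participants=30, n_trials=6, seed=11)
print(f"generating data at Z={truth.Z}, w={truth.w}, n={truth.n}, Rmax={truth.Rmax}")

df = generate_amplitude_dataset(cfg)
df["channel"] = "pooled"
pdf = participant_amplitudes(df, modality="pupil")
pts = amplitude_points(pdf, conds)
print(f"{len(pts)} amplitude observations "
      f"({cfg.n_participants} participants, {len(conds)} conditions, both frequencies)")

summary = sample_posterior(pts, config=FitConfig(kind="pupil", seed=18))
print("\nPosterior summary (medians with central 95% intervals):")
print(summary.table().round(4).to_string(index=False))
print(f"\nconverged: {summary.converged} (contract: R-hat < 1.05, ESS > 400)")
print("The 95% interval for w should cover the generating value 0.61 —")
print("the suppression weight is recoverable from amplitude data alone.")
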