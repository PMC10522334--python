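"""Synthetic flicker-experiment data with the statistical structure the
analysis assumes.

Three generator families cover every input the pipeline consumes:

* per-trial complex steady-state amplitudes (participant-level phase and
  log-normal amplitude scale, isotropic complex trial noise),
* raw time-domain trials (pupil at 120 Hz with an onset constriction
  transient and dropped frames; EEG at 1 kHz over occipital electrodes),
* full matching sessions (54 staircase blocks of 50 trials per
  participant) from the stochastic gain-control observer.

All generators are pure functions of (config, seed). Default design is the
factorial 6 ocular conditions x 5 contrasts (6, 12, 24, 48, 96%) with a
48% mask and N=30 participants. Trial-noise magnitudes are tuning
constants chosen to give realistic single-trial SNR per modality; the true
values are only recoverable from recorded human data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .io import OCCIPITAL_ELECTRODES, RecordingSet
from .matching import RATIOS, STANDARDS, simulate_matching_block
from .model import ModelParams, StimulusCondition, predicted_amplitudes

__all__ = [
    "GeneratorConfig",
    "default_conditions",
    "generate_amplitude_dataset",
    "generate_raw_trials",
    "generate_matching_dataset",
    "write_manifest",
    "REFERENCE_PARAMS",
]

#: group-median gain-control parameters per dataset (reference values used
#: as generator defaults so synthetic data resemble each modality)
REFERENCE_PARAMS: Mapping[str, ModelParams] = {
    "pupil": ModelParams(Z=3.44, n=0.01, w=0.61, Rmax=0.00023),
    "eeg_1f": ModelParams(Z=2.62, n=0.15, w=0.02, Rmax=0.00336),
    "eeg_2f": ModelParams(Z=3.71, n=0.07, w=0.02, Rmax=0.0031),
    "matching": ModelParams(Z=0.30, n=5.10, w=0.09, Rmax=None),
}

CONTRASTS = (6.0, 12.0, 24.0, 48.0, 96.0)
MASK_CONTRAST = 48.0
TARGET_FREQ = 2.0
MASK_FREQ = 1.6

#: per-trial complex noise SD by modality (response units: mm, uV)
TRIAL_NOISE_SD = {"pupil": 0.01, "eeg": 0.3}


def default_conditions(
    contrasts: Sequence[float] = CONTRASTS,
    configs: Sequence[str] | None = None,
) -> list[StimulusCondition]:
    """The factorial design: each ocular configuration at each contrast."""
    if configs is None:
        configs = (
            "monocular",
            "binocular",
            "dichoptic",
            "monocular_cross",
            "binocular_cross",
            "dichoptic_cross",
        )
    conds = []
    for cfg in configs:
        for c in contrasts:
            mask = MASK_CONTRAST if cfg.startswith("dichoptic") else 0.0
            freq2 = MASK_FREQ if cfg.endswith("_cross") else None
            conds.append(
                StimulusCondition(
                    ocular_config=cfg,
                    target_contrast=c,
                    mask_contrast=mask,
                    target_freq=TARGET_FREQ,
                    mask_freq=freq2,
                )
            )
    return conds


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise configuration for the generators."""

    params: ModelParams = REFERENCE_PARAMS["pupil"]
    modality: str = "pupil"
    conditions: tuple[StimulusCondition, ...] = tuple(default_conditions())
    n_participants: int = 30
    n_trials: int = 6  # repetitions of each condition per participant
    trial_noise_sd: float | None = None  # per-axis SD of complex trial noise
    participant_scale_sd: float = 0.2  # SD of log10 amplitude scale
    participant_phase_sd: float = 0.3  # rad; jitter about the stimulus-locked phase
    rate: float | None = None
    trial_s: float = 15.0
    stim_s: float = 12.0
    dropped_frame_p: float = 0.01  # pupil only
    seed: int = 0

    def noise_sd(self) -> float:
        if self.trial_noise_sd is not None:
            return self.trial_noise_sd
        return TRIAL_NOISE_SD[self.modality]

    def sampling_rate(self) -> float:
        if self.rate is not None:
            return self.rate
        return 120.0 if self.modality == "pupil" else 1000.0


def _condition_label(cond: StimulusCondition) -> str:
    return f"{cond.ocular_config}_c{cond.target_contrast:g}"


def generate_amplitude_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Per-trial complex amplitudes at each stimulated frequency.

    amplitude(participant, condition, trial, f) =
        scale_p * prediction(condition, f) * exp(i*phi_p) + noise,
    with scale_p log-normal (log10 SD ``participant_scale_sd``), phi_p a
    participant-level phase common to all of that participant's trials
    (stimulus-locked: Gaussian jitter of SD ``participant_phase_sd`` about
    zero, so group-level coherent averaging retains the signal), and
    isotropic complex Gaussian trial noise. Returns a tidy DataFrame with
    columns participant, condition, trial, freq_hz, re, im.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd()
    rows = []
    for p in range(config.n_participants):
        scale = 10.0 ** rng.normal(0.0, config.participant_scale_sd)
        phase = rng.normal(0.0, config.participant_phase_sd)
        rot = np.exp(1j * phase)
        for cond in config.conditions:
            preds = predicted_amplitudes(cond, config.params)
            label = _condition_label(cond)
            for t in range(config.n_trials):
                for f, amp in preds.items():
                    z = scale * amp * rot + (
                        rng.normal(0.0, sd) + 1j * rng.normal(0.0, sd)
                    )
                    rows.append(
                        {
                            "participant": f"P{p:02d}",
                            "condition": label,
                            "trial": t,
                            "freq_hz": f,
                            "re": z.real,
                            "im": z.imag,
                        }
                    )
    return pd.DataFrame(rows)


def generate_raw_trials(config: GeneratorConfig) -> RecordingSet:
    """Raw time-domain trials for the signal-processing pipeline.

    Each trial is ``trial_s`` seconds at the modality's rate: baseline, an
    onset transient (pupil only — an exponential constriction with 1 s time
    constant, confined to the 2 s the epoching skips), model-amplitude
    sinusoids at the condition's frequencies, broadband Gaussian noise and,
    for pupil, randomly dropped frames (NaN). Channels are the two eyes
    (pupil) or the four occipital electrodes (EEG).
    """
    rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate()
    n = int(round(config.trial_s * rate))
    t = np.arange(n) / rate
    stim = t < config.stim_s
    sd = config.noise_sd()
    if config.modality == "pupil":
        channels = ("left_eye", "right_eye")
        baseline = 5.0  # mm resting diameter
    else:
        channels = OCCIPITAL_ELECTRODES
        baseline = 0.0
    rec = RecordingSet(modality=config.modality, rate=rate, onset_index=0)
    for p in range(config.n_participants):
        scale = 10.0 ** rng.normal(0.0, config.participant_scale_sd)
        phase = rng.normal(0.0, config.participant_phase_sd)
        for cond in config.conditions:
            preds = predicted_amplitudes(cond, config.params)
            label = _condition_label(cond)
            for trial in range(config.n_trials):
                osc = np.zeros(n)
                for f, amp in preds.items():
                    osc += scale * amp * np.sin(2 * np.pi * f * t + phase)
                for chan in channels:
                    x = baseline + np.where(stim, osc, 0.0)
                    if config.modality == "pupil":
                        # onset constriction (1 s time constant) settles to its
                        # plateau at the 2 s epoch skip, so the transient is
                        # confined to the portion the analysis discards
                        transient = np.where(t < 2.0, 1 - np.exp(-t / 1.0), 1.0)
                        x = x - 0.5 * np.where(stim, transient, 0.0)
                    x = x + rng.normal(0.0, sd, size=n)
                    if config.modality == "pupil" and config.dropped_frame_p > 0:
                        x[rng.random(n) < config.dropped_frame_p] = np.nan
                    rec.trials[(f"P{p:02d}", label, trial, chan)] = x
    return rec


def generate_matching_dataset(
    config: GeneratorConfig,
    n_repetitions: int = 3,
    n_trials: int = 50,
) -> pd.DataFrame:
    """Full matching sessions from the stochastic gain-control observer.

    Per participant: ``n_repetitions`` x len(STANDARDS) x 9 ratio/side
    conditions (ratios < 1 run once per side, ratio 1 once), each a
    staircase block of ``n_trials`` trials — the default 54 blocks give
    2700 trials per participant. Between-participant variability comes from
    the stochastic decision rule; all participants share the observer model.
    """
    rng = np.random.default_rng(config.seed)
    obs = replace(config.params, Rmax=None)
    conds = [(r, s) for r in RATIOS for s in (("both",) if r == 1.0 else ("left", "right"))]
    rows = []
    for p in range(config.n_participants):
        for rep in range(n_repetitions):
            for standard in STANDARDS:
                for ratio, side in conds:
                    block = simulate_matching_block(
                        obs,
                        ratio=ratio,
                        standard=standard,
                        side=side,
                        n_trials=n_trials,
                        seed=rng,
                    )
                    for i, tr in enumerate(block):
                        rows.append(
                            {
                                "participant": f"P{p:02d}",
                                "block": rep,
                                "ratio": ratio,
                                "side": side,
                                "standard_pct": tr.standard_contrast,
                                "target_cL": tr.target_cL,
                                "target_cR": tr.target_cR,
                                "trial": i,
                                "response": int(tr.response),
                            }
                        )
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, config: GeneratorConfig, extra: dict | None = None) -> None:
    """Record the generating configuration and seed beside a dataset."""
    d = {
        "modality": config.modality,
        "params": {
            "Z": config.params.Z,
            "w": config.params.w,
            "n": config.params.n,
            "Rmax": config.params.Rmax,
        },
        "n_participants": config.n_participants,
        "n_trials": config.n_trials,
        "trial_noise_sd": config.noise_sd(),
        "participant_scale_sd": config.participant_scale_sd,
        "seed": config.seed,
        "n_conditions": len(config.conditions),
    }
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))
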