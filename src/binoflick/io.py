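"""Readers and preprocessors for pupil and EEG trial recordings.

Trials travel as long-format CSV (participant, condition, trial, channel,
sample_index, value) with a JSON sidecar giving the sampling rate, modality
and stimulus-onset index. Preprocessing order is fixed:

    read -> interpolate gaps -> epoch -> spectrum -> pool / average

The 5 Hz low-pass filter exists only for waveform display and is never part
of the analysis path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "RecordingSet",
    "InterpolationResult",
    "read_trials_csv",
    "write_trials_csv",
    "interpolate_gaps",
    "pool_eyes",
    "average_electrodes",
    "lowpass_display",
    "OCCIPITAL_ELECTRODES",
]

TRIAL_COLUMNS = ["participant", "condition", "trial", "channel", "sample_index", "value"]

#: posterior electrodes averaged for the steady-state EEG response
OCCIPITAL_ELECTRODES = ("POz", "Oz", "O1", "O2")

NOMINAL_RATES = {"pupil": 120.0, "eeg": 1000.0}


@dataclass
class RecordingSet:
    """All trials of one modality for a set of participants.

    ``trials`` maps (participant, condition, trial, channel) to a 1-D sample
    array at ``rate`` samples/s. Missing samples are NaN, never dropped.
    """

    modality: str
    rate: float
    trials: dict[tuple[str, str, int, str], np.ndarray] = field(default_factory=dict)
    onset_index: int = 0

    def __post_init__(self) -> None:
        if self.modality not in NOMINAL_RATES:
            raise ValueError(f"modality must be 'pupil' or 'eeg', got {self.modality!r}")

    @property
    def channels(self) -> list[str]:
        return sorted({k[3] for k in self.trials})

    def keys(self):
        return self.trials.keys()


def write_trials_csv(path: str | Path, rec: RecordingSet) -> None:
    """Write a RecordingSet to the long CSV schema plus JSON sidecar."""
    path = Path(path)
    rows = []
    for (pp, cond, trial, chan), samples in sorted(rec.trials.items()):
        rows.append(
            pd.DataFrame(
                {
                    "participant": pp,
                    "condition": cond,
                    "trial": trial,
                    "channel": chan,
                    "sample_index": np.arange(len(samples)),
                    "value": samples,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {"modality": rec.modality, "rate": rec.rate, "onset_index": rec.onset_index}
        )
    )


def read_trials_csv(path: str | Path, modality: str | None = None) -> RecordingSet:
    """Load a long-format trials CSV (schema in the module docstring).

    Row order is irrelevant; samples are placed by ``sample_index``. Missing
    sample indices within a trial become NaN (marked, not silently dropped),
    to be resolved by :func:`interpolate_gaps`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df["sample_index"].isna()
    if bad.any():
        raise ValueError(f"{path}: NaN sample_index at row {int(np.flatnonzero(bad)[0]) + 2}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {}
    modality = modality or meta.get("modality")
    if modality is None:
        raise ValueError("modality not given and no sidecar metadata found")
    rate = float(meta.get("rate", NOMINAL_RATES[modality]))
    rec = RecordingSet(
        modality=modality, rate=rate, onset_index=int(meta.get("onset_index", 0))
    )
    for (pp, cond, trial, chan), g in df.groupby(
        ["participant", "condition", "trial", "channel"], sort=False
    ):
        idx = g["sample_index"].to_numpy(dtype=int)
        n = idx.max() + 1
        samples = np.full(n, np.nan)
        samples[idx] = g["value"].to_numpy(dtype=float)
        rec.trials[(str(pp), str(cond), int(trial), str(chan))] = samples
    return rec


@dataclass(frozen=True)
class InterpolationResult:
    trace: np.ndarray
    n_interpolated: int
    usable: bool
    longest_gap_s: float


def interpolate_gaps(trace: np.ndarray, rate: float, max_gap_s: float = 0.5) -> InterpolationResult:
    """Linearly interpolate across NaN gaps (dropped frames, blinks).

    Gaps longer than ``max_gap_s`` leave the trial flagged unusable
    (``usable=False``); the interpolated trace is still returned. Leading
    or trailing NaNs are filled by nearest-value extension.
    """
    trace = np.asarray(trace, dtype=float).copy()
    bad = ~np.isfinite(trace)
    if not bad.any():
        return InterpolationResult(trace, 0, True, 0.0)
    if bad.all():
        return InterpolationResult(trace, int(bad.sum()), False, len(trace) / rate)
    # longest run of consecutive missing samples
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]]))))[::2]
    longest = float(runs.max()) / rate
    idx = np.arange(len(trace))
    trace[bad] = np.interp(idx[bad], idx[~bad], trace[~bad])
    return InterpolationResult(trace, int(bad.sum()), longest <= max_gap_s, longest)


def pool_eyes(left: Sequence[complex], right: Sequence[complex]) -> np.ndarray:
    """Pool per-trial complex amplitudes across the two eyes.

    The consensual pupil response makes the two eyes' records equivalent
    measurements of the same signal, so trials are concatenated into one
    pool at the complex-amplitude level, before coherent averaging.
    """
    return np.concatenate([np.asarray(left, dtype=complex), np.asarray(right, dtype=complex)])


def average_electrodes(
    spectra: Mapping[str, np.ndarray | complex],
    names: Sequence[str] = OCCIPITAL_ELECTRODES,
) -> np.ndarray | complex:
    """Coherent (complex) mean across named electrodes.

    ``spectra`` maps electrode name to a complex amplitude or spectrum
    array; all requested electrodes must be present.
    """
    absent = [e for e in names if e not in spectra]
    if absent:
        raise KeyError(f"missing electrode(s): {absent}")
    stacked = np.asarray([np.asarray(spectra[e]) for e in names])
    out = stacked.mean(axis=0)
    return out if out.ndim else complex(out)


def lowpass_display(trace: np.ndarray, rate: float, cutoff: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass for waveform display only.

    Never applied before spectral analysis — it exists to make the 2 Hz
    entrainment visible in plotted group waveforms.
    """
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz is not below Nyquist ({rate / 2} Hz)")
    sos = butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))
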