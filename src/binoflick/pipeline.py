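"""End-to-end analysis orchestration.

Ties the stages together in the fixed order
read -> interpolate -> epoch -> spectrum -> pool/average -> statistics,
producing tidy tables of complex amplitudes and condition summaries, and
preparing amplitude observations for the Bayesian fit. Each helper returns
plain DataFrames so every intermediate is inspectable and serialisable.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import AmplitudePoint
from .io import OCCIPITAL_ELECTRODES, RecordingSet, interpolate_gaps, pool_eyes, average_electrodes
from .model import StimulusCondition
from .spectral import (
    amplitude_spectrum,
    bootstrap_se,
    coherent_mean,
    epoch_trial,
    mahalanobis_filter,
    ratio_db,
    tcirc2,
)

__all__ = [
    "trial_amplitudes",
    "participant_amplitudes",
    "group_summary",
    "binocular_ratio_table",
    "amplitude_points",
]

PIPELINE_ORDER = ("read", "interpolate", "epoch", "spectrum", "pool", "average")


def trial_amplitudes(
    rec: RecordingSet,
    freqs: Sequence[float],
    skip_s: float = 2.0,
    keep_s: float = 10.0,
    max_gap_s: float = 0.5,
) -> pd.DataFrame:
    """Per-trial complex amplitudes at the analysis frequencies.

    Pupil traces are gap-interpolated first (trials whose longest gap
    exceeds ``max_gap_s`` are dropped); every trial is epoched to the
    steady-state window and Fourier-transformed. Returns columns
    participant, condition, trial, channel, freq_hz, re, im.
    """
    rows = []
    for (pp, cond, trial, chan), samples in rec.trials.items():
        x = np.asarray(samples, dtype=float)
        if rec.modality == "pupil":
            res = interpolate_gaps(x, rec.rate, max_gap_s=max_gap_s)
            if not res.usable:
                continue
            x = res.trace
        elif not np.all(np.isfinite(x)):
            continue  # NaN-bearing epochs never enter the analysis path
        spec = amplitude_spectrum(epoch_trial(x, rec.rate, skip_s=skip_s, keep_s=keep_s))
        for f in freqs:
            z = spec.at(f)
            rows.append(
                {"participant": pp, "condition": cond, "trial": trial,
                 "channel": chan, "freq_hz": f, "re": z.real, "im": z.imag}
            )
    return pd.DataFrame(rows)


def _coherent_cell(values: np.ndarray) -> complex:
    kept, _ = mahalanobis_filter(values)
    return coherent_mean(kept)


def participant_amplitudes(trial_df: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Collapse trials (and channels) to one complex amplitude per
    participant x condition x frequency.

    Pupil: the two eyes' trials are pooled into one set (consensual
    response), outlier-filtered, and coherently averaged. EEG: trials are
    averaged per electrode, then the four occipital electrodes are
    coherently averaged.
    """
    rows = []
    for (pp, cond, f), g in trial_df.groupby(["participant", "condition", "freq_hz"]):
        if modality == "pupil":
            eyes = {c: (sub["re"].to_numpy() + 1j * sub["im"].to_numpy())
                    for c, sub in g.groupby("channel")}
            vals = list(eyes.values())
            pooled = pool_eyes(vals[0], vals[1]) if len(vals) == 2 else np.asarray(vals[0])
            z = _coherent_cell(pooled)
        else:
            per_elec = {
                c: _coherent_cell(sub["re"].to_numpy() + 1j * sub["im"].to_numpy())
                for c, sub in g.groupby("channel")
            }
            names = [e for e in OCCIPITAL_ELECTRODES if e in per_elec] or sorted(per_elec)
            z = complex(average_electrodes(per_elec, names=names))
        rows.append({"participant": pp, "condition": cond, "freq_hz": f,
                     "re": z.real, "im": z.imag})
    return pd.DataFrame(rows)


def group_summary(part_df: pd.DataFrame, bootstrap_seed: int = 0) -> pd.DataFrame:
    """Group-level coherent averages with outlier exclusion, bootstrap SEs
    across participants, and a zero-mean test per cell."""
    rows = []
    for (cond, f), g in part_df.groupby(["condition", "freq_hz"]):
        z = g["re"].to_numpy() + 1j * g["im"].to_numpy()
        kept, excluded = mahalanobis_filter(z)
        mean = coherent_mean(kept)
        se = bootstrap_se(kept, seed=bootstrap_seed) if kept.size >= 2 else np.nan
        res = tcirc2(kept) if kept.size >= 2 else None
        rows.append(
            {"condition": cond, "freq_hz": f, "amplitude": abs(mean),
             "re": mean.real, "im": mean.imag, "se": se,
             "n_participants": int(kept.size), "n_excluded": int(excluded.size),
             "stat": res.statistic if res else np.nan,
             "df1": res.df1 if res else 0, "df2": res.df2 if res else 0,
             "p": res.p if res else np.nan}
        )
    return pd.DataFrame(rows)


def binocular_ratio_table(
    part_df: pd.DataFrame,
    freq_hz: float = 2.0,
    binocular_prefix: str = "binocular_c",
    monocular_prefix: str = "monocular_c",
) -> pd.DataFrame:
    """Per-contrast binocular:monocular dB ratios, computed per participant
    then averaged, with bootstrap SEs."""
    d = part_df[part_df["freq_hz"] == freq_hz].copy()
    d["amplitude"] = np.hypot(d["re"], d["im"])
    rows = []
    bino = d[d["condition"].str.startswith(binocular_prefix)]
    mono = d[d["condition"].str.startswith(monocular_prefix)]
    contrasts = sorted(
        float(c.removeprefix(binocular_prefix)) for c in bino["condition"].unique()
    )
    for c in contrasts:
        b = bino[bino["condition"] == f"{binocular_prefix}{c:g}"].set_index("participant")["amplitude"]
        m = mono[mono["condition"] == f"{monocular_prefix}{c:g}"].set_index("participant")["amplitude"]
        common = b.index.intersection(m.index)
        ratios = []
        for pp in common:
            if b[pp] > 0 and m[pp] > 0:
                ratios.append(ratio_db(b[pp], m[pp]))
        ratios = np.asarray(ratios)
        rows.append(
            {"contrast": c, "freq_hz": freq_hz, "ratio_db": float(ratios.mean()),
             "se_db": bootstrap_se(ratios) if len(ratios) >= 2 else np.nan,
             "n": len(ratios)}
        )
    return pd.DataFrame(rows)


def amplitude_points(
    part_df: pd.DataFrame, conditions: Sequence[StimulusCondition]
) -> list[AmplitudePoint]:
    """Amplitude observations (|coherent mean| per participant cell) paired
    with their stimulus conditions, ready for the likelihood."""
    from .synth import _condition_label

    by_label: Mapping[str, StimulusCondition] = {_condition_label(c): c for c in conditions}
    pts = []
    for row in part_df.itertuples():
        cond = by_label.get(row.condition)
        if cond is None:
            continue
        pts.append(
            AmplitudePoint(
                condition=cond,
                freq_hz=float(row.freq_hz),
                amplitude=float(np.hypot(row.re, row.im)),
            )
        )
    return pts
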