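"""Dichoptic contrast-matching machinery.

A two-interval procedure: one interval holds a binocular standard flickering
at a fixed contrast (24% or 48%), the other a target whose overall contrast
is driven by a 1-up/1-down staircase in dB steps while its interocular
contrast ratio is fixed per block. Pooled responses per condition are fitted
with a cumulative-normal psychometric function whose 50% point is the point
of subjective equality (PSE); PSEs across ratios trace a matching contour in
the (left contrast, right contrast) plane that discriminates linear
summation from winner-take-all combination.

dB convention: level_db = 20*log10(contrast_pct), i.e. dB re 1% contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .model import ModelParams, binocular_response

__all__ = [
    "MatchingTrial",
    "StaircaseState",
    "PsychometricFit",
    "db_to_pct",
    "pct_to_db",
    "staircase_update",
    "simulate_matching_block",
    "fit_psychometric",
    "assemble_contour",
    "RATIOS",
    "STANDARDS",
]

#: interocular target ratios of the design; ratios < 1 are run on both sides
RATIOS = (0.0, 0.25, 0.5, 0.75, 1.0)
STANDARDS = (24.0, 48.0)


def db_to_pct(db: float | np.ndarray) -> float | np.ndarray:
    return 10.0 ** (np.asarray(db, dtype=float) / 20.0)


def pct_to_db(pct: float | np.ndarray) -> float | np.ndarray:
    return 20.0 * np.log10(np.asarray(pct, dtype=float))


@dataclass(frozen=True)
class MatchingTrial:
    """One two-interval matching trial."""

    standard_contrast: float
    target_cL: float
    target_cR: float
    ratio: float
    side: Literal["left", "right", "both"]
    response: bool  # True = target judged more intense


@dataclass
class StaircaseState:
    """1-up/1-down staircase over target level in dB re 1% contrast."""

    level: float
    step: float = 3.0
    final_step: float = 1.5
    reversals_to_halve: int = 2
    n_reversals: int = 0
    last_direction: int = 0
    history: list[float] = field(default_factory=list)
    reversal_levels: list[float] = field(default_factory=list)


def staircase_update(state: StaircaseState, response: bool) -> StaircaseState:
    """Advance the staircase one trial.

    'Target more intense' moves the level down one step; otherwise up.
    The step halves after ``reversals_to_halve`` reversals.
    """
    direction = -1 if response else +1
    new = replace(
        state,
        history=state.history + [state.level],
        reversal_levels=list(state.reversal_levels),
    )
    if state.last_direction != 0 and direction != state.last_direction:
        new.n_reversals += 1
        new.reversal_levels.append(state.level)
        if new.n_reversals == new.reversals_to_halve:
            new.step = new.final_step
    new.level = new.level + direction * new.step
    new.last_direction = direction
    return new


def _target_contrasts(level_db: float, ratio: float, side: str) -> tuple[float, float]:
    c = float(db_to_pct(level_db))
    c = min(c, 100.0)  # display ceiling at presentation time
    lo = ratio * c
    if side == "both" or ratio == 1.0:
        return c, c
    return (c, lo) if side == "left" else (lo, c)


def simulate_matching_block(
    observer: ModelParams,
    ratio: float,
    standard: float,
    side: str = "left",
    n_trials: int = 50,
    start_level_db: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[MatchingTrial]:
    """Simulate one staircase block of a stochastic matching observer.

    The observer compares gain-control responses (matching mode, no Rmax)
    and chooses the target with probability
    ``Phi((Resp_target - Resp_standard) / n)``; its decision noise is the
    observer's ``n`` parameter. Target levels follow the 1-up/1-down
    staircase. Zero decision noise gives a deterministic comparison.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = replace(observer, Rmax=None)
    resp_std = binocular_response(standard, standard, obs)
    if start_level_db is None:
        start_level_db = float(pct_to_db(standard)) + 6.0
    state = StaircaseState(level=start_level_db)
    trials: list[MatchingTrial] = []
    for _ in range(n_trials):
        cL, cR = _target_contrasts(state.level, ratio, side)
        resp_t = binocular_response(cL, cR, obs)
        if obs.n == 0:
            p = 1.0 if resp_t > resp_std else (0.5 if resp_t == resp_std else 0.0)
        else:
            p = float(norm.cdf((resp_t - resp_std) / obs.n))
        chose_target = bool(rng.random() < p)
        trials.append(
            MatchingTrial(
                standard_contrast=standard,
                target_cL=cL,
                target_cR=cR,
                ratio=ratio,
                side=side,
                response=chose_target,
            )
        )
        state = staircase_update(state, chose_target)
    return trials


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood cumulative-normal fit to pooled binary responses."""

    pse: float  # dB level at 50% "target more intense"
    slope: float  # SD of the cumulative normal, dB
    n_trials: int
    converged: bool
    degenerate: bool = False


def _trial_level_db(t: MatchingTrial) -> float:
    return float(pct_to_db(max(t.target_cL, t.target_cR)))


def fit_psychometric(
    trials: Sequence[MatchingTrial] | pd.DataFrame,
    min_trials: int = 20,
    min_levels: int = 3,
) -> PsychometricFit:
    """Fit P(target chosen) = Phi((level_db - pse) / slope) by ML.

    Trials are pooled across repetitions of one condition. The PSE may
    extrapolate beyond the 100% contrast ceiling (40 dB) when the observer
    never finds the target intense enough within range. Degenerate data
    (all responses identical, or perfectly separated responses) are flagged.
    """
    if isinstance(trials, pd.DataFrame):
        levels = pct_to_db(trials[["target_cL", "target_cR"]].max(axis=1).to_numpy())
        resp = trials["response"].to_numpy(dtype=bool)
    else:
        levels = np.array([_trial_level_db(t) for t in trials])
        resp = np.array([t.response for t in trials], dtype=bool)
    n = len(levels)
    if n < min_trials or len(np.unique(np.round(levels, 6))) < min_levels:
        raise ValueError(f"need >= {min_trials} trials over >= {min_levels} levels, got {n}")
    if resp.all() or not resp.any():
        return PsychometricFit(
            pse=float(np.median(levels)), slope=np.inf, n_trials=n, converged=False, degenerate=True
        )
    # orientation check: choices must increase with level overall
    hi = resp[levels >= np.median(levels)].mean()
    lo = resp[levels < np.median(levels)].mean()
    if hi < lo - 0.25:
        raise ValueError("responses decrease with target level; check response coding")

    def nll(theta: np.ndarray) -> float:
        pse, log_slope = theta
        p = norm.cdf((levels - pse) / np.exp(log_slope))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(np.where(resp, np.log(p), np.log1p(-p))))

    x0 = np.array([float(np.median(levels)), np.log(2.0)])
    best = None
    for s0 in (0.5, 2.0, 6.0):
        res = minimize(nll, np.array([x0[0], np.log(s0)]), method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    pse, log_slope = best.x
    slope = float(np.exp(log_slope))
    degenerate = slope < 0.1  # (near-)perfectly separated responses, dB
    return PsychometricFit(
        pse=float(pse), slope=slope, n_trials=n, converged=bool(best.success), degenerate=degenerate
    )


def assemble_contour(
    fits: Sequence[tuple[float, str, PsychometricFit]] | pd.DataFrame,
    standard: float,
    average_sides: bool = False,
) -> pd.DataFrame:
    """Turn per-condition PSE fits into (cL, cR) matching-contour points.

    ``fits`` holds (ratio, side, fit) triples — 9 conditions for the full
    design. PSEs are converted from dB to % contrast and split into per-eye
    contrasts by the condition ratio. With ``average_sides=True`` the two
    mirror-symmetric sides of each ratio are averaged (in dB) into one
    radial position reported for both sides. When several participants'
    fits share a (ratio, side) cell, their PSEs are averaged in dB.
    """
    if isinstance(fits, pd.DataFrame):
        rows = [(r.ratio, r.side, r.pse_db) for r in fits.itertuples()]
    else:
        rows = [(ratio, side, fit.pse) for ratio, side, fit in fits]
    df = pd.DataFrame(rows, columns=["ratio", "side", "pse_db"])
    mean_db = df.groupby(["ratio", "side"], as_index=False)["pse_db"].mean()
    if average_sides:
        pooled = mean_db.groupby("ratio", as_index=False)["pse_db"].mean()
        mean_db = (
            mean_db[["ratio", "side"]]
            .merge(pooled, on="ratio")[["ratio", "side", "pse_db"]]
        )
    out = []
    expected = {(r, s) for r in RATIOS for s in (("both",) if r == 1.0 else ("left", "right"))}
    seen = set()
    for row in mean_db.itertuples():
        c = float(db_to_pct(row.pse_db))
        lo = row.ratio * c
        if row.side == "both" or row.ratio == 1.0:
            cL = cR = c
        elif row.side == "left":
            cL, cR = c, lo
        else:
            cL, cR = lo, c
        seen.add((row.ratio, row.side))
        out.append({"ratio": row.ratio, "side": row.side, "pse_db": row.pse_db, "cL": cL, "cR": cR})
    missing = expected - seen
    if missing:
        import warnings

        warnings.warn(f"partial contour: missing conditions {sorted(missing)}", stacklevel=2)
    return pd.DataFrame(out).sort_values(["ratio", "side"]).reset_index(drop=True)
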