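"""Binocular contrast gain-control model for luminance flicker.

The model is a single-stage divisive gain-control architecture. Each eye's
channel responds to its own temporal (Michelson) contrast, divisively
normalised by a saturation constant ``Z`` and by the other eye's contrast
weighted by the interocular suppression weight ``w``::

    Resp_L = L**2 / (Z + L + w * R)
    Resp_R = R**2 / (Z + R + w * L)
    Resp_B = Rmax * (Resp_L + Resp_R) + n

with the numerator exponent fixed at 2. ``w`` is the parameter of scientific
interest: values near 1 abolish the binocular advantage at high contrast
(ocularity invariance), values near 0 produce near-linear binocular
facilitation.

The same equations applied sample-by-sample to half-wave-rectified contrast
waveforms yield the full steady-state spectrum of the response, including
harmonic and intermodulation components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "StimulusCondition",
    "OCULAR_CONFIGS",
    "channel_response",
    "binocular_response",
    "binocular_ratio",
    "response_waveform",
    "predicted_amplitudes",
    "model_matching_contour",
    "canonical_contour",
]

#: exponent of the numerator; fixed, because it trades off with w when free
NUMERATOR_EXPONENT = 2

OCULAR_CONFIGS = (
    "monocular",
    "binocular",
    "dichoptic",
    "monocular_cross",
    "binocular_cross",
    "dichoptic_cross",
)


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the gain-control model.

    Parameters
    ----------
    Z : float
        Saturation constant, in % contrast units. Shifts the
        contrast-response function laterally. Must be positive.
    w : float
        Interocular suppression weight (dimensionless, >= 0).
    n : float
        Noise parameter. In response mode it is an additive offset on the
        summed response; in matching mode it is the decision-noise SD of
        the probit choice rule. Must be non-negative.
    Rmax : float or None
        Output scaling (response units per model unit). ``None`` selects
        matching mode, where the scaling has no effect and the additive
        noise term cancels in response differences.
    """

    Z: float
    w: float
    n: float
    Rmax: float | None = None

    def __post_init__(self) -> None:
        if not self.Z > 0:
            raise ValueError(f"Z must be > 0, got {self.Z}")
        if self.w < 0:
            raise ValueError(f"w must be >= 0, got {self.w}")
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if self.Rmax is not None and not self.Rmax > 0:
            raise ValueError(f"Rmax must be > 0 when present, got {self.Rmax}")

    @property
    def matching_mode(self) -> bool:
        return self.Rmax is None

    def with_noise_scaled(self, N: int) -> "ModelParams":
        """Return a copy with n divided by sqrt(N) (group-level correction)."""
        from .bayes import group_noise_scaling

        return replace(self, n=group_noise_scaling(self.n, N))


@dataclass(frozen=True)
class StimulusCondition:
    """One ocular configuration at one target contrast.

    ``target_contrast`` modulates at ``target_freq`` (2 Hz by default); the
    *_cross configurations add a second frequency (1.6 Hz) in the other eye,
    and the dichoptic configurations fix the mask contrast at 48%.
    """

    ocular_config: str
    target_contrast: float
    mask_contrast: float = 0.0
    target_freq: float = 2.0
    mask_freq: float | None = None
    target_eye: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if self.ocular_config not in OCULAR_CONFIGS:
            raise ValueError(f"unknown ocular_config {self.ocular_config!r}")
        for c in (self.target_contrast, self.mask_contrast):
            if not 0 <= c <= 100:
                raise ValueError(f"contrast {c} outside [0, 100]")
        if self.ocular_config.endswith("_cross") and self.mask_freq is None:
            raise ValueError("cross-frequency configuration needs mask_freq")
        if self.ocular_config in ("dichoptic", "dichoptic_cross") and self.mask_contrast != 48:
            raise ValueError("dichoptic configurations use a fixed 48% mask")

    def eye_contrasts(self) -> tuple[dict[float, float], dict[float, float]]:
        """Per-eye mapping {frequency: contrast} for target and other eye."""
        c, m = self.target_contrast, self.mask_contrast
        f1 = self.target_freq
        f2 = self.mask_freq
        cfg = self.ocular_config
        if cfg == "monocular":
            return {f1: c}, {}
        if cfg == "binocular":
            return {f1: c}, {f1: c}
        if cfg == "dichoptic":
            return {f1: c}, {f1: m}
        if cfg == "monocular_cross":
            # target eye sees the 1.6 Hz flicker, other eye mean luminance
            return {f2: c}, {}
        if cfg == "binocular_cross":
            return {f1: c}, {f2: c}
        # dichoptic_cross: target at f1, fixed-contrast mask at f2
        return {f1: c}, {f2: m}


def _check_contrasts(*contrasts: float) -> None:
    for c in contrasts:
        if np.any(np.asarray(c) < 0):
            raise ValueError("contrast must be non-negative")


def channel_response(c_own, c_other, params: ModelParams):
    """Response of one eye's channel, ``c_own**2 / (Z + c_own + w*c_other)``.

    Accepts scalars or arrays (broadcast). Contrasts are % Michelson.
    """
    _check_contrasts(c_own, c_other)
    c_own = np.asarray(c_own, dtype=float)
    c_other = np.asarray(c_other, dtype=float)
    out = c_own**NUMERATOR_EXPONENT / (params.Z + c_own + params.w * c_other)
    return out if out.ndim else float(out)


def binocular_response(cL, cR, params: ModelParams):
    """Summed binocular response ``Rmax*(Resp_L + Resp_R) + n``.

    In matching mode (``Rmax is None``) returns the bare channel sum: the
    additive noise term cancels in any response difference, so ``n`` acts
    as decision-noise SD in the choice rule instead.
    """
    s = channel_response(cL, cR, params) + channel_response(cR, cL, params)
    if params.matching_mode:
        return s
    return params.Rmax * s + params.n


def binocular_ratio(contrast, params: ModelParams, include_noise: bool = False):
    """Ratio of binocular (c, c) to monocular (c, 0) response.

    With ``include_noise=False`` the ratio is taken on the bare channel sums
    (``2*(Z+c)/(Z+c*(1+w))``), which equals exactly 2 when w = 0.
    """
    if not include_noise and np.any(np.asarray(contrast) <= 0):
        raise ZeroDivisionError("noise-free ratio undefined at zero contrast")
    if include_noise:
        return binocular_response(contrast, contrast, params) / binocular_response(
            contrast, 0.0, params
        )
    bare = replace(params, Rmax=None)
    return binocular_response(contrast, contrast, bare) / binocular_response(
        contrast, 0.0, bare
    )


def response_waveform(
    waveL: np.ndarray,
    waveR: np.ndarray,
    params: ModelParams,
    rate: float | None = None,
    rate_other: float | None = None,
) -> np.ndarray:
    """Apply the gain-control equations pointwise to contrast waveforms.

    Each eye's signed instantaneous contrast is half-wave rectified into an
    on-channel (negative lobes -> 0) before the divisive equations are
    applied at each sample. Rectification followed by the static
    nonlinearity generates both odd and even harmonics of the inputs and,
    when w > 0, intermodulation components at sums and differences of the
    two eyes' frequencies.

    Parameters
    ----------
    waveL, waveR : arrays of signed % contrast, equal length.
    rate, rate_other : optional sampling rates of the two inputs; if both
        given they must match.
    """
    waveL = np.asarray(waveL, dtype=float)
    waveR = np.asarray(waveR, dtype=float)
    if waveL.shape != waveR.shape:
        raise ValueError("eye waveforms must have equal length")
    if rate is not None and rate_other is not None and rate != rate_other:
        raise ValueError("eye waveforms must share a sampling rate")
    L = np.clip(waveL, 0.0, None)
    R = np.clip(waveR, 0.0, None)
    respL = L**NUMERATOR_EXPONENT / (params.Z + L + params.w * R)
    respR = R**NUMERATOR_EXPONENT / (params.Z + R + params.w * L)
    s = respL + respR
    if params.matching_mode:
        return s
    return params.Rmax * s + params.n


def predicted_amplitudes(cond: StimulusCondition, params: ModelParams) -> dict[float, float]:
    """Scalar-mode predicted response amplitude at each stimulated frequency.

    Frequencies are resolved independently: the channel driven at frequency f
    responds with its own contrast at f in the numerator, suppressed by the
    other eye's total contrast. Channels driven at the same frequency sum.
    The additive noise floor n enters every frequency's amplitude.
    """
    eyeT, eyeO = cond.eye_contrasts()
    totT = sum(eyeT.values())
    totO = sum(eyeO.values())
    freqs = sorted(set(eyeT) | set(eyeO))
    out: dict[float, float] = {}
    for f in freqs:
        s = 0.0
        if f in eyeT:
            s += channel_response(eyeT[f], totO, params)
        if f in eyeO:
            s += channel_response(eyeO[f], totT, params)
        if params.matching_mode:
            out[f] = s
        else:
            out[f] = params.Rmax * s + params.n
    return out


def model_matching_contour(
    params: ModelParams,
    standard_contrast: float,
    ratios: Sequence[float],
    ceiling: float = 100.0,
    mirror: bool = True,
) -> list[tuple[float, float]]:
    """Predicted contrast-matching contour of the gain-control model.

    For each interocular ratio r, finds the target contrast c such that a
    (c, r*c) stimulus matches the binocular standard in model response,
    by monotone root finding. Points are returned as (cL, cR); with
    ``mirror=True`` the symmetric eye assignment (r*c, c) is appended for
    r < 1.
    """
    if not 0 < standard_contrast <= 100:
        raise ValueError("standard contrast must lie in (0, 100]")
    target = binocular_response(standard_contrast, standard_contrast, params)
    hi = 10.0 * ceiling
    pts: list[tuple[float, float]] = []
    for r in ratios:
        if not 0 <= r <= 1:
            raise ValueError(f"ratio {r} outside [0, 1]")

        def f(c: float, r=r) -> float:
            return binocular_response(c, r * c, params) - target

        if f(hi) < 0:
            raise ValueError(
                f"no matching contrast below {hi}% for ratio {r} (unreachable match)"
            )
        c = brentq(f, 0.0, hi, rtol=1e-9)
        pts.append((c, r * c))
        if mirror and r < 1:
            pts.append((r * c, c))
    return pts


def canonical_contour(
    rule: str,
    standard_contrast: float,
    ratios: Sequence[float],
    mirror: bool = True,
) -> list[tuple[float, float]]:
    """Matching contours of the canonical summation rules.

    ``linear``: contrasts satisfy cL + cR = 2*standard (pure additivity).
    ``max``: winner-take-all, max(cL, cR) = standard.
    """
    pts: list[tuple[float, float]] = []
    for r in ratios:
        if not 0 <= r <= 1:
            raise ValueError(f"ratio {r} outside [0, 1]")
        if rule == "linear":
            c = 2.0 * standard_contrast / (1.0 + r)
        elif rule == "max":
            c = standard_contrast
        else:
            raise ValueError(f"unknown summation rule {rule!r} (use 'linear' or 'max')")
        pts.append((c, r * c))
        if mirror and r < 1:
            pts.append((r * c, c))
    return pts
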