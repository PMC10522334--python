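"""Hierarchical Bayesian estimation of the gain-control parameters.

A single group-level parameter set (Z, w, n, and Rmax for response data) is
estimated from the pooled individual data of all participants: Student-t
likelihood (nu = 5) for steady-state response amplitudes, Bernoulli/probit
likelihood for single-trial matching choices. Priors are zero-truncated
Gaussians — mean 1, SD 0.5 for w and Rmax; mean 5, SD 2 for Z and n.

Sampling uses an affine-invariant ensemble sampler (emcee); walkers are
treated as chains for split R-hat and effective-sample-size diagnostics
(arviz). The contract for a converged fit is R-hat < 1.05 and ESS > 400.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import special, stats

from .model import ModelParams, StimulusCondition, predicted_amplitudes

__all__ = [
    "PriorSpec",
    "FitConfig",
    "PosteriorSummary",
    "AmplitudePoint",
    "STUDENT_T_DF",
    "default_priors",
    "group_noise_scaling",
    "loglik_amplitudes",
    "loglik_matching",
    "sample_posterior",
]

#: degrees of freedom of the amplitude likelihood (fixed, heavy-tailed)
STUDENT_T_DF = 5.0

RESPONSE_PARAMS = ("Z", "w", "n", "Rmax")
MATCHING_PARAMS = ("Z", "w", "n")


@dataclass(frozen=True)
class PriorSpec:
    """Zero-truncated Gaussian priors, one (mean, sd) pair per parameter."""

    means: Mapping[str, float]
    sds: Mapping[str, float]

    def logpdf(self, names: Sequence[str], values: np.ndarray) -> float:
        if np.any(values < 0):
            return -np.inf
        lp = 0.0
        for name, v in zip(names, values):
            m, s = self.means[name], self.sds[name]
            lp += stats.norm.logpdf(v, m, s) - stats.norm.logsf(0.0, m, s)
        return float(lp)

    def sample(self, names: Sequence[str], rng: np.random.Generator) -> np.ndarray:
        out = np.empty(len(names))
        for i, name in enumerate(names):
            m, s = self.means[name], self.sds[name]
            v = -1.0
            while v < 0:
                v = rng.normal(m, s)
            out[i] = v
        return out


def default_priors() -> PriorSpec:
    return PriorSpec(
        means={"Z": 5.0, "n": 5.0, "w": 1.0, "Rmax": 1.0},
        sds={"Z": 2.0, "n": 2.0, "w": 0.5, "Rmax": 0.5},
    )


@dataclass(frozen=True)
class FitConfig:
    """Sampler configuration for one dataset fit."""

    kind: str  # pupil | eeg_1f | eeg_2f | matching
    walkers: int = 32
    draws: int = 4000
    warmup: int = 2000
    seed: int = 0
    group_size: int = 1
    fixed: Mapping[str, float] = field(default_factory=dict)

    @property
    def param_names(self) -> tuple[str, ...]:
        base = MATCHING_PARAMS if self.kind == "matching" else RESPONSE_PARAMS
        return tuple(p for p in base if p not in self.fixed)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior medians, central intervals, and convergence diagnostics."""

    median: Mapping[str, float]
    interval_95: Mapping[str, tuple[float, float]]
    rhat: Mapping[str, float]
    ess: Mapping[str, float]
    converged: bool
    draws: pd.DataFrame  # columns: chain, draw, <params>

    def table(self) -> pd.DataFrame:
        rows = []
        for p, m in self.median.items():
            lo, hi = self.interval_95[p]
            rows.append(
                {"parameter": p, "median": m, "ci_lo": lo, "ci_hi": hi,
                 "rhat": self.rhat[p], "ess": self.ess[p]}
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AmplitudePoint:
    """One steady-state amplitude observation entering the likelihood."""

    condition: StimulusCondition
    freq_hz: float
    amplitude: float


def group_noise_scaling(n: float, N: int) -> float:
    """Scale the noise parameter by sqrt(N) for coherently averaged group data.

    Coherent averaging over N participants shrinks phase-incoherent noise by
    sqrt(N); a model fitted to the group average therefore uses n/sqrt(N).
    """
    if N < 1:
        raise ValueError("group size must be >= 1")
    return n / np.sqrt(N)


def _params_from(names: Sequence[str], values: np.ndarray, fixed: Mapping[str, float],
                 matching: bool) -> ModelParams | None:
    d = dict(fixed)
    d.update(zip(names, values))
    try:
        return ModelParams(
            Z=d["Z"], w=d["w"], n=d["n"], Rmax=None if matching else d["Rmax"]
        )
    except ValueError:
        return None


def loglik_amplitudes(
    data: Sequence[AmplitudePoint],
    params: ModelParams,
    scale: float | None = None,
) -> float:
    """Student-t log likelihood of amplitude data under the model.

    Each observation contributes a t(nu=5) density centred on the model's
    predicted amplitude at its condition and frequency, with scale ``n``
    (or an explicit ``scale``, e.g. after group-noise scaling).
    """
    s = params.n if scale is None else scale
    if s <= 0:
        return -np.inf
    preds = np.array(
        [predicted_amplitudes(p.condition, params)[p.freq_hz] for p in data]
    )
    obs = np.array([p.amplitude for p in data])
    ll = stats.t.logpdf(obs, df=STUDENT_T_DF, loc=preds, scale=s).sum()
    return float(ll) if np.isfinite(ll) else -np.inf


def loglik_matching(trials: pd.DataFrame | Sequence, params: ModelParams) -> float:
    """Bernoulli log likelihood of single-trial matching choices.

    Choice probability is Phi((Resp_target - Resp_standard) / n) with
    matching-mode responses (Rmax absent); probabilities are clipped to
    [1e-9, 1 - 1e-9].
    """
    from .model import binocular_response

    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame(
            [
                {
                    "standard_pct": t.standard_contrast,
                    "target_cL": t.target_cL,
                    "target_cR": t.target_cR,
                    "response": t.response,
                }
                for t in trials
            ]
        )
    bare = ModelParams(Z=params.Z, w=params.w, n=params.n, Rmax=None)
    if bare.n <= 0:
        return -np.inf
    cL = trials["target_cL"].to_numpy(dtype=float)
    cR = trials["target_cR"].to_numpy(dtype=float)
    std = trials["standard_pct"].to_numpy(dtype=float)
    resp = trials["response"].to_numpy(dtype=bool)
    dr = binocular_response(cL, cR, bare) - binocular_response(std, std, bare)
    p = np.clip(stats.norm.cdf(dr / bare.n), 1e-9, 1 - 1e-9)
    ll = np.where(resp, np.log(p), np.log1p(-p)).sum()
    return float(ll) if np.isfinite(ll) else -np.inf


def _precompute_amplitude_design(data: Sequence[AmplitudePoint]):
    """Vectorise the amplitude likelihood: per-point channel drive terms.

    Each point's prediction is Rmax*(sum of c^2/(Z + c + w*c_other)) + n
    over the (at most two) channels driven at the point's frequency; the
    per-channel (c_own, c_other) pairs are condition constants, so the
    MCMC inner loop reduces to array arithmetic.
    """
    own1, oth1, own2, oth2, obs = [], [], [], [], []
    for p in data:
        eyeT, eyeO = p.condition.eye_contrasts()
        totT, totO = sum(eyeT.values()), sum(eyeO.values())
        a = (eyeT[p.freq_hz], totO) if p.freq_hz in eyeT else (0.0, 0.0)
        b = (eyeO[p.freq_hz], totT) if p.freq_hz in eyeO else (0.0, 0.0)
        own1.append(a[0]); oth1.append(a[1])
        own2.append(b[0]); oth2.append(b[1])
        obs.append(p.amplitude)
    return tuple(np.asarray(v, dtype=float) for v in (own1, oth1, own2, oth2, obs))


def sample_posterior(
    data,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
) -> PosteriorSummary:
    """MCMC posterior over the free gain-control parameters.

    ``data`` is a sequence of :class:`AmplitudePoint` for the amplitude
    kinds, or a trials DataFrame for the matching kind. The exponent is
    fixed at 2 throughout. Non-convergence (R-hat >= 1.05 or ESS <= 400)
    flags the result; draws are still returned.
    """
    priors = priors or default_priors()
    config = config or FitConfig(kind="pupil")
    names = config.param_names
    matching = config.kind == "matching"
    rng = np.random.default_rng(config.seed)

    if matching:
        trials = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
        cL = trials["target_cL"].to_numpy(dtype=float)
        cR = trials["target_cR"].to_numpy(dtype=float)
        std = trials["standard_pct"].to_numpy(dtype=float)
        resp = trials["response"].to_numpy(dtype=bool)

        def loglik(p: ModelParams) -> float:
            dr = (
                cL**2 / (p.Z + cL + p.w * cR)
                + cR**2 / (p.Z + cR + p.w * cL)
                - 2 * std**2 / (p.Z + std * (1 + p.w))
            )
            prob = np.clip(special.ndtr(dr / p.n), 1e-9, 1 - 1e-9)
            ll = np.where(resp, np.log(prob), np.log1p(-prob)).sum()
            return float(ll) if np.isfinite(ll) else -np.inf

    else:
        design = _precompute_amplitude_design(list(data))
        own1, oth1, own2, oth2, obs = design
        sqrtN = np.sqrt(config.group_size)
        # Student-t log density, constants hoisted out of the sampler loop
        nu = STUDENT_T_DF
        t_const = float(
            special.gammaln((nu + 1) / 2) - special.gammaln(nu / 2) - 0.5 * np.log(nu * np.pi)
        )
        npts = obs.size

        def loglik(p: ModelParams) -> float:
            pred = own1**2 / (p.Z + own1 + p.w * oth1) + own2**2 / (
                p.Z + own2 + p.w * oth2
            )
            pred = p.Rmax * pred + p.n
            s = p.n / sqrtN
            if s <= 0:
                return -np.inf
            z = (obs - pred) / s
            ll = npts * (t_const - np.log(s)) - ((nu + 1) / 2) * np.log1p(z * z / nu).sum()
            return float(ll) if np.isfinite(ll) else -np.inf

    # priors: constants hoisted (truncation normalisation is theta-independent)
    mu = np.array([priors.means[k] for k in names])
    sd = np.array([priors.sds[k] for k in names])
    prior_const = float(
        -np.sum(np.log(sd)) - np.sum(stats.norm.logsf(0.0, mu, sd)) - len(names) / 2 * np.log(2 * np.pi)
    )

    def logpost(theta: np.ndarray) -> float:
        if np.any(theta < 0):
            return -np.inf
        lp = prior_const - 0.5 * float(np.sum(((theta - mu) / sd) ** 2))
        p = _params_from(names, theta, config.fixed, matching)
        if p is None or p.n <= 0:
            return -np.inf
        return lp + loglik(p)

    ndim = len(names)
    nwalk = max(config.walkers, 2 * ndim + 2)
    p0 = np.array([priors.sample(names, rng) for _ in range(nwalk)])
    # start walkers at finite-posterior prior draws
    for i in range(nwalk):
        for _ in range(100):
            if np.isfinite(logpost(p0[i])):
                break
            p0[i] = priors.sample(names, rng)
    sampler = emcee.EnsembleSampler(nwalk, ndim, logpost)
    sampler.random_state = np.random.RandomState(config.seed).get_state()
    state = sampler.run_mcmc(p0, config.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.draws, progress=False)
    chain = sampler.get_chain()  # (draws, walkers, ndim)

    posterior = {name: chain[:, :, i].T for i, name in enumerate(names)}  # (chain, draw)
    idata = az.from_dict(posterior=posterior)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in names}
    ess = {k: float(ess_ds[k].values) for k in names}
    ndraws = chain.shape[0]
    flat = chain.transpose(1, 0, 2).reshape(-1, ndim)  # walker-major
    median = {k: float(np.median(flat[:, i])) for i, k in enumerate(names)}
    interval = {
        k: (float(np.quantile(flat[:, i], 0.025)), float(np.quantile(flat[:, i], 0.975)))
        for i, k in enumerate(names)
    }
    converged = all(r < 1.05 for r in rhat.values()) and all(e > 400 for e in ess.values())
    draws = pd.DataFrame(flat, columns=list(names))
    draws.insert(0, "draw", np.tile(np.arange(ndraws), nwalk))
    draws.insert(0, "chain", np.repeat(np.arange(nwalk), ndraws))
    return PosteriorSummary(
        median=median, interval_95=interval, rhat=rhat, ess=ess,
        converged=converged, draws=draws,
    )
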