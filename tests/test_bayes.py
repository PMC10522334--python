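"""Likelihood oracles, prior behaviour, and posterior sampling checks
(prior recovery, noise-shrinkage, simulation-based calibration)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binoflick import (
    AmplitudePoint,
    FitConfig,
    ModelParams,
    StimulusCondition,
    binocular_response,
    default_priors,
    group_noise_scaling,
    loglik_amplitudes,
    loglik_matching,
    sample_posterior,
)
from binoflick.bayes import STUDENT_T_DF
from binoflick.matching import MatchingTrial, simulate_matching_block


def _amp_points(params, contrasts=(6, 12, 24, 48, 96), rng=None, noise=0.0):
    pts = []
    for cfg in ("monocular", "binocular", "dichoptic"):
        for c in contrasts:
            cond = StimulusCondition(
                ocular_config=cfg, target_contrast=c,
                mask_contrast=48.0 if cfg == "dichoptic" else 0.0,
            )
            from binoflick import predicted_amplitudes

            amp = predicted_amplitudes(cond, params)[2.0]
            if noise:
                amp = amp + noise * rng.standard_t(STUDENT_T_DF)
            pts.append(AmplitudePoint(condition=cond, freq_hz=2.0, amplitude=max(amp, 0.0)))
    return pts


class TestLikelihoodOracles:
    def test_amplitude_loglik_matches_reference_density(self, pupil_params, rng):
        pts = _amp_points(pupil_params, rng=rng, noise=0.005)
        got = loglik_amplitudes(pts, pupil_params)
        # independent oracle: per-point scipy t density at the model mean
        from binoflick import predicted_amplitudes

        expected = sum(
            stats.t.logpdf(
                p.amplitude, df=STUDENT_T_DF,
                loc=predicted_amplitudes(p.condition, pupil_params)[2.0],
                scale=pupil_params.n,
            )
            for p in pts
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_amplitude_loglik_peaks_at_generating_params(self, pupil_params):
        # data exactly at the model predictions with a tiny noise scale:
        # the likelihood is maximal at the generating parameters
        tight = ModelParams(Z=pupil_params.Z, w=pupil_params.w, n=1e-4,
                            Rmax=pupil_params.Rmax)
        pts = _amp_points(tight)
        base = loglik_amplitudes(pts, tight)
        for dw in (-0.2, 0.2):
            off = ModelParams(Z=tight.Z, w=tight.w + dw, n=tight.n, Rmax=tight.Rmax)
            assert loglik_amplitudes(pts, off) < base

    def test_rmax_rescaling_leaves_residuals(self, pupil_params):
        pts = _amp_points(pupil_params)
        # doubling amplitudes, Rmax and n scales residuals and the noise
        # floor consistently: per-point standardized residuals unchanged
        doubled_pts = [
            AmplitudePoint(p.condition, p.freq_hz, 2 * p.amplitude) for p in pts
        ]
        doubled = ModelParams(Z=pupil_params.Z, w=pupil_params.w,
                              n=2 * pupil_params.n, Rmax=2 * pupil_params.Rmax)
        a = loglik_amplitudes(pts, pupil_params)
        b = loglik_amplitudes(doubled_pts, doubled)
        # densities differ only by the Jacobian of the scale change
        assert b == pytest.approx(a - len(pts) * np.log(2), abs=1e-9)

    def test_matching_loglik_matches_per_trial_oracle(self, matching_params, rng):
        trials = []
        for _ in range(200):
            cL, cR = rng.uniform(0, 100, size=2)
            trials.append(MatchingTrial(48.0, cL, cR, 0.5, "left", bool(rng.random() < 0.5)))
        got = loglik_matching(trials, matching_params)
        expected = 0.0
        for t in trials:
            dr = binocular_response(t.target_cL, t.target_cR, matching_params) - \
                binocular_response(48.0, 48.0, matching_params)
            p = stats.norm.cdf(dr / matching_params.n)
            p = min(max(p, 1e-9), 1 - 1e-9)
            expected += np.log(p) if t.response else np.log1p(-p)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_equal_stimuli_probability_half(self, matching_params):
        trials = [MatchingTrial(48.0, 48.0, 48.0, 1.0, "both", True)] * 4
        assert loglik_matching(trials, matching_params) == pytest.approx(4 * np.log(0.5))

    def test_zero_noise_limit_saturates(self):
        sharp = ModelParams(Z=0.3, w=0.09, n=1e-9)
        trials = [MatchingTrial(24.0, 96.0, 96.0, 1.0, "both", True)]
        assert loglik_matching(trials, sharp) == pytest.approx(0.0, abs=1e-6)


class TestGroupNoiseScaling:
    def test_study_value(self):
        assert group_noise_scaling(0.01, 30) == pytest.approx(0.0018257418, abs=1e-9)

    def test_identity_for_single_participant(self):
        assert group_noise_scaling(0.37, 1) == 0.37

    def test_round_trip(self):
        assert group_noise_scaling(0.2, 25) * np.sqrt(25) == pytest.approx(0.2, rel=1e-12)

    def test_invalid_group_size(self):
        with pytest.raises(ValueError):
            group_noise_scaling(0.1, 0)


class TestPriors:
    def test_truncation_no_negative_draws(self, rng):
        priors = default_priors()
        draws = np.array(
            [priors.sample(("Z", "w", "n", "Rmax"), rng) for _ in range(2000)]
        )
        assert np.all(draws >= 0)

    def test_negative_parameter_zero_density(self):
        priors = default_priors()
        assert priors.logpdf(("w",), np.array([-0.1])) == -np.inf

    def test_stated_prior_moments(self):
        priors = default_priors()
        assert (priors.means["w"], priors.sds["w"]) == (1.0, 0.5)
        assert (priors.means["Rmax"], priors.sds["Rmax"]) == (1.0, 0.5)
        assert (priors.means["Z"], priors.sds["Z"]) == (5.0, 2.0)
        assert (priors.means["n"], priors.sds["n"]) == (5.0, 2.0)


class TestSampling:
    def test_prior_recovery_with_uninformative_data(self, rng):
        # flat amplitudes with huge noise carry no information about w:
        # the posterior on w should reproduce the prior
        cond = StimulusCondition(ocular_config="binocular", target_contrast=48)
        pts = [AmplitudePoint(cond, 2.0, 1.0)] * 3
        cfg = FitConfig(kind="pupil", walkers=16, draws=2000, warmup=1000, seed=4,
                        fixed={"Z": 5.0, "n": 1e6, "Rmax": 1e-6})
        summary = sample_posterior(pts, config=cfg)
        w_draws = summary.draws["w"].to_numpy()
        priors = default_priors()
        prior_draws = np.array([priors.sample(("w",), rng)[0] for _ in range(4000)])
        ks = stats.ks_2samp(w_draws, prior_draws).statistic
        assert ks < 0.1

    def test_posterior_medians_shrink_to_truth_as_noise_falls(self, pupil_params, rng):
        errs = []
        for i, noise in enumerate((0.01, 0.002, 0.0004)):
            # n is both the additive response floor and the noise scale, so
            # the generating parameter set shrinks with the data noise
            gen = ModelParams(Z=pupil_params.Z, w=pupil_params.w, n=noise,
                              Rmax=pupil_params.Rmax)
            pts = _amp_points(gen, rng=np.random.default_rng(100 + i), noise=noise)
            cfg = FitConfig(kind="pupil", walkers=16, draws=1500, warmup=1500, seed=50 + i,
                            fixed={"Z": pupil_params.Z, "Rmax": pupil_params.Rmax})
            s = sample_posterior(pts, config=cfg)
            errs.append(abs(s.median["w"] - pupil_params.w))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05

    def test_simulation_based_calibration_of_w(self):
        # ranks of the true w within posterior draws are uniform when data
        # are generated from the model+prior; chi-square test at alpha=0.01
        priors = default_priors()
        fixed = {"Z": 3.44, "n": 0.01, "Rmax": 0.00023}
        reps, L = 150, 24
        ranks = []
        master = np.random.default_rng(777)
        for r in range(reps):
            w_true = priors.sample(("w",), master)[0]
            gen = ModelParams(Z=fixed["Z"], w=w_true, n=fixed["n"], Rmax=fixed["Rmax"])
            pts = _amp_points(gen, rng=master, noise=fixed["n"])
            cfg = FitConfig(kind="pupil", walkers=8, draws=120, warmup=200,
                            seed=int(master.integers(2**31 - 1)), fixed=fixed)
            s = sample_posterior(pts, config=cfg)
            draws = s.draws["w"].to_numpy()
            thin = draws[:: max(1, len(draws) // L)][:L]
            ranks.append(int(np.sum(thin < w_true)))
        counts = np.bincount(ranks, minlength=L + 1)
        # merge into 5 bins for a stable chi-square
        binned = counts.reshape(5, -1).sum(axis=1)
        chi2 = ((binned - reps / 5) ** 2 / (reps / 5)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_matching_kind_excludes_rmax(self, matching_params):
        rng = np.random.default_rng(21)
        trials = []
        for ratio in (0.0, 0.5, 1.0):
            side = "both" if ratio == 1.0 else "left"
            for _ in range(2):
                trials += simulate_matching_block(matching_params, ratio, 48.0,
                                                  side=side, seed=rng)
        df = pd.DataFrame(
            [{"standard_pct": t.standard_contrast, "target_cL": t.target_cL,
              "target_cR": t.target_cR, "response": t.response} for t in trials]
        )
        cfg = FitConfig(kind="matching", walkers=16, draws=500, warmup=500, seed=9)
        s = sample_posterior(df, config=cfg)
        assert set(s.median) == {"Z", "w", "n"}
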