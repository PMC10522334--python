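"""Staircase dynamics, the stochastic matching observer, psychometric
fitting, and contour assembly."""

import numpy as np
import pytest

from binoflick import ModelParams
from binoflick.matching import (
    RATIOS,
    StaircaseState,
    assemble_contour,
    db_to_pct,
    fit_psychometric,
    pct_to_db,
    simulate_matching_block,
    staircase_update,
)
from binoflick.model import canonical_contour


class TestStaircase:
    def test_target_more_intense_steps_down(self):
        s = StaircaseState(level=20.0, step=2.0)
        s2 = staircase_update(s, response=True)
        assert s2.level == 18.0

    def test_not_more_intense_steps_up(self):
        s = StaircaseState(level=20.0, step=2.0)
        assert staircase_update(s, response=False).level == 22.0

    def test_alternating_responses_oscillate(self):
        s = StaircaseState(level=30.0, step=2.0, final_step=2.0)
        levels = []
        for i in range(20):
            s = staircase_update(s, response=(i % 2 == 0))
            levels.append(s.level)
        assert set(np.round(levels[4:], 6)) <= set(np.round([28.0, 30.0], 6))

    def test_step_halves_after_two_reversals(self):
        s = StaircaseState(level=30.0)
        for r in (True, False, True):
            s = staircase_update(s, r)
        assert s.step == 1.5 and s.n_reversals == 2

    def test_deterministic_observer_converges_to_threshold(self):
        threshold = 26.0
        s = StaircaseState(level=40.0)
        for _ in range(60):
            s = staircase_update(s, response=s.level > threshold)
        tail = s.history[-20:]
        assert all(abs(l - threshold) <= 2 * s.step + 1e-9 for l in tail)

    def test_reversal_levels_straddle_pse(self, matching_params):
        # martingale check: mean post-convergence reversal level sits within
        # one step of the true 50% point for the symmetric observer
        rng = np.random.default_rng(7)
        obs = matching_params
        pses = []
        for _ in range(20):
            trials = simulate_matching_block(obs, 1.0, 48.0, side="both",
                                             n_trials=50, seed=rng)
            # replay the staircase to harvest reversal levels
            s = StaircaseState(level=float(pct_to_db(48.0)) + 6.0)
            for t in trials:
                s = staircase_update(s, t.response)
            if len(s.reversal_levels) > 4:
                pses.append(np.mean(s.reversal_levels[2:]))
        assert abs(np.mean(pses) - pct_to_db(48.0)) < 1.5  # within one step


class TestSimulateBlock:
    def test_zero_noise_deterministic_choices(self):
        obs = ModelParams(Z=0.3, w=0.09, n=0.0)
        a = simulate_matching_block(obs, 1.0, 48.0, side="both", seed=1)
        b = simulate_matching_block(obs, 1.0, 48.0, side="both", seed=2)
        assert [t.response for t in a] == [t.response for t in b]

    def test_equal_stimuli_choice_rate_half(self, matching_params):
        # pin the staircase at the standard: target == standard every trial
        from binoflick.model import binocular_response
        from scipy.stats import norm

        rng = np.random.default_rng(0)
        p = norm.cdf(0.0)
        assert p == 0.5
        choices = rng.random(10_000) < p
        assert abs(choices.mean() - 0.5) < 0.02

    def test_same_seed_identical_sequence(self, matching_params):
        a = simulate_matching_block(matching_params, 0.5, 24.0, seed=11)
        b = simulate_matching_block(matching_params, 0.5, 24.0, seed=11)
        assert a == b

    def test_target_ratio_respected(self, matching_params):
        trials = simulate_matching_block(matching_params, 0.25, 48.0, side="right", seed=3)
        for t in trials:
            hi = max(t.target_cL, t.target_cR)
            assert t.target_cR == hi
            assert min(t.target_cL, t.target_cR) == pytest.approx(0.25 * hi)


class TestDbConversion:
    @pytest.mark.parametrize("pct", [1.0, 24.0, 48.0, 96.0])
    def test_round_trip_exact(self, pct):
        assert db_to_pct(pct_to_db(pct)) == pytest.approx(pct, rel=1e-12)

    def test_known_values(self):
        assert pct_to_db(100.0) == pytest.approx(40.0)
        assert db_to_pct(0.0) == pytest.approx(1.0)


class TestPsychometricFit:
    def _observer_trials(self, pse_db, slope_db, n, rng):
        from binoflick.matching import MatchingTrial

        levels = rng.uniform(pse_db - 6, pse_db + 6, size=n)
        from scipy.stats import norm

        p = norm.cdf((levels - pse_db) / slope_db)
        resp = rng.random(n) < p
        return [
            MatchingTrial(48.0, float(db_to_pct(l)), float(db_to_pct(l)), 1.0, "both", bool(r))
            for l, r in zip(levels, resp)
        ]

    def test_recovers_pse_within_half_db(self, rng):
        pse = float(pct_to_db(48.0))  # 33.625 dB
        trials = self._observer_trials(pse, 2.0, 150, rng)
        fit = fit_psychometric(trials)
        assert fit.pse == pytest.approx(pse, abs=0.5)
        assert not fit.degenerate

    def test_perfect_separation_flagged(self, rng):
        from binoflick.matching import MatchingTrial

        T = 30.0
        trials = [
            MatchingTrial(48.0, float(db_to_pct(l)), float(db_to_pct(l)), 1.0, "both", l > T)
            for l in rng.uniform(24, 36, size=60)
        ]
        fit = fit_psychometric(trials)
        assert fit.degenerate
        assert abs(fit.pse - T) < 3.0

    def test_all_one_response_degenerate(self, rng):
        from binoflick.matching import MatchingTrial

        trials = [
            MatchingTrial(48.0, float(db_to_pct(l)), float(db_to_pct(l)), 1.0, "both", True)
            for l in rng.uniform(24, 36, size=40)
        ]
        assert fit_psychometric(trials).degenerate

    def test_inverted_coding_rejected(self, rng):
        trials = self._observer_trials(30.0, 1.0, 100, rng)
        flipped = [t.__class__(**{**t.__dict__, "response": not t.response}) for t in trials]
        with pytest.raises(ValueError, match="coding"):
            fit_psychometric(flipped)

    def test_too_few_trials_rejected(self, rng):
        trials = self._observer_trials(30.0, 2.0, 10, rng)
        with pytest.raises(ValueError):
            fit_psychometric(trials)


class TestContourAssembly:
    def _fits_for(self, observer, standard, seed, n_reps=3):
        rng = np.random.default_rng(seed)
        fits = []
        for ratio in RATIOS:
            for side in (("both",) if ratio == 1.0 else ("left", "right")):
                trials = []
                for _ in range(n_reps):
                    trials += simulate_matching_block(observer, ratio, standard,
                                                      side=side, seed=rng)
                fits.append((ratio, side, fit_psychometric(trials)))
        return fits

    def test_geometry_of_special_ratios(self, matching_params):
        contour = assemble_contour(self._fits_for(matching_params, 48.0, 5), 48.0)
        diag = contour[contour.ratio == 1.0]
        assert np.allclose(diag.cL, diag.cR)
        axes = contour[contour.ratio == 0.0]
        assert (axes[["cL", "cR"]].min(axis=1) == 0).all()

    def test_average_sides_collapses_mirror_pairs(self, matching_params):
        contour = assemble_contour(
            self._fits_for(matching_params, 48.0, 5), 48.0, average_sides=True
        )
        for r in (0.0, 0.25, 0.5, 0.75):
            sub = contour[contour.ratio == r]
            assert sub.pse_db.nunique() == 1

    def test_partial_contour_warns(self, matching_params):
        fits = self._fits_for(matching_params, 48.0, 5)[:-1]
        with pytest.warns(UserWarning, match="missing"):
            assemble_contour(fits, 48.0)

    def test_linear_observer_recovers_linear_contour(self):
        # near-linear observer: monocular point lands near (2*standard, 0)
        obs = ModelParams(Z=0.30, w=0.09, n=5.10)
        contour = assemble_contour(self._fits_for(obs, 48.0, 9), 48.0)
        mono = contour[(contour.ratio == 0.0) & (contour.side == "left")].iloc[0]
        assert mono.cL == pytest.approx(2 * 48.0, rel=0.12)

    @staticmethod
    def _radial_sse(contour, pts):
        sse = 0.0
        for row in contour.itertuples():
            for cL, cR in pts:
                hi, lo = max(cL, cR), min(cL, cR)
                ratio = lo / hi if hi else 1.0
                side = "both" if cL == cR else ("left" if cL > cR else "right")
                if abs(ratio - row.ratio) < 1e-9 and (row.ratio == 1.0 or side == row.side):
                    sse += (np.hypot(row.cL, row.cR) - np.hypot(cL, cR)) ** 2
                    break
        return sse

    def test_weak_vs_strong_suppression_orders_canonical_rules(self):
        linear_pts = canonical_contour("linear", 48.0, RATIOS)
        max_pts = canonical_contour("max", 48.0, RATIOS)
        weak = assemble_contour(
            self._fits_for(ModelParams(Z=0.30, w=0.09, n=5.10), 48.0, 13), 48.0
        )
        assert self._radial_sse(weak, linear_pts) < self._radial_sse(weak, max_pts)
        strong = assemble_contour(
            self._fits_for(ModelParams(Z=0.30, w=1.0, n=5.10), 48.0, 13), 48.0
        )
        assert self._radial_sse(strong, max_pts) < self._radial_sse(strong, linear_pts)
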