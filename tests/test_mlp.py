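"""The adaptive maximum-likelihood track.

The incremental likelihood accumulators are checked against a deliberately
naive from-scratch oracle that loops over the full trial history with the
scalar psychometric function.
"""

import math

import numpy as np
import pytest

from sonijnd import (
    Direction,
    MLPConventions,
    PsychometricHypothesis,
    Quadrant,
    TrialRecord,
    best_hypothesis,
    init_grid,
    inverse_psi,
    jnd_estimate,
    psi,
    quadrant_standard,
    run_track,
    select_next_stimulus,
    update_likelihoods,
)
from sonijnd.mlp import TrackAborted, TrackState, snap_to_grid


def make_state(conventions=None, standard=None):
    return TrackState(
        standard=standard or quadrant_standard(Quadrant.I),
        direction=Direction.PLUS_X,
        conventions=conventions or MLPConventions(),
    )


def brute_force_loglik(history, conventions, base=math.e):
    """Oracle: recompute every accumulator from scratch with scalar psi."""
    out = []
    for alpha in conventions.alpha_grid():
        hyp = PsychometricHypothesis(float(alpha), conventions.beta, conventions.gamma)
        total = 0.0
        for tr in history:
            p = psi(tr.delta, hyp)
            total += math.log(p, base) if tr.correct else math.log(1.0 - p, base)
        out.append(total)
    return np.array(out)


def random_history(rng, conventions, n):
    grid = conventions.alpha_grid()
    return [
        TrialRecord(
            n=i + 1,
            delta=float(rng.choice(grid)),
            presentation_order="standard_first",
            correct=bool(rng.integers(2)),
        )
        for i in range(n)
    ]


class TestHypothesisGrid:
    def test_default_grid_is_100_midpoints_from_0001_to_01(self, conventions):
        grid = init_grid(conventions)
        assert len(grid) == 100
        alphas = [h.alpha for h in grid]
        assert alphas[0] == pytest.approx(0.001)
        assert alphas[-1] == pytest.approx(0.1)
        steps = np.diff(alphas)
        assert steps == pytest.approx(np.full(99, 0.001))
        assert all(h.beta == 100.0 and h.gamma == 0.5 for h in grid)

    def test_two_hypotheses_are_the_endpoints(self):
        c = MLPConventions(n_hypotheses=2)
        grid = init_grid(c)
        assert [h.alpha for h in grid] == [c.alpha_min, c.alpha_max]

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            MLPConventions(n_hypotheses=1)


class TestLikelihoodUpdate:
    def test_single_correct_trial_at_sweet_point_probability(self, conventions):
        # choose the delta at which the first hypothesis predicts p = 0.809
        hyp = init_grid(conventions)[0]
        delta = inverse_psi(0.809, hyp)
        state = make_state(conventions)
        update_likelihoods(
            state, TrialRecord(1, delta, "standard_first", correct=True)
        )
        assert state.log10_likelihoods()[0] == pytest.approx(
            math.log10(0.809), abs=1e-6
        )

    def test_all_correct_history_favors_smallest_alpha(self, conventions, rng):
        state = make_state(conventions)
        for i in range(12):
            delta = float(rng.choice(conventions.alpha_grid()))
            update_likelihoods(state, TrialRecord(i + 1, delta, "standard_first", True))
        assert best_hypothesis(state).alpha == conventions.alpha_min
        # oracle agrees
        oracle = brute_force_loglik(state.history, conventions)
        assert int(np.argmax(oracle)) == 0

    def test_empty_history_ties_break_to_smallest_alpha(self, conventions):
        state = make_state(conventions)
        assert np.all(state.log_likelihoods == 0.0)
        assert best_hypothesis(state).alpha == conventions.alpha_min

    @pytest.mark.parametrize("seed", range(5))
    def test_incremental_equals_from_scratch_after_every_trial(self, conventions, seed):
        rng = np.random.default_rng(seed)
        state = make_state(conventions)
        for trial in random_history(rng, conventions, 12):
            update_likelihoods(state, trial)
            oracle = brute_force_loglik(state.history, conventions)
            assert state.log_likelihoods == pytest.approx(oracle, abs=1e-10)

    def test_argmax_invariant_to_log_base(self, conventions, rng):
        history = random_history(rng, conventions, 12)
        nat = brute_force_loglik(history, conventions, base=math.e)
        b10 = brute_force_loglik(history, conventions, base=10)
        assert int(np.argmax(nat)) == int(np.argmax(b10))

    @pytest.mark.parametrize("seed", range(10))
    def test_correct_trial_never_raises_argmax_wrong_never_lowers_it(
        self, conventions, seed
    ):
        rng = np.random.default_rng(100 + seed)
        history = random_history(rng, conventions, rng.integers(1, 10))
        base = int(np.argmax(brute_force_loglik(history, conventions)))
        delta = float(rng.choice(conventions.alpha_grid()))
        plus = history + [TrialRecord(len(history) + 1, delta, "standard_first", True)]
        minus = history + [TrialRecord(len(history) + 1, delta, "standard_first", False)]
        assert int(np.argmax(brute_force_loglik(plus, conventions))) <= base
        assert int(np.argmax(brute_force_loglik(minus, conventions))) >= base


class TestStimulusSelection:
    def test_first_trial_is_the_clearly_audible_initial_offset(self, conventions):
        assert select_next_stimulus(make_state(conventions)) == pytest.approx(0.07)

    def test_sweet_point_rounded_to_grid(self, conventions):
        # force the best hypothesis to alpha = 0.05 with one decisive history
        state = make_state(conventions)
        idx = int(np.argmin(np.abs(conventions.alpha_grid() - 0.05)))
        state.log_likelihoods[idx] = 1.0
        state.history.append(TrialRecord(1, 0.07, "standard_first", True))
        # inverse at p_target is 0.054811 -> nearest grid value 0.055
        assert select_next_stimulus(state) == pytest.approx(0.055)

    def test_sweet_point_clamped_to_grid_ceiling(self, conventions):
        state = make_state(conventions)
        state.log_likelihoods[-1] = 1.0  # best alpha = 0.1 -> inverse 0.104811
        state.history.append(TrialRecord(1, 0.07, "standard_first", False))
        assert select_next_stimulus(state) == pytest.approx(0.1)

    def test_snap_rounds_half_away_from_zero(self, conventions):
        assert snap_to_grid(0.0545, conventions) == pytest.approx(0.055)
        assert snap_to_grid(0.0544, conventions) == pytest.approx(0.054)
        assert snap_to_grid(0.0, conventions) == pytest.approx(0.001)


class TestJNDReadout:
    def _state_with_best_alpha(self, conventions, alpha):
        state = make_state(conventions)
        idx = int(np.argmin(np.abs(conventions.alpha_grid() - alpha)))
        state.log_likelihoods[idx] = 1.0
        for i in range(conventions.n_trials):
            state.history.append(TrialRecord(i + 1, 0.07, "standard_first", True))
        return state

    def test_sweet_point_readout(self, conventions):
        state = self._state_with_best_alpha(conventions, 0.03)
        assert jnd_estimate(state, "sweet_point") == pytest.approx(0.034811, abs=1e-6)

    def test_midpoint_readout(self, conventions):
        state = self._state_with_best_alpha(conventions, 0.03)
        assert jnd_estimate(state, "midpoint") == pytest.approx(0.03)

    def test_midpoint_floor_is_smallest_grid_alpha(self, conventions):
        state = self._state_with_best_alpha(conventions, 0.001)
        assert jnd_estimate(state, "midpoint") == 0.001

    def test_incomplete_track_rejected(self, conventions):
        with pytest.raises(RuntimeError, match="completed"):
            jnd_estimate(make_state(conventions))


class TestRunTrack:
    def test_always_correct_drives_estimate_to_grid_floor(self, standard_I, conventions):
        state, jnd = run_track(
            standard_I, Direction.PLUS_X, lambda delta: True, conventions, seed=0
        )
        assert best_hypothesis(state).alpha == conventions.alpha_min
        assert jnd_estimate(state, "midpoint") == conventions.alpha_min

    def test_always_wrong_drives_estimate_to_grid_ceiling(self, standard_I, conventions):
        state, jnd = run_track(
            standard_I, Direction.PLUS_X, lambda delta: False, conventions, seed=0
        )
        assert best_hypothesis(state).alpha == conventions.alpha_max
        assert jnd == conventions.alpha_max  # sweet point clamps to the ceiling

    def test_runs_exactly_n_trials_on_the_grid(self, standard_I, conventions, rng):
        state, _ = run_track(
            standard_I, Direction.PLUS_X, lambda d: bool(rng.integers(2)),
            conventions, seed=3,
        )
        assert len(state.history) == conventions.n_trials
        grid = conventions.alpha_grid()
        for tr in state.history:
            assert np.min(np.abs(grid - tr.delta)) < 1e-12

    def test_responder_failure_preserves_partial_log(self, standard_I, conventions):
        calls = {"n": 0}

        def flaky(delta):
            calls["n"] += 1
            if calls["n"] == 4:
                raise IOError("listener walked away")
            return True

        with pytest.raises(TrackAborted) as exc:
            run_track(standard_I, Direction.PLUS_X, flaky, conventions, seed=0)
        assert len(exc.value.state.history) == 3
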