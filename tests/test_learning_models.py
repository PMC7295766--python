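"""Belief updating, the 72-variant model grid, trajectories and leak ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfother import fbt_design as fd
from selfother.learning_models import (BeliefState, ModelSpec, ParamSet,
                                       compute_pes, enumerate_model_space,
                                       leak_ratio, run_trajectory,
                                       self_other_correlation, update_beliefs)


def _trial(ttype, outcome=1):
    return fd.Trial(index=0, trial_type=ttype, outcome=outcome)


def _params(alpha=0.1, tau=0.02, delta=0.0, lam=0.0):
    return ParamSet(alpha={(a, c): alpha for a in ("self", "other")
                           for c in ("nonshared", "shared")},
                    tau={"self": tau, "other": tau},
                    delta={"self": delta, "other": delta},
                    lam={"self": lam, "other": lam})


class TestPredictionErrors:
    def test_decoy_zeroes_self_pe(self):
        state = BeliefState(b_self=0.3, b_other=0.4)
        pe_s, pe_o = compute_pes(state, _trial("decoy", 1))
        assert pe_s == 0.0 and pe_o == pytest.approx(0.6)

    def test_privileged_zeroes_other_pe(self):
        state = BeliefState(b_self=0.3, b_other=0.4)
        pe_s, pe_o = compute_pes(state, _trial("privileged", 1))
        assert pe_s == pytest.approx(0.7) and pe_o == 0.0

    def test_matching_belief_gives_zero_error(self):
        state = BeliefState(b_self=1.0, b_other=0.5)
        pe_s, _ = compute_pes(state, _trial("privileged", 1))
        assert pe_s == 0.0

    def test_shared_trial_both_errors(self):
        state = BeliefState(b_self=0.3, b_other=0.8)
        pe_s, pe_o = compute_pes(state, _trial("shared", 1))
        assert pe_s == pytest.approx(0.7)
        assert pe_o == pytest.approx(0.2)


class TestBeliefUpdate:
    def test_identity_when_all_rates_zero(self):
        state = BeliefState(b_self=0.37, b_other=0.81)
        new = update_beliefs(state, _trial("shared", 1), _params(alpha=0.0))
        assert new.b_self == pytest.approx(0.37)
        assert new.b_other == pytest.approx(0.81)

    def test_single_term_update(self):
        state = BeliefState(b_self=0.5, b_other=0.5)
        new = update_beliefs(state, _trial("privileged", 1), _params(alpha=0.1))
        assert new.b_self == pytest.approx(0.55)
        assert new.b_other == pytest.approx(0.5)

    def test_full_update_hand_computed(self):
        # shared trial, outcome 1, b_self=0.6, b_other=0.7:
        # pe_self=0.4, pe_other=0.3
        # b_self' = 0.6 + 0.1*0.4 + 0.1*(0.5-0.6) + 0.05*0.3 = 0.645
        state = BeliefState(b_self=0.6, b_other=0.7)
        new = update_beliefs(state, _trial("shared", 1),
                             _params(alpha=0.1, delta=0.1, lam=0.05))
        assert new.b_self == pytest.approx(0.645)
        # b_other' = 0.7 + 0.1*0.3 + 0.1*(-0.2) + 0.05*0.4 = 0.73
        assert new.b_other == pytest.approx(0.73)

    def test_mirrored_update_for_other(self):
        state = BeliefState(b_self=0.5, b_other=0.5)
        new = update_beliefs(state, _trial("decoy", 1),
                             _params(alpha=0.2, lam=0.1))
        assert new.b_other == pytest.approx(0.6)    # own alpha term
        assert new.b_self == pytest.approx(0.55)    # leak of pe_other

    def test_shared_trial_uses_shared_alpha(self):
        params = ParamSet(
            alpha={("self", "nonshared"): 0.1, ("self", "shared"): 0.3,
                   ("other", "nonshared"): 0.1, ("other", "shared"): 0.3},
            tau={"self": 0.02, "other": 0.02})
        state = BeliefState(b_self=0.5, b_other=0.5)
        new = update_beliefs(state, _trial("shared", 1), params)
        assert new.b_self == pytest.approx(0.65)

    @settings(max_examples=200, deadline=None)
    @given(alpha=st.floats(0, 1), delta=st.floats(0, 1), lam=st.floats(0, 1),
           b_s=st.floats(0, 1), b_o=st.floats(0, 1),
           outcome=st.integers(0, 1),
           ttype=st.sampled_from(["privileged", "shared", "decoy"]))
    def test_beliefs_stay_in_unit_interval(self, alpha, delta, lam, b_s, b_o,
                                           outcome, ttype):
        state = BeliefState(b_self=b_s, b_other=b_o)
        new = update_beliefs(state, _trial(ttype, outcome),
                             _params(alpha=alpha, delta=delta, lam=lam))
        assert 0.0 <= new.b_self <= 1.0
        assert 0.0 <= new.b_other <= 1.0


class TestModelSpace:
    def test_seventy_two_variants(self):
        specs = enumerate_model_space()
        assert len(specs) == 72
        assert len({s.id for s in specs}) == 72

    def test_bijection_onto_structure_grid(self):
        keys = {(s.alpha_structure, s.tau_structure, s.n_delta, s.n_lambda)
                for s in enumerate_model_space()}
        assert len(keys) == 4 * 2 * 3 * 3

    def test_minimum_free_parameters(self):
        assert min(s.n_params for s in enumerate_model_space()) == 2

    def test_parameter_count_example(self):
        spec = ModelSpec("by_both", "by_agent", 2, 1)
        assert spec.n_params == 4 + 2 + 2 + 1

    def test_spec_json_round_trip(self):
        spec = ModelSpec("by_agent", "single", 1, 2, id="M42")
        assert ModelSpec.from_json(spec.to_json()) == spec


class TestTrajectory:
    def test_empty_sequence(self):
        w = fd.RandomWalk(np.array([0.5]), 0.025)
        seq = fd.TrialSequence([], w, w)
        assert run_trajectory(seq, _params()) == []

    def test_matches_stepwise_replay(self, short_seq):
        params = _params(alpha=0.15, delta=0.05, lam=0.08)
        traj = run_trajectory(short_seq, params)
        state = BeliefState()
        for trial, got in zip(short_seq.trials, traj):
            state = update_beliefs(state, trial, params)
            assert state.b_self == pytest.approx(got.b_self)
            assert state.b_other == pytest.approx(got.b_other)

    def test_no_leak_self_ignores_decoys(self):
        # two sequences differing only in decoy outcomes give the same b_self
        w = fd.RandomWalk(np.full(20, 0.5), 0.025)
        sched = ["privileged", "decoy"] * 10
        base = fd.assign_outcomes(sched, w, w, seed=0)
        flipped = fd.TrialSequence(
            [fd.Trial(t.index, t.trial_type,
                      1 - t.outcome if t.trial_type == "decoy" else t.outcome)
             for t in base.trials], w, w)
        t1 = run_trajectory(base, _params(lam=0.0))
        t2 = run_trajectory(flipped, _params(lam=0.0))
        assert [s.b_self for s in t1] == pytest.approx([s.b_self for s in t2])


class TestSelfOtherCorrelation:
    def test_identical_beliefs(self):
        traj = [BeliefState(b_self=b, b_other=b)
                for b in np.linspace(0.1, 0.9, 40)]
        np.testing.assert_allclose(self_other_correlation(traj, 4), 1.0)

    def test_single_bin_whole_trajectory(self, short_seq):
        traj = run_trajectory(short_seq, _params(alpha=0.2))
        r = self_other_correlation(traj, 1)
        bs = [s.b_self for s in traj]
        bo = [s.b_other for s in traj]
        assert r[0] == pytest.approx(np.corrcoef(bs, bo)[0, 1])

    def test_zero_variance_bin_flagged(self):
        traj = [BeliefState(b_self=0.5, b_other=b)
                for b in np.linspace(0.2, 0.8, 10)]
        assert np.isnan(self_other_correlation(traj, 1)[0])

    def test_invalid_bins(self, short_seq):
        traj = run_trajectory(short_seq, _params())
        with pytest.raises(ValueError):
            self_other_correlation(traj, 0)
        with pytest.raises(ValueError):
            self_other_correlation(traj[:5], 3)

    def test_leak_increases_merging(self):
        """Mean Self-Other belief correlation rises monotonically with
        the leak (within the leak < learning-rate regime)."""
        spec = ModelSpec("single", "single", 0, 1)
        seqs = [fd.generate_sequence("hi_share", "train", seed=200 + s)
                for s in range(6)]
        means = []
        for lam in (0.0, 0.03, 0.06, 0.09):
            vals = {"alpha": 0.15, "tau": 0.02, "lambda": lam}
            rs = [np.nanmean(self_other_correlation(
                run_trajectory(sq, ParamSet.from_values(spec, vals)), 4))
                for sq in seqs]
            means.append(np.mean(rs))
        assert np.all(np.diff(means) > 0)

    def test_no_leak_uncoupled_streams_centre_on_zero(self):
        """Without shared trials or leak, Self and Other beliefs track
        independent walks: correlations centre on zero across draws."""
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            wa = fd.generate_random_walk(300, seed=rng)
            wb = fd.generate_random_walk(300, seed=rng)
            sched = list(rng.permutation(["privileged"] * 150 + ["decoy"] * 150))
            seq = fd.assign_outcomes(sched, wa, wb, rng)
            traj = run_trajectory(seq, _params(alpha=0.15))
            rs.append(self_other_correlation(traj, 1)[0])
        assert abs(np.mean(rs)) < 0.15


class TestLeakRatio:
    def test_zero_leak(self):
        spec = ModelSpec("single", "single", 0, 1)
        params = ParamSet.from_values(
            spec, {"alpha": 0.1, "tau": 0.02, "lambda": 0.0})
        assert leak_ratio(params, spec)["mean"] == 0.0

    def test_simple_ratio(self):
        spec = ModelSpec("single", "single", 0, 1)
        params = ParamSet.from_values(
            spec, {"alpha": 0.1, "tau": 0.02, "lambda": 0.05})
        assert leak_ratio(params, spec)["self"] == pytest.approx(0.5)

    def test_split_alpha_averaged(self):
        spec = ModelSpec("by_trial_class", "single", 0, 1)
        params = ParamSet.from_values(
            spec, {"alpha_nonshared": 0.1, "alpha_shared": 0.3,
                   "tau": 0.02, "lambda": 0.1})
        assert leak_ratio(params, spec)["self"] == pytest.approx(0.5)

    def test_error_without_leak(self):
        spec = ModelSpec("single", "single", 0, 0)
        params = ParamSet.from_values(spec, {"alpha": 0.1, "tau": 0.02})
        with pytest.raises(ValueError):
            leak_ratio(params, spec)
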