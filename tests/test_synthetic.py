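"""Generators: per-bin samplers, frame-level MCMC, outcomes, effects."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dfftcourt import (CourtGrid, OutcomeLink, TruthSpec, assign_outcomes,
                       default_truth, inject_player_effect,
                       inside_three_point_arc, sample_frames, sample_states)
from dfftcourt.synthetic import MCMCOptions, _CourtSampler

FAST_MCMC = MCMCOptions(burn_in=150, thin=4, play_gap=5)


def point_mass_truth(grid):
    f = np.full((20, 20), 50.0)
    f[2, 3] = 0.0
    return TruthSpec(grid, 5.0, 20, f, np.zeros(100), np.zeros(100))


class TestSampleStates:
    def test_seeded_reproducibility(self):
        truth = default_truth()
        s1 = sample_states(truth, 50, seed=9)
        s2 = sample_states(truth, 50, seed=9)
        assert all(np.array_equal(a.n_o, b.n_o) and np.array_equal(a.n_d, b.n_d)
                   for a, b in zip(s1, s2))

    def test_point_mass_truth_gives_constant_states(self, grid):
        states = sample_states(point_mass_truth(grid), 20, seed=1)
        for s in states:
            assert np.all(s.n_o == 2) and np.all(s.n_d == 3)

    def test_uniform_truth_frequencies_within_multinomial_error(self, grid):
        """Empirical per-state frequencies match a uniform truth within a
        3-sigma multinomial band."""
        truth = TruthSpec(grid, 5.0, 4, np.zeros((4, 4)), np.zeros(100),
                          np.zeros(100))
        n = 30_000
        states = sample_states(truth, n, seed=2)
        codes = np.stack([s.n_o[0] * 4 + s.n_d[0] for s in states])
        counts = np.bincount(codes, minlength=16)
        p = 1 / 16
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3.5 * sigma)

    def test_matches_truth_marginals(self):
        truth = default_truth()
        states = sample_states(truth, 4000, seed=3)
        n_o = np.stack([s.n_o for s in states])
        model_means = np.einsum("blm,l->b", truth.model().prob_table(),
                                np.arange(20.))
        assert np.corrcoef(n_o.mean(axis=0), model_means)[0, 1] > 0.99


class TestSampleFrames:
    def test_seeded_reproducibility(self):
        truth = default_truth()
        t1 = sample_frames(truth, 5, 2, mcmc=FAST_MCMC, seed=4)
        t2 = sample_frames(truth, 5, 2, mcmc=FAST_MCMC, seed=4)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_flat_truth_occupancy_near_uniform(self, grid):
        flat = TruthSpec(grid, 5.0, 20, np.zeros((20, 20)), np.zeros(100),
                         np.zeros(100), ball_attraction=0.0, p_onball=0.0)
        tab = sample_frames(flat, 120, 2, mcmc=FAST_MCMC, seed=5)
        pos = tab.df[tab.df.object_class != "ball"][["x", "y"]].to_numpy()
        H, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=4,
                                 range=[[-25, 25], [0, 50]])
        expect = len(pos) / 16
        assert H.min() > 0.5 * expect
        assert H.max() < 1.7 * expect

    def test_single_bin_attraction_dominates_occupancy(self, grid):
        v_o = np.zeros(100)
        v_o[44] = -2.0  # strong offensive preference for one bin
        truth = TruthSpec(grid, 5.0, 20, default_truth().f, v_o,
                          np.zeros(100), ball_attraction=0.0)
        tab = sample_frames(truth, 150, 2, mcmc=FAST_MCMC, seed=6)
        off = tab.df[tab.df.object_class == "offense"]
        b = CourtGrid().bin_index(off.x.to_numpy(), off.y.to_numpy())
        counts = np.bincount(b, minlength=100)
        assert counts.argmax() == 44

    def test_frames_valid_and_ball_follows_carrier(self):
        truth = replace(default_truth(), p_onball=1.0)
        tab = sample_frames(truth, 30, 2, mcmc=FAST_MCMC, seed=7)
        for fr in tab.frames():
            d = np.linalg.norm(fr.offense - fr.ball, axis=1).min()
            assert d < 1e-9  # carried ball sits on an offensive agent

    def test_energy_stationarity_across_thinned_samples(self, grid):
        """Detailed-balance smoke test: the energy of thinned samples has no
        drift between the first and second half of the chain."""
        truth = default_truth()
        tab = sample_frames(truth, 240, 1, mcmc=FAST_MCMC, seed=8)
        rng = np.random.default_rng(0)
        sampler = _CourtSampler(truth, FAST_MCMC, rng)
        energies = []
        for fr in tab.frames():
            pos = np.vstack([fr.offense, fr.defense])
            mass = np.stack([sampler._agent_mass(p) for p in pos])
            sampler.ball = fr.ball
            sampler.carrier = None
            energies.append(sampler._energy(pos, mass))
        # consecutive plays are autocorrelated: compare halves on the scale
        # of 20-play block means
        blocks = np.asarray(energies)[:240].reshape(12, 20).mean(axis=1)
        a, b = blocks[:6], blocks[6:]
        se = np.sqrt(a.var(ddof=1) / 6 + b.var(ddof=1) / 6)
        assert abs(a.mean() - b.mean()) < 4 * se


@pytest.fixture(scope="module")
def outcome_table():
    truth = default_truth()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sample_frames(truth, 150, 2, mcmc=FAST_MCMC, seed=9)


class TestAssignOutcomes:

    def test_zero_slope_matches_base_rate(self, outcome_table):
        link = OutcomeLink(intercept=0.0, slope_pct=0.0)
        out, scores = assign_outcomes(outcome_table, link, seed=1, return_scores=True)
        rate = (scores.outcome > 0).mean()
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / len(scores))

    def test_success_monotone_in_score(self):
        truth = default_truth()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = sample_frames(truth, 400, 1, mcmc=FAST_MCMC, seed=10)
        link = OutcomeLink(slope_pct=8.0)  # steep link for a sharp signal
        _, scores = assign_outcomes(tab, link, seed=2, return_scores=True)
        med = scores.score.median()
        hi = (scores.outcome > 0)[scores.score > med].mean()
        lo = (scores.outcome > 0)[scores.score <= med].mean()
        assert hi > lo

    def test_outcome_r_mapping_respects_arc(self, outcome_table):
        link = OutcomeLink(intercept=50.0)  # force success
        out, scores = assign_outcomes(outcome_table, link, seed=3, return_scores=True)
        for fr in out.frames():
            if fr.t_to_shot == 0.0:
                expected = 2 if inside_three_point_arc(*fr.ball) else 3
                assert fr.outcome == expected

    def test_seeded_reproducibility(self, outcome_table):
        a = assign_outcomes(outcome_table, seed=4).df
        b = assign_outcomes(outcome_table, seed=4).df
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_constant_within_play(self, outcome_table):
        out = assign_outcomes(outcome_table, seed=5)
        assert (out.df.groupby("play_id")["outcome"].nunique() == 1).all()


class TestPlayerEffects:
    def test_magnitude_zero_is_null_twin(self, grid, rng):
        base = default_truth()
        t_null = inject_player_effect(base, "null_twin", 0.0, agent=0)
        t_mag0 = inject_player_effect(base, "magnet", 0.0, agent=0)
        s1 = _CourtSampler(t_null, FAST_MCMC, np.random.default_rng(1))
        s2 = _CourtSampler(t_mag0, FAST_MCMC, np.random.default_rng(1))
        pos = np.column_stack([rng.uniform(-20, 20, 10),
                               rng.uniform(5, 45, 10)])
        mass = np.stack([s1._agent_mass(p) for p in pos])
        s1.ball = s2.ball = np.array([0.0, 30.0])
        s1.carrier = s2.carrier = None
        assert s1._energy(pos, mass) == pytest.approx(s2._energy(pos, mass))

    def test_effects_compose_additively_in_energy(self, grid, rng):
        base = default_truth()
        t1 = inject_player_effect(base, "magnet", 1.0, agent=0)
        t2 = inject_player_effect(t1, "tether", 2.0, agent=0, buddy=1)
        pos = np.column_stack([rng.uniform(-20, 20, 10),
                               rng.uniform(5, 45, 10)])
        ball = np.array([0.0, 30.0])

        def energy(truth):
            s = _CourtSampler(truth, FAST_MCMC, np.random.default_rng(1))
            mass = np.stack([s._agent_mass(p) for p in pos])
            s.ball, s.carrier = ball, None
            return s._energy(pos, mass)

        e_base = energy(base)
        e_mag = energy(t1)
        e_both = energy(t2)
        d_tether = -2.0 * np.exp(-((pos[0] - pos[1]) ** 2).sum() / 50)
        assert e_both - e_mag == pytest.approx(d_tether)
        d_mag = -1.0 * np.exp(
            -((pos[5:] - pos[0]) ** 2).sum(axis=1).min() / 50)
        assert e_mag - e_base == pytest.approx(d_mag)

    def test_magnet_raises_local_defense_near_flagged_agent(self):
        """Monte-Carlo contrast: defenders crowd the magnet player."""
        base = inject_player_effect(default_truth(), "null_twin", 0.0)
        mag = inject_player_effect(default_truth(), "magnet", 3.0, agent=0)

        def mean_local_defense(truth, seed):
            tab = sample_frames(truth, 250, 1, mcmc=FAST_MCMC, seed=seed)
            vals = []
            for fr in tab.frames():
                d = np.linalg.norm(fr.defense - fr.offense[0], axis=1)
                vals.append((d < 7.5).sum())
            return np.mean(vals)

        assert (mean_local_defense(mag, 11)
                > mean_local_defense(base, 11) + 0.15)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown effect"):
            inject_player_effect(default_truth(), "wormhole", 1.0)
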