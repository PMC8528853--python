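"""Bayesian decoding, weighted correlation, shuffle scoring and PCC."""

import numpy as np
import pytest

from ensemblelat import replay as rp, synth
from ensemblelat.types import DecodingTemplate, PosteriorMatrix, RippleEvent, UnitSpikeTrain


def _template(rates, tau=0.020, track=150.0):
    rates = np.asarray(rates, float)
    n_pos = rates.shape[1]
    centers = (np.arange(n_pos) + 0.5) * track / n_pos
    return DecodingTemplate(unit_ids=np.arange(rates.shape[0]), rates=rates,
                            bin_centers=centers, direction=1, tau=tau)


def _unit(uid, times):
    return UnitSpikeTrain(uid, "L", np.asarray(times, float))


def _one_hot_posterior(peak_bins, n_pos=20, tau=0.020, bin_cm=1.0):
    pr = np.zeros((n_pos, len(peak_bins)))
    for i, p in enumerate(peak_bins):
        pr[p, i] = 1.0
    centers = (np.arange(n_pos) + 0.5) * bin_cm
    times = tau * (np.arange(len(peak_bins)) + 0.5)
    return PosteriorMatrix(Pr=pr, bin_times=times, bin_centers_cm=centers)


class TestCandidateSelection:
    units = [_unit(i, [10.02 + 0.01 * i]) for i in range(6)]

    def _ripple(self, dur_ms, n_active):
        ev = RippleEvent(hemisphere="L", t_start=10.0, t_stop=10.0 + dur_ms / 1e3,
                         t_peak=10.01)
        return ev, self.units[:n_active]

    def test_short_ripple_excluded(self):
        ev, units = self._ripple(40.0, 6)
        assert rp.select_candidate_events([ev], units) == []

    def test_too_few_active_cells_excluded(self):
        ev, units = self._ripple(100.0, 4)
        assert rp.select_candidate_events([ev], units) == []

    def test_qualifying_event_kept(self):
        ev, units = self._ripple(100.0, 6)
        out = rp.select_candidate_events([ev], units)
        assert len(out) == 1 and len(out[0].active_unit_ids) == 6


class TestBayesianDecode:
    def test_flat_templates_give_uniform_posterior(self):
        tmpl = _template(np.full((4, 10), 3.0))
        units = [_unit(i, [0.005 + 0.001 * i]) for i in range(4)]
        post = rp.bayesian_decode((0.0, 0.1), units, tmpl)
        np.testing.assert_allclose(post.Pr, 0.1, atol=1e-12)

    def test_two_position_likelihood_oracle(self):
        # f1 = (10, .01), f2 = (.01, 10); two spikes from cell 1 in one bin
        tmpl = _template([[10.0, 0.01], [0.01, 10.0]])
        units = [_unit(0, [0.001, 0.005]), _unit(1, [])]
        post = rp.bayesian_decode((0.0, 0.02), units, tmpl)
        tau = 0.02
        raw = np.array([10.0 ** 2 * np.exp(-tau * (10.0 + 0.01)),
                        0.01 ** 2 * np.exp(-tau * (0.01 + 10.0))])
        np.testing.assert_allclose(post.Pr[:, 0], raw / raw.sum(), rtol=1e-9)
        assert np.argmax(post.Pr[:, 0]) == 0

    def test_zero_spike_bin_follows_summed_rate(self):
        rates = np.array([[5.0, 0.5, 5.0], [5.0, 0.5, 5.0]])
        tmpl = _template(rates)
        post = rp.bayesian_decode((0.0, 0.02), [_unit(0, []), _unit(1, [])], tmpl)
        assert np.argmax(post.Pr[:, 0]) == 1  # minimal summed rate

    def test_columns_sum_to_one_even_under_shuffles(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0, 10, size=(8, 30))
        tmpl = _template(rates)
        units = [_unit(i, np.sort(rng.uniform(0, 0.1, 3))) for i in range(8)]
        counts, _ = rp._bin_counts((0.0, 0.1), units, tmpl)
        shifts = rng.integers(0, 30, size=(50, 8))
        fb = rp._shuffled_rates(tmpl.floored_rates(), shifts)
        pr = rp._posterior_batch(counts, fb, tmpl.tau)
        np.testing.assert_allclose(pr.sum(axis=2), 1.0, atol=1e-9)


class TestWeightedCorrelation:
    def test_perfect_diagonal_scores_one(self):
        post = _one_hot_posterior([2, 5, 8, 11, 14])
        assert rp.weighted_correlation(post) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_posterior_scores_zero(self):
        pr = np.full((10, 6), 0.1)
        post = PosteriorMatrix(Pr=pr, bin_times=np.arange(6) * 0.02,
                               bin_centers_cm=np.arange(10) + 0.5)
        assert rp.weighted_correlation(post) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_matches_pearson_oracle(self):
        rng = np.random.default_rng(1)
        peaks = rng.integers(0, 20, size=12)
        post = _one_hot_posterior(peaks.tolist())
        r = rp.weighted_correlation(post)
        oracle = np.corrcoef(np.arange(12), post.bin_centers_cm[peaks])[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_single_bin_raises(self):
        with pytest.raises(ValueError):
            rp.weighted_correlation(_one_hot_posterior([3]))


class TestMonteCarloP:
    @pytest.mark.parametrize("n,S,expected", [
        (0, 1000, 1 / 1001), (1000, 1000, 1.0), (49, 1000, 50 / 1001),
        (9, 200, 10 / 201),
    ])
    def test_formula(self, n, S, expected):
        assert rp.monte_carlo_p(n, S) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rp.monte_carlo_p(-1, 100)
        with pytest.raises(ValueError):
            rp.monte_carlo_p(101, 100)


class TestDirectionSelection:
    def _score(self, p, r, d):
        return dict(p_mc=p, r=r, direction=d)

    def test_smaller_p_wins_and_is_significant(self):
        chosen, sig = rp.pick_direction_and_significance(
            [self._score(0.03, 0.5, 1), self._score(0.20, 0.6, -1)])
        assert chosen["direction"] == 1 and sig

    def test_winner_above_alpha_not_significant(self):
        chosen, sig = rp.pick_direction_and_significance(
            [self._score(0.08, 0.5, 1), self._score(0.06, 0.4, -1)])
        assert chosen["direction"] == -1 and not sig

    def test_p_tie_broken_by_larger_abs_r(self):
        chosen, sig = rp.pick_direction_and_significance(
            [self._score(0.049, 0.7, 1), self._score(0.049, -0.5, -1)])
        assert chosen["direction"] == 1 and sig


class TestKinematics:
    def test_advancing_peaks_arithmetic(self):
        # peaks advance 3 cm per 20 ms bin over 5 bins
        post = _one_hot_posterior([10, 13, 16, 19, 22], n_pos=30, bin_cm=1.0)
        out = rp.replay_kinematics(post, tau=0.020)
        assert out["distance_cm"] == pytest.approx(12.0)
        assert out["mean_jump_cm"] == pytest.approx(3.0)
        assert out["speed_m_s"] == pytest.approx(0.12 / 0.1)

    def test_constant_peak_gives_zero_motion(self):
        post = _one_hot_posterior([7, 7, 7, 7])
        out = rp.replay_kinematics(post)
        assert out["distance_cm"] == 0.0
        assert out["speed_m_s"] == 0.0
        assert out["mean_jump_cm"] == 0.0


class TestSequenceScore:
    def test_rz_is_zscore_of_abs_r_against_null(self):
        rng = np.random.default_rng(2)
        rates = rng.uniform(0, 8, size=(10, 40))
        tmpl = _template(rates)
        units = [_unit(i, np.sort(rng.uniform(0, 0.12, 3))) for i in range(10)]
        s = rp.sequence_score_rz((0.0, 0.12), units, tmpl, n_shuffles=100, seed=0)
        assert s["rz"] == pytest.approx(
            (abs(s["r"]) - s["null_abs_mean"]) / s["null_abs_sd"], rel=1e-9)
        assert s["p_mc"] == pytest.approx((s["n_exceed"] + 1) / 101)

    def test_decoding_equivariant_under_joint_circular_shift(self):
        rng = np.random.default_rng(3)
        # mid-track fields so a small shift causes no wrap-around
        rates = np.array([8.0 * np.exp(-0.5 * ((np.arange(40) - c) / 2.0) ** 2)
                          for c in (12, 15, 18, 21, 24)])
        tmpl = _template(rates)
        units = [_unit(i, [0.01 + 0.02 * i]) for i in range(5)]
        p0 = rp.bayesian_decode((0.0, 0.1), units, tmpl)
        shifted = _template(np.roll(rates, 5, axis=1))
        p1 = rp.bayesian_decode((0.0, 0.1), units, shifted)
        # the posterior shifts rigidly (circularly) with the templates ...
        np.testing.assert_allclose(p1.Pr, np.roll(p0.Pr, 5, axis=0), atol=1e-12)
        # ... and r is preserved up to the small wrapped-mass relabelling
        # (position labels are linear, so wrapped tail mass moves ends)
        assert rp.weighted_correlation(p1) == pytest.approx(
            rp.weighted_correlation(p0), abs=0.01)

    def test_true_sequences_score_high_and_null_events_low(self):
        rng = np.random.default_rng(4)
        rates = np.array([10.0 * np.exp(-0.5 * ((np.arange(50) - c) / 2.5) ** 2)
                          for c in range(5, 45, 4)])
        tmpl = _template(rates)
        # sequence event: each cell fires when the trajectory crosses its field
        seq_units = [_unit(i, [0.01 + 0.02 * i, 0.012 + 0.02 * i]) for i in range(10)]
        s_seq = rp.sequence_score_rz((0.0, 0.2), seq_units, tmpl, n_shuffles=200, seed=1)
        assert s_seq["rz"] > 2 and s_seq["p_mc"] < 0.05
        # structureless event: same cells, scrambled spike times
        null_units = [_unit(i, np.sort(rng.uniform(0, 0.2, 2))) for i in range(10)]
        s_null = rp.sequence_score_rz((0.0, 0.2), null_units, tmpl, n_shuffles=200, seed=2)
        assert s_null["p_mc"] > 0.05


class TestPerCellContribution:
    def test_flat_template_cell_contributes_zero(self):
        rng = np.random.default_rng(5)
        rates = np.array([8.0 * np.exp(-0.5 * ((np.arange(40) - c) / 2.0) ** 2)
                          for c in (8, 14, 20, 26, 32)] + [np.full(40, 2.0)])
        tmpl = _template(rates)
        units = [_unit(i, [0.01 + 0.02 * i, 0.013 + 0.02 * i]) for i in range(5)]
        units.append(_unit(5, [0.03, 0.07]))  # flat-template cell
        s = rp.sequence_score_rz((0.0, 0.1), units, tmpl, n_shuffles=100, seed=0)
        out = rp.per_cell_contribution((0.0, 0.1), units, tmpl, s,
                                       n_shuffles=50, seed=0)
        # circular shifts leave a flat template identical -> rZ unchanged
        assert out["pcc"][5] == pytest.approx(0.0, abs=1e-9)

    def test_pcc_scales_linearly_with_participant_count(self):
        assert rp.pcc_from_delta(0.7, 10) == pytest.approx(2 * rp.pcc_from_delta(0.7, 5))

    def test_planted_carrier_cell_dominates(self):
        probe = synth.make_pcc_probe_event(seed=3)
        s = rp.sequence_score_rz(probe["window"], probe["units"], probe["template"],
                                 n_shuffles=100, seed=0)
        out = rp.per_cell_contribution(probe["window"], probe["units"],
                                       probe["template"], s, n_shuffles=100, seed=0)
        top = max(out["pcc"], key=out["pcc"].get)
        assert top == probe["carrier_id"]


class TestLateralizedComparison:
    def test_single_hemisphere_population_flags_empty_opposite_arm(self):
        rng = np.random.default_rng(6)
        rates = np.array([10.0 * np.exp(-0.5 * ((np.arange(50) - c) / 2.5) ** 2)
                          for c in range(5, 45, 4)])
        tmpl = _template(rates)
        templates = {1: tmpl, -1: tmpl}
        units = [_unit(i, np.sort(np.r_[0.01 + 0.02 * i, 10.01 + 0.02 * i]))
                 for i in range(10)]
        rip_ev = [RippleEvent(hemisphere="L", t_start=0.0, t_stop=0.2, t_peak=0.1)]
        rep = rp.lateralized_replay_comparisons(rip_ev, units, templates,
                                                n_shuffles=50, seed=0,
                                                compute_pcc=False)
        assert rep["opposite_arm_empty"]
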