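"""Heaviside threshold machinery, expected value, validity, psychophysics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import webforage as wf
from webforage.task import Offer, SessionConfig, TrialRecord
from webforage.thresholds import heaviside, threshold_candidates

from conftest import make_agent


def brute_force_threshold(delays, choices, delay_min=3, delay_max=30):
    """Independent oracle: plain-Python exhaustive SSE minimization over
    the candidate set, with the same tied-span midpoint rule."""
    delays = list(map(float, delays))
    choices = list(map(float, choices))
    if all(c == 1 for c in choices):
        return max(delays)
    if all(c == 0 for c in choices):
        return min(delays)
    uniq = sorted(set(delays))
    cands = {float(delay_min), float(delay_max)}
    for a, b in zip(uniq, uniq[1:]):
        cands.add((a + b) / 2)
    cands = sorted(cands)
    sses = []
    for t in cands:
        sse = 0.0
        for d, c in zip(delays, choices):
            if d < t:
                pred = 1.0
            elif d > t:
                pred = 0.0
            else:
                pred = 0.5
            sse += (c - pred) ** 2
        sses.append(sse)
    best = min(sses)
    tied = [t for t, s in zip(cands, sses) if abs(s - best) < 1e-12]
    return (tied[0] + tied[-1]) / 2


class TestHeaviside:
    def test_step_primitive_values(self):
        assert heaviside(0.0) == 0.5
        assert heaviside(-3.0) == 0.0
        assert heaviside(2.0) == 1.0


class TestFitHeavisideThreshold:
    def test_all_stays_return_maximal_offered_delay(self):
        assert wf.fit_heaviside_threshold([4, 9, 22], [1, 1, 1]) == 22

    def test_all_skips_return_minimal_offered_delay(self):
        assert wf.fit_heaviside_threshold([4, 9, 22], [0, 0, 0]) == 4

    def test_clean_switch_returns_boundary_midpoint(self):
        t = wf.fit_heaviside_threshold([4, 6, 8, 10, 12], [1, 1, 1, 0, 0])
        assert t == 9  # midpoint of last stay (8) and first skip (10)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            wf.fit_heaviside_threshold([], [])

    def test_non_binary_choices_rejected(self):
        with pytest.raises(ValueError):
            wf.fit_heaviside_threshold([5, 6], [1, 2])

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.tuples(st.integers(3, 30), st.integers(0, 1)),
                    min_size=1, max_size=12))
    def test_matches_brute_force_oracle(self, pairs):
        delays = [p[0] for p in pairs]
        choices = [p[1] for p in pairs]
        got = wf.fit_heaviside_threshold(delays, choices)
        assert got == pytest.approx(brute_force_threshold(delays, choices))


class TestLooThresholds:
    def test_redundant_point_exclusion_keeps_threshold(self):
        # duplicated delays make every trial redundant: removing any one
        # leaves the candidate set and the optimal step location intact
        delays = [5, 5, 7, 7, 15, 15, 17, 17]
        choices = [1, 1, 1, 1, 0, 0, 0, 0]
        vec = wf.loo_threshold_vector(delays, choices)
        full = wf.fit_heaviside_threshold(delays, choices)
        assert np.allclose(vec, full)

    def test_vector_equals_brute_force_refits(self):
        rng = np.random.default_rng(2)
        delays = rng.integers(3, 31, size=12)
        choices = (rng.random(12) < 0.5).astype(int)
        vec = wf.loo_threshold_vector(delays, choices)
        for i in range(12):
            keep = [j for j in range(12) if j != i]
            expect = brute_force_threshold(delays[keep], choices[keep])
            assert vec[i] == pytest.approx(expect)

    def test_all_stay_gallery_yields_max_offered(self):
        vec = wf.loo_threshold_vector([5, 9, 13], [1, 1, 1])
        assert vec.tolist() == [13, 13, 9]  # leaving out 13 leaves max 9

    def test_single_trial_gallery_is_an_error(self):
        with pytest.raises(ValueError):
            wf.loo_threshold_vector([10], [1])


def _session_records(pattern):
    """Build a tiny session from (gallery, low, mid, high, choice) tuples."""
    recs = []
    for i, (g, lo, mi, hi, choice) in enumerate(pattern):
        offer = Offer(g, lo, mi, hi)
        if choice == "stay":
            realized = mi
            cls = "mid" if offer.is_risky else "nonrisk"
            recs.append(TrialRecord("s0", i, offer, "stay", realized, cls, 2,
                                    1.0, float(i) * 10, float(i) * 10 + 5))
        else:
            recs.append(TrialRecord("s0", i, offer, "skip", None, None, None,
                                    1.0, float(i) * 10, float(i) * 10 + 5))
    return recs


class TestAssignTrialThresholds:
    def test_nonrisky_trials_get_gallery_mean_of_loo_vector(self):
        recs = _session_records([
            ("kittens", 6, 8, 10, "stay"),
            ("kittens", 10, 12, 14, "stay"),
            ("kittens", 16, 18, 20, "skip"),
            ("kittens", 9, 9, 9, "stay"),
        ])
        ts = wf.assign_trial_thresholds(recs)
        vec = ts.loo["kittens"]
        assert len(vec) == 3  # one per risky trial
        assert ts.threshold_for_trial(3) == pytest.approx(vec.mean())

    def test_gallery_without_risky_trials_is_flagged(self):
        recs = _session_records([
            ("kittens", 9, 9, 9, "stay"),
            ("kittens", 20, 20, 20, "skip"),
            ("dance", 6, 8, 10, "stay"),
            ("dance", 14, 16, 18, "skip"),
        ])
        ts = wf.assign_trial_thresholds(recs)
        assert "kittens" in ts.flagged_galleries
        assert np.isnan(ts.threshold_for_trial(0))

    def test_four_galleries_yield_four_subject_thresholds(self, small_study,
                                                          small_thresholds):
        for sid, ts in small_thresholds.items():
            finite = [v for v in ts.gallery_mean.values() if np.isfinite(v)]
            assert len(finite) == 4
            for v in finite:
                assert 3 <= v <= 30


class TestExpectedValue:
    def test_threshold_minus_mean_delay(self):
        assert wf.expected_value(Offer("g", 5, 10, 15), 20.0) == 10.0

    def test_offer_at_threshold_has_zero_value(self):
        assert wf.expected_value(Offer("g", 12, 12, 12), 12.0) == 0.0

    def test_global_minimum(self):
        assert wf.expected_value(Offer("g", 30, 30, 30), 3.0) == -27.0

    def test_depends_only_on_mean_of_delays(self):
        # same mean, different spreads -> same EV
        assert (wf.expected_value(Offer("g", 5, 10, 15), 20.0)
                == wf.expected_value(Offer("g", 8, 10, 12), 20.0))

    def test_missing_threshold_is_an_error(self):
        with pytest.raises(ValueError):
            wf.expected_value(Offer("g", 5, 10, 15), float("nan"))


class TestValidityCorrelations:
    def test_proportional_ratings_give_perfect_correlation(self):
        r_rat, r_rank, flags = wf.validity_correlations(
            [10, 14, 18, 22], [1.0, 1.4, 1.8, 2.2], [4, 3, 2, 1])
        assert r_rat == pytest.approx(1.0)
        assert r_rank == pytest.approx(1.0)  # rank 1 = most preferred
        assert flags == []

    def test_constant_thresholds_flagged_absent(self):
        r_rat, r_rank, flags = wf.validity_correlations(
            [15, 15, 15, 15], [1, 2, 3, 4], [4, 3, 2, 1])
        assert r_rat is None and r_rank is None
        assert set(flags) == {"ratings", "rankings"}


class TestPsychophysics:
    def test_noise_free_step_agents_give_a_perfect_step(self):
        rows = []
        for sid in ("a", "b"):
            for aligned in (-5, -3, -1, 1, 3, 5):
                rows.append({"subject_id": sid, "is_risky": False,
                             "mid": 15 + aligned, "assigned_threshold": 15.0,
                             "stay": int(aligned < 0)})
        curve = wf.psychophysics_curve(pd.DataFrame(rows),
                                       align_range=(-27.5, 27.5))
        non = curve[curve.condition == "nonrisky"].dropna(subset=["mean_stay"])
        assert (non[non.bin < 0].mean_stay == 1.0).all()
        assert (non[non.bin > 0].mean_stay == 0.0).all()

    def test_profile_values_are_proportions(self, small_frame):
        curve = wf.psychophysics_curve(
            small_frame[["subject_id", "is_risky", "mid", "threshold", "stay"]]
            .rename(columns={"threshold": "assigned_threshold"}))
        vals = curve.mean_stay.dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_logistic_agents_cross_half_at_threshold(self):
        # generative logistic midpoint: stay proportion in the aligned
        # bin at zero should sit near 0.5 for beta = 0.5 agents
        pop = wf.PopulationConfig(n_subjects=30, beta_mean=0.5, beta_sd=0.0)
        study = wf.simulate_study(pop, seed=3, with_esi=False,
                                  with_discounting=False)
        sets = wf.compute_thresholds(study)
        from webforage.framing import study_frame
        frame = study_frame(study.sessions, sets)
        curve = wf.psychophysics_curve(
            frame[["subject_id", "is_risky", "mid", "threshold", "stay"]]
            .rename(columns={"threshold": "assigned_threshold"}),
            align_range=(-27.5, 27.5))
        at_zero = curve[(curve.bin == 0.0)].mean_stay.mean()
        assert abs(at_zero - 0.5) < 0.05


class TestEvExtremes:
    def test_exhaustive_range_on_integer_grid(self):
        lo, hi = wf.ev_extremes(3, 30)
        assert (lo, hi) == (-27.0, 27.0)
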