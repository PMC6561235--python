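"""Outcome framing, sequential datasets, mixed models, BH, matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import webforage as wf
from webforage.framing import (ModelResult, bh_adjust, build_matched_subsets,
                               coef, fit_mixed_model,
                               prepare_sequential_dataset, run_model_suite)
from webforage.task import BAD, GOOD, MID, NONE, NONRISK, Offer, TrialRecord


def _trial(offer, choice, realized=None, cls=None, rating=2, idx=0):
    return TrialRecord("s0", idx, offer, choice, realized, cls,
                       rating if choice == "stay" else None, 1.0, 0.0, 5.0)


class TestClassifyOutcome:
    def test_low_delay_is_good(self):
        t = _trial(Offer("g", 5, 10, 15), "stay", 5, GOOD)
        assert wf.classify_outcome(t) == GOOD

    def test_nonrisky_stay(self):
        t = _trial(Offer("g", 7, 7, 7), "stay", 7, NONRISK)
        assert wf.classify_outcome(t) == NONRISK

    def test_skip_has_no_outcome(self):
        t = _trial(Offer("g", 5, 10, 15), "skip")
        assert wf.classify_outcome(t) == NONE

    def test_classification_uses_position_not_value(self):
        # the same realized delay is bad in one offer, good in another
        bad = _trial(Offer("g", 5, 10, 15), "stay", 15, BAD)
        good = _trial(Offer("g", 15, 20, 25), "stay", 15, GOOD)
        assert wf.classify_outcome(bad) == BAD
        assert wf.classify_outcome(good) == GOOD

    def test_foreign_delay_is_a_data_error(self):
        t = _trial(Offer("g", 5, 10, 15), "stay", 10, MID)
        t.realized_delay = 11  # corrupt after construction
        with pytest.raises(ValueError):
            wf.classify_outcome(t)


class TestPrepareSequentialDataset:
    def test_centering_identity(self, small_frame):
        centered = small_frame.dropna(subset=["rating_centered"])
        means = centered.groupby(["subject_id", "gallery"])["rating_centered"].mean()
        assert np.allclose(means, 0.0, atol=1e-9)

    def test_videos_consumed_counts_prior_stays(self, small_frame):
        for _, sub in small_frame.groupby("subject_id"):
            expect = sub.stay.cumsum().shift(1, fill_value=0)
            assert (sub.videos_consumed.values == expect.values).all()
            assert (np.diff(sub.videos_consumed.values) >= 0).all()

    def test_choice_dataset_requires_consecutive_risky_structure(self, small_frame):
        d = prepare_sequential_dataset(small_frame, "choice")
        assert d.is_risky.all()
        assert (d.prev_stay == 1).all()

    def test_no_consecutive_risky_pairs_gives_empty_dataset(self):
        # alternating risky/non-risky with skips: no previous-stay + risky pairs
        rows = []
        for i in range(10):
            risky = i % 2 == 0
            offer = Offer("g", 5, 10, 15) if risky else Offer("g", 8, 8, 8)
            rows.append({
                "subject_id": "s0", "trial_index": i, "gallery": "g",
                "low": offer.low, "mid": offer.mid, "high": offer.high,
                "is_risky": risky, "spread": offer.spread,
                "stay": 0, "realized_delay": None, "outcome_class": NONE,
                "rating": None, "decision_rt": 1.0, "threshold": 12.0,
                "expected_value": 2.0, "actual_value": np.nan,
                "videos_consumed": 0, "rating_centered": np.nan,
            })
        d = prepare_sequential_dataset(pd.DataFrame(rows), "choice")
        assert d.empty


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_ps_stay_equal(self):
        assert np.allclose(bh_adjust([0.05, 0.05, 0.05]), 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.random(rng.integers(1, 12))
            expect = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expect, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(18)
        p = rng.random(30)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestMatchedSubsets:
    def _dataset(self, subject_rows):
        rows = []
        for sid, cls, v in subject_rows:
            rows.append({"subject_id": sid, "prev_class": cls, "prev_value": v,
                         "stay": 1})
        return pd.DataFrame(rows)

    def test_greedy_trace_example(self):
        d = self._dataset([("s0", BAD, 2.0), ("s0", BAD, 5.0),
                           ("s0", GOOD, 2.2), ("s0", GOOD, 9.0)])
        m = build_matched_subsets(d, "bad_vs_good")
        assert len(m) == 2  # one pair: bad 2.0 <-> good 2.2
        assert sorted(m.prev_value) == [2.0, 2.2]
        assert m.pair_id.nunique() == 1

    def test_identical_value_multisets_fully_match(self):
        vals = [1.0, 3.0, 7.5]
        d = self._dataset([("s0", BAD, v) for v in vals]
                          + [("s0", GOOD, v) for v in vals])
        m = build_matched_subsets(d, "bad_vs_good")
        assert len(m) == 6

    def test_zero_tolerance_disjoint_values_match_nothing(self):
        d = self._dataset([("s0", BAD, 1.0), ("s0", GOOD, 2.0)])
        m = build_matched_subsets(d, "bad_vs_good", tolerance=0.0)
        assert m.empty

    def test_pairs_are_value_balanced_by_construction(self, small_frame):
        d = prepare_sequential_dataset(small_frame, "choice")
        d = d[d.prev_is_risky.astype(bool)]
        m = build_matched_subsets(d, "bad_vs_good", tolerance=0.5)
        if m.empty:
            pytest.skip("no matches in this tiny fixture")
        gaps = m.groupby("pair_id").prev_value.agg(np.ptp)
        assert (gaps <= 0.5 + 1e-9).all()


def simulate_glmm(n_subj, rows_per_subj, bad_coef, seed,
                  sigma_u=0.5, value_coef=0.02):
    """Direct simulation from the analysis model family (logistic with a
    per-subject random intercept): the clean recovery oracle."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, sigma_u)
        for _ in range(rows_per_subj):
            v = rng.normal(0, 6)
            cls = rng.choice([GOOD, MID, BAD])
            lin = 0.2 + value_coef * v + bad_coef * (cls == BAD) + u
            rows.append({"subject_id": f"s{s}", "prev_value": v,
                         "prev_class": cls,
                         "stay": int(rng.random() < expit(lin))})
    return pd.DataFrame(rows)


class TestFitMixedModel:
    FORMULA = "stay ~ prev_value + C(prev_class, Treatment('good'))"

    def test_null_framing_effect_centers_on_zero(self):
        ests = []
        for rep in range(20):
            d = simulate_glmm(40, 25, 0.0, seed=100 + rep)
            res = fit_mixed_model(d, self.FORMULA, "binary")
            ests.append(coef(res, "[T.bad]").estimate)
        ests = np.array(ests)
        assert abs(ests.mean()) < 2 * ests.std(ddof=1) / np.sqrt(len(ests))

    def test_true_effect_covered_by_intervals(self):
        covered = 0
        for rep in range(20):
            d = simulate_glmm(40, 25, -0.6, seed=200 + rep)
            res = fit_mixed_model(d, self.FORMULA, "binary")
            row = coef(res, "[T.bad]")
            covered += row.ci_lo <= -0.6 <= row.ci_hi
        assert covered >= 0.8 * 20

    def test_single_subject_grouping_is_an_error(self):
        d = simulate_glmm(1, 40, 0.0, seed=1)
        with pytest.raises(ValueError):
            fit_mixed_model(d, self.FORMULA, "binary")

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError):
            fit_mixed_model(pd.DataFrame(), "stay ~ prev_value", "binary")

    def test_continuous_backend_recovers_linear_effect(self):
        rng = np.random.default_rng(9)
        rows = []
        for s in range(30):
            u = rng.normal(0, 0.3)
            for _ in range(40):
                v = rng.normal(0, 5)
                y = 0.1 + 0.05 * v + u + rng.normal(0, 1)
                rows.append({"subject_id": f"s{s}", "v": v, "y": y})
        d = pd.DataFrame(rows)
        res = fit_mixed_model(d, "y ~ v", "continuous")
        row = coef(res, "v")
        assert row.ci_lo <= 0.05 <= row.ci_hi


@pytest.fixture(scope="module")
def suite(small_frame):
    return run_model_suite(small_frame)


class TestModelSuite:
    def test_all_families_attempted(self, suite):
        expected = {"choice_primary", "rating_primary", "rt", "global_choice",
                    "global_rating", "control", "secondary"}
        produced = {k for k, v in suite.items() if isinstance(v, ModelResult)}
        missing = expected - produced - set(suite["skipped"])
        assert not missing

    def test_fdr_never_decreases_p(self, suite):
        for name, res in suite.items():
            if not isinstance(res, ModelResult):
                continue
            t = res.table.dropna(subset=["p_adj"])
            assert (t.p_adj >= t.p - 1e-12).all(), name

    def test_intervals_contain_estimates(self, suite):
        for name, res in suite.items():
            if not isinstance(res, ModelResult):
                continue
            t = res.table.dropna(subset=["estimate", "ci_lo", "ci_hi"])
            assert ((t.ci_lo <= t.estimate) & (t.estimate <= t.ci_hi)).all(), name


class TestControlModelInvariance:
    def test_framing_sign_survives_consumption_controls(self):
        # data generated without consumption confounds: adding consumption
        # and risk-spread covariates must not flip the framing sign
        pop = wf.PopulationConfig(n_subjects=40, gamma0=-0.8, gamma_E=0.0,
                                  eta=0.0)
        study = wf.simulate_study(pop, seed=61, with_esi=False,
                                  with_discounting=False)
        sets = wf.compute_thresholds(study)
        from webforage.framing import study_frame
        frame = study_frame(study.sessions, sets)
        ch = prepare_sequential_dataset(frame, "choice")
        chp = ch[ch.prev_is_risky.astype(bool)
                 & ch.prev_class.isin([GOOD, MID, BAD])]
        primary = fit_mixed_model(
            chp, "stay ~ prev_value + C(prev_class, Treatment('good'))",
            "binary")
        control = fit_mixed_model(
            chp, "stay ~ prev_value + C(prev_class, Treatment('good'))"
                 " + videos_consumed + spread", "binary")
        b1 = coef(primary, "[T.bad]").estimate
        b2 = coef(control, "[T.bad]").estimate
        assert b1 < 0 and b2 < 0
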