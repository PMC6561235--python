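"""Revealed-preference delay thresholds.

A subject's threshold for a gallery is the delay at which stay choices
reliably turn into skips. It is estimated by fitting a Heaviside step
function to (presented delay, choice) pairs: the fitted step location
minimizes the sum of squared residuals between the 0/1 choices and the
step predictor 1 - H(delay - T). Unlike a logistic fit, the step fit
returns a sensible boundary value (the minimal or maximal delay
offered) when a subject stayed or skipped everything in a gallery.

Per-trial thresholds are leave-one-out: the threshold attached to risky
trial i is fitted on all other risky trials of the gallery (risky
trials are represented by their mid delay), so no trial influences its
own covariate. Non-risky trials inherit the gallery mean of the LOO
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import Offer, TrialRecord


def heaviside(x):
    """H(x): 0 below zero, 1/2 at zero, 1 above zero."""
    return np.heaviside(np.asarray(x, dtype=float), 0.5)


def _step_sse(delays: np.ndarray, choices: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    pred = 1.0 - heaviside(delays[None, :] - candidates[:, None])
    resid = choices[None, :] - pred
    return (resid ** 2).sum(axis=1)


def threshold_candidates(delays: np.ndarray, delay_min: float, delay_max: float) -> np.ndarray:
    u = np.unique(delays)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate(([delay_min], mids, [delay_max])))


def fit_heaviside_threshold(
    delays: Sequence[float],
    choices: Sequence[int],
    delay_min: float = 3,
    delay_max: float = 30,
) -> float:
    """Fit the step location T to (delay, choice) pairs.

    choices: 1 = stay, 0 = skip. The SSE is minimized over the candidate
    set {delay_min, midpoints of adjacent unique delays, delay_max};
    when several candidates tie, the midpoint of the tied span is
    returned. All-stay data return the maximal offered delay, all-skip
    the minimal (the step estimator's graceful extremes).
    """
    delays = np.asarray(delays, dtype=float)
    choices = np.asarray(choices, dtype=float)
    if delays.size == 0:
        raise ValueError("no trials to fit")
    if not np.isin(choices, (0.0, 1.0)).all():
        raise ValueError("choices must be coded 0 (skip) / 1 (stay)")
    if choices.all():
        return float(delays.max())
    if not choices.any():
        return float(delays.min())
    cand = threshold_candidates(delays, delay_min, delay_max)
    sse = _step_sse(delays, choices, cand)
    best = np.flatnonzero(np.isclose(sse, sse.min()))
    return float((cand[best[0]] + cand[best[-1]]) / 2.0)


def loo_threshold_vector(
    delays: Sequence[float],
    choices: Sequence[int],
    delay_min: float = 3,
    delay_max: float = 30,
) -> np.ndarray:
    """One threshold per trial, each fitted with that trial left out."""
    delays = np.asarray(delays, dtype=float)
    choices = np.asarray(choices, dtype=float)
    n = delays.size
    if n < 2:
        raise ValueError("leave-one-out thresholds need at least 2 trials")
    keep = ~np.eye(n, dtype=bool)
    return np.array([
        fit_heaviside_threshold(delays[keep[i]], choices[keep[i]], delay_min, delay_max)
        for i in range(n)
    ])


def expected_value(offer: Offer, threshold: float) -> float:
    """EV = threshold - mean offered delay (equal outcome likelihoods).

    Positive EV means the offer is better than the subject's revealed
    price; for delays and thresholds in [3, 30] s it spans [-27, 27].
    """
    if threshold is None or not np.isfinite(threshold):
        raise ValueError("expected value requires an assigned threshold")
    return float(threshold - offer.mean_delay)


def ev_extremes(delay_min: int = 3, delay_max: int = 30) -> tuple[float, float]:
    """Exhaustive EV range over integer thresholds and non-risky delays."""
    thresholds = np.arange(delay_min, delay_max + 1, dtype=float)
    delays = np.arange(delay_min, delay_max + 1, dtype=float)
    ev = thresholds[:, None] - delays[None, :]
    return float(ev.min()), float(ev.max())


@dataclass
class ThresholdSet:
    """Per-gallery LOO threshold vectors plus per-trial assignments."""

    subject_id: str
    loo: dict                       # gallery -> np.ndarray of LOO thresholds
    gallery_mean: dict              # gallery -> float or nan (flagged)
    per_trial: pd.DataFrame         # trial_index, gallery, assigned_threshold, expected_value
    flagged_galleries: list = field(default_factory=list)

    def threshold_for_trial(self, trial_index: int) -> float:
        row = self.per_trial.loc[self.per_trial.trial_index == trial_index]
        return float(row.assigned_threshold.iloc[0]) if len(row) else float("nan")


def assign_trial_thresholds(
    records: Sequence[TrialRecord],
    delay_min: float = 3,
    delay_max: float = 30,
    include_nonrisky_in_fit: bool = False,
) -> ThresholdSet:
    """Build the full ThresholdSet for one subject's session.

    Risky trial i receives its own LOO threshold; non-risky trials
    receive the gallery mean of the LOO vector. Galleries with fewer
    than two fit trials are flagged and their thresholds left absent.
    By default only risky trials (via their mid delay) enter the step
    fits; `include_nonrisky_in_fit` widens the fit to all trials.
    """
    if not records:
        raise ValueError("empty session")
    subject = records[0].subject_id
    galleries = sorted({r.offer.gallery for r in records})
    loo: dict = {}
    gmean: dict = {}
    flagged: list = []
    assigned = {}
    for g in galleries:
        trials = [r for r in records if r.offer.gallery == g]
        if include_nonrisky_in_fit:
            fit_trials = trials
        else:
            fit_trials = [r for r in trials if r.offer.is_risky]
        delays = np.array([r.offer.mid for r in fit_trials], dtype=float)
        stays = np.array([1.0 if r.choice == "stay" else 0.0 for r in fit_trials])
        if len(fit_trials) < 2:
            loo[g] = np.array([])
            gmean[g] = float("nan")
            flagged.append(g)
            continue
        vec = loo_threshold_vector(delays, stays, delay_min, delay_max)
        loo[g] = vec
        gmean[g] = float(vec.mean())
        for r, t in zip(fit_trials, vec):
            assigned[r.trial_index] = float(t)
    rows = []
    for r in records:
        t = assigned.get(r.trial_index, gmean[r.offer.gallery])
        ev = (expected_value(r.offer, t)
              if t is not None and np.isfinite(t) else float("nan"))
        rows.append({
            "trial_index": r.trial_index,
            "gallery": r.offer.gallery,
            "assigned_threshold": t,
            "expected_value": ev,
        })
    return ThresholdSet(
        subject_id=subject,
        loo=loo,
        gallery_mean=gmean,
        per_trial=pd.DataFrame(rows),
        flagged_galleries=flagged,
    )


def validity_correlations(
    thresholds: Sequence[float],
    mean_ratings: Sequence[float],
    rankings: Sequence[float],
) -> tuple[Optional[float], Optional[float], list]:
    """External validity: thresholds vs stated preferences over galleries.

    Rankings are reverse-coded (rank 1 = most preferred) before
    correlating so a positive r means choice/report consistency.
    Zero-variance inputs yield an absent correlation plus a flag.
    """
    t = np.asarray(thresholds, dtype=float)
    ratings = np.asarray(mean_ratings, dtype=float)
    ranks = -np.asarray(rankings, dtype=float)
    flags = []

    def _corr(a, b, label):
        if np.std(a) == 0 or np.std(b) == 0 or np.isnan(a).any() or np.isnan(b).any():
            flags.append(label)
            return None
        return float(np.corrcoef(a, b)[0, 1])

    return _corr(t, ratings, "ratings"), _corr(t, ranks, "rankings"), flags


def psychophysics_curve(
    trials: pd.DataFrame,
    bin_width: float = 1.0,
    align_range: tuple[float, float] = (-27.0, 27.0),
) -> pd.DataFrame:
    """Stay proportion aligned to threshold, averaged within then across
    subjects, separately for risky and non-risky trials.

    `trials` needs columns subject_id, is_risky, mid, assigned_threshold,
    stay (0/1). Empty bins are absent (NaN), never zero.
    """
    df = trials.dropna(subset=["assigned_threshold"]).copy()
    df["aligned"] = df["mid"] - df["assigned_threshold"]
    edges = np.arange(align_range[0], align_range[1] + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    df["bin"] = pd.cut(df["aligned"], edges, labels=centers)
    out = []
    for risky, sub in df.groupby("is_risky"):
        per_subj = (sub.groupby(["subject_id", "bin"], observed=False)["stay"]
                    .mean().reset_index())
        agg = per_subj.groupby("bin", observed=False)["stay"].agg(["mean", "count"])
        for b, row in agg.iterrows():
            out.append({
                "bin": float(b),
                "condition": "risky" if risky else "nonrisky",
                "mean_stay": row["mean"] if row["count"] > 0 else float("nan"),
                "n_subjects": int(row["count"]),
            })
    return pd.DataFrame(out)


__all__ = [
    "heaviside", "fit_heaviside_threshold", "loo_threshold_vector",
    "threshold_candidates", "expected_value", "ev_extremes",
    "ThresholdSet", "assign_trial_thresholds",
    "validity_correlations", "psychophysics_curve",
]
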