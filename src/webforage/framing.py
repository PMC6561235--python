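"""Outcome framing and the sequential regression-model suite.

A realized delay on a risky trial is framed by its *position* within
the offer — good (low delay), bad (high delay), or mid — never by its
economic value. The model suite asks how these framings shape the next
choice, the current rating, and reaction times, at the group level,
with follow-up value-matched contrasts, global consumption trends, a
confound-control model, and an integrated choice-by-rating model.
All fixed-effect p-values within a model are FDR-adjusted by the
Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import BAD, GOOD, MID, NONE, NONRISK, TrialRecord
from .thresholds import ThresholdSet


def classify_outcome(trial: TrialRecord) -> str:
    """Frame a trial's outcome: good/mid/bad on risky stays (by the
    realized delay's position in the offer), nonrisk on non-risky
    stays, none on skips."""
    if trial.choice == "skip":
        return NONE
    if trial.realized_delay not in trial.offer.delays:
        raise ValueError(
            f"realized delay {trial.realized_delay} not in offer {trial.offer.delays}")
    if not trial.offer.is_risky:
        return NONRISK
    if trial.realized_delay == trial.offer.low:
        return GOOD
    if trial.realized_delay == trial.offer.high:
        return BAD
    return MID


def session_frame(records: Sequence[TrialRecord], thrset: ThresholdSet) -> pd.DataFrame:
    """Tidy per-trial table for one subject, joining assigned thresholds.

    Adds actual value (threshold - realized delay, stays only), EV,
    gallery-mean-centered ratings, and the running count of videos
    consumed before each trial.
    """
    thr = thrset.per_trial.set_index("trial_index")
    rows = []
    consumed = 0
    for r in records:
        t = thr.loc[r.trial_index, "assigned_threshold"]
        stay = r.choice == "stay"
        rows.append({
            "subject_id": r.subject_id,
            "trial_index": r.trial_index,
            "gallery": r.offer.gallery,
            "low": r.offer.low, "mid": r.offer.mid, "high": r.offer.high,
            "is_risky": r.offer.is_risky,
            "spread": r.offer.spread,
            "stay": int(stay),
            "realized_delay": r.realized_delay,
            "outcome_class": r.outcome_class,
            "rating": r.rating,
            "decision_rt": r.decision_rt,
            "threshold": t,
            "expected_value": thr.loc[r.trial_index, "expected_value"],
            "actual_value": (t - r.realized_delay) if stay and np.isfinite(t) else np.nan,
            "videos_consumed": consumed,
        })
        if stay:
            consumed += 1
    df = pd.DataFrame(rows)
    centered = df.groupby("gallery")["rating"].transform(lambda s: s - s.mean())
    df["rating_centered"] = centered
    return df


def study_frame(sessions: dict, threshold_sets: dict) -> pd.DataFrame:
    """Concatenate session frames across subjects."""
    return pd.concat(
        [session_frame(recs, threshold_sets[sid]) for sid, recs in sessions.items()],
        ignore_index=True,
    )


def _lagged(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("outcome_class", "actual_value", "rating_centered", "is_risky", "stay"):
        out[f"prev_{col}"] = out.groupby("subject_id")[col].shift(1)
    # lag structure requires consecutive encounters within a subject
    prev_idx = out.groupby("subject_id")["trial_index"].shift(1)
    out = out[prev_idx.notna() & (out["trial_index"] == prev_idx + 1)]
    return out


def prepare_sequential_dataset(frame: pd.DataFrame, target: str) -> pd.DataFrame:
    """Row filters for each model family.

    target:
      'choice'        previous stay, current risky (primary model further
                      restricts to previous *risky* stays via prev_is_risky)
      'rating'        risky stays (current-trial framing)
      'rating_lagged' stays following a previous stay (lag-1 framing, used
                      by the matched rating follow-ups)
      'rt'            trials following a risky stay
      'global_choice' all trials with an assigned threshold
      'global_rating' all stay trials
      'secondary'     previous stay of class good/bad/nonrisk, current risky
    """
    if target == "choice":
        d = _lagged(frame)
        d = d[(d.prev_stay == 1) & d.is_risky & d.prev_actual_value.notna()]
        return d.rename(columns={"prev_outcome_class": "prev_class",
                                 "prev_actual_value": "prev_value"})
    if target == "rating":
        d = frame[(frame.stay == 1) & frame.is_risky].copy()
        d = d[d.actual_value.notna()]
        d["value"] = d.actual_value
        return d
    if target == "rating_lagged":
        d = _lagged(frame)
        d = d[(d.stay == 1) & (d.prev_stay == 1) & d.prev_actual_value.notna()]
        return d.rename(columns={"prev_outcome_class": "prev_class",
                                 "prev_actual_value": "prev_value"})
    if target == "rt":
        d = _lagged(frame)
        d = d[(d.prev_stay == 1) & d.prev_is_risky.astype(bool)
              & d.prev_actual_value.notna()]
        d = d.rename(columns={"prev_outcome_class": "prev_class",
                              "prev_actual_value": "prev_value"})
        d["log_rt"] = np.log(d.decision_rt)
        return d
    if target == "global_choice":
        return frame[frame.expected_value.notna()].copy()
    if target == "global_rating":
        return frame[(frame.stay == 1) & frame.expected_value.notna()].copy()
    if target == "secondary":
        d = _lagged(frame)
        d = d[(d.prev_stay == 1) & d.is_risky
              & d.prev_outcome_class.isin([GOOD, BAD, NONRISK])
              & d.prev_actual_value.notna()]
        return d.rename(columns={"prev_outcome_class": "prev_class",
                                 "prev_actual_value": "prev_value",
                                 "prev_rating_centered": "prev_rating"})
    raise ValueError(f"unknown target {target!r}")


# --------------------------------------------------------------------------
# Mixed-effects fitting

_GLMER_SCRIPT = r"""
suppressMessages(library(lme4))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1], check.names = FALSE)
fixed <- setdiff(colnames(d), c("y", "subject", "slopevar"))
rhs <- paste(sprintf("`%s`", fixed), collapse = " + ")
re <- "(1|subject)"
if ("slopevar" %in% colnames(d)) re <- paste(re, "+ (0 + slopevar|subject)")
f <- as.formula(paste("y ~ 0 +", rhs, "+", re))
m <- glmer(f, data = d, family = binomial,
           control = glmerControl(optimizer = "bobyqa"))
s <- summary(m)$coefficients
out <- data.frame(term = rownames(s), estimate = s[, 1], se = s[, 2], p = s[, 4])
write.csv(out, args[2], row.names = FALSE)
"""


def _fit_glmer(data: pd.DataFrame, formula: str, group: str,
               random_slope: Optional[str]):
    """Logistic mixed model through lme4's glmer (Rscript subprocess).

    The patsy design matrix is exported with positional column names so
    treatment coding and interactions survive the round trip; terms map
    back by position.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    import patsy

    lhs, rhs = (s.strip() for s in formula.split("~", 1))
    X = patsy.dmatrix(rhs, data, return_type="dataframe")
    names = list(X.columns)
    export = X.set_axis([f"x{i}" for i in range(len(names))], axis=1)
    export["y"] = np.asarray(data[lhs], dtype=int)
    export["subject"] = data[group].astype(str).values
    if random_slope:
        export["slopevar"] = np.asarray(data[random_slope], dtype=float)
    with tempfile.TemporaryDirectory() as td:
        dpath, opath = Path(td, "d.csv"), Path(td, "o.csv")
        spath = Path(td, "fit.R")
        export.to_csv(dpath, index=False)
        spath.write_text(_GLMER_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(spath), str(dpath), str(opath)],
            capture_output=True, text=True, timeout=600)
        if proc.returncode != 0 or not opath.exists():
            raise RuntimeError(f"glmer failed: {proc.stderr[-400:]}")
        out = pd.read_csv(opath)
        notes = [line for line in proc.stderr.splitlines()
                 if "converge" in line.lower()]
    order = {f"`x{i}`": i for i in range(len(names))}
    order.update({f"x{i}": i for i in range(len(names))})
    out["idx"] = out["term"].map(order)
    out = out.sort_values("idx")
    return ([names[i] for i in out["idx"]], out["estimate"].values,
            out["se"].values, out["p"].values, notes)


@dataclass
class ModelResult:
    """Fitted fixed effects in the printed-table layout."""

    name: str
    table: pd.DataFrame            # term, estimate, ci_lo, ci_hi, p, p_adj
    n_obs: int
    n_subjects: int
    converged: bool = True
    backend: str = ""
    notes: list = field(default_factory=list)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1, and restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def fit_mixed_model(
    data: pd.DataFrame,
    formula: str,
    outcome_kind: str,
    group: str = "subject_id",
    random_slope: Optional[str] = None,
    name: str = "model",
) -> ModelResult:
    """Fit one mixed-effects model and return its coefficient table.

    Binary outcomes use a logit link with a per-subject random
    intercept (plus an independent random slope component when
    requested), fit by maximum likelihood through lme4's glmer with
    Wald p-values; when R is unavailable the statsmodels Laplace (MAP)
    approximation stands in and is recorded in `backend`. Continuous outcomes use a
    linear mixed model (REML) with a correlated random intercept/slope
    when a slope is requested. Non-convergence and separation are
    flagged, never silently returned.
    """
    if data.empty:
        raise ValueError(f"{name}: empty dataset")
    n_subj = data[group].nunique()
    if n_subj < 2:
        raise ValueError(f"{name}: needs at least two subjects")
    notes: list = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if outcome_kind == "binary":
            try:
                names, est, sd, p, gl_notes = _fit_glmer(
                    data, formula, group, random_slope)
                notes.extend(gl_notes)
                backend = "lme4 glmer (ML, Wald)"
            except (RuntimeError, OSError, FileNotFoundError) as exc:
                notes.append(f"glmer unavailable ({exc}); Laplace fallback")
                from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

                vc = {"subject": f"0 + C({group})"}
                if random_slope:
                    vc["subject_slope"] = f"0 + C({group}):{random_slope}"
                model = BinomialBayesMixedGLM.from_formula(formula, vc, data)
                fit = model.fit_map()
                names = list(fit.model.exog_names)
                est = np.asarray(fit.fe_mean)
                sd = np.asarray(fit.fe_sd)
                z = np.divide(est, sd, out=np.zeros_like(est), where=sd > 0)
                p = 2 * stats.norm.sf(np.abs(z))
                backend = "statsmodels BinomialBayesMixedGLM (Laplace/MAP)"
            if not np.all(np.isfinite(est)) or np.any(np.abs(est) > 20):
                converged = False
                notes.append("suspected separation or divergence")
            lo, hi = est - 1.96 * sd, est + 1.96 * sd
        elif outcome_kind == "continuous":
            import statsmodels.formula.api as smf

            re_formula = f"1 + {random_slope}" if random_slope else "1"
            model = smf.mixedlm(formula, data, groups=data[group], re_formula=re_formula)
            fit = model.fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
            fe = fit.fe_params
            names = list(fe.index)
            est = fe.values
            ci = fit.conf_int().loc[names]
            lo, hi = ci[0].values, ci[1].values
            p = fit.pvalues.loc[names].values
            backend = "statsmodels MixedLM (REML)"
        else:
            raise ValueError("outcome_kind must be 'binary' or 'continuous'")
        # warnings become diagnostics; the converged flag reflects actual
        # evidence (divergent estimates, or the optimizer's own verdict)
        for w in caught:
            msg = str(w.message)
            if any(k in msg for k in ("onverge", "Singular", "singular", "boundary")):
                notes.append(msg)
    table = pd.DataFrame({
        "term": names, "estimate": est, "ci_lo": lo, "ci_hi": hi, "p": p,
    })
    nonint = table.term != "Intercept"
    table["p_adj"] = np.nan
    table.loc[nonint, "p_adj"] = bh_adjust(table.loc[nonint, "p"].values)
    return ModelResult(name=name, table=table, n_obs=len(data),
                       n_subjects=n_subj, converged=converged,
                       backend=backend, notes=notes)


def coef(result: ModelResult, pattern: str) -> pd.Series:
    """First coefficient row whose term contains `pattern`."""
    hit = result.table[result.table.term.str.contains(pattern, regex=False)]
    if hit.empty:
        raise KeyError(f"{result.name}: no term matching {pattern!r}")
    return hit.iloc[0]


# --------------------------------------------------------------------------
# Value-matched follow-up subsets

def build_matched_subsets(
    dataset: pd.DataFrame,
    contrast: str,
    value_col: str = "prev_value",
    class_col: str = "prev_class",
    tolerance: float = 0.5,
) -> pd.DataFrame:
    """Greedy per-subject matching of bad-outcome trials to comparison
    trials of near-identical actual value (within +/- `tolerance` s).

    contrast: 'bad_vs_good' or 'bad_vs_nonrisk'. Each bad trial is
    paired with the nearest unused comparison trial; unmatched trials
    are dropped. Pair ids are recorded in `pair_id`.
    """
    comparison = {"bad_vs_good": GOOD, "bad_vs_nonrisk": NONRISK}[contrast]
    pieces = []
    pair_id = 0
    for _, sub in dataset.groupby("subject_id"):
        bads = sub[sub[class_col] == BAD].sort_values(value_col)
        comps = sub[sub[class_col] == comparison].sort_values(value_col)
        used = np.zeros(len(comps), dtype=bool)
        cvals = comps[value_col].values
        for _, brow in bads.iterrows():
            if not len(cvals):
                break
            dist = np.abs(cvals - brow[value_col])
            dist[used] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= tolerance:
                used[j] = True
                b = brow.copy(); b["pair_id"] = pair_id
                c = comps.iloc[j].copy(); c["pair_id"] = pair_id
                pieces.append(pd.DataFrame([b, c]))
                pair_id += 1
    if not pieces:
        return dataset.iloc[0:0].assign(pair_id=pd.Series(dtype=int))
    return pd.concat(pieces, ignore_index=True)


# --------------------------------------------------------------------------
# The full suite

def simple_slopes(
    dataset: pd.DataFrame,
    outcome: str,
    value_col: str,
    class_col: str,
    outcome_kind: str,
    name: str,
) -> ModelResult:
    """Within-class association of value with the outcome (one mixed
    fit per outcome class), reported alongside the interaction terms."""
    rows = []
    for cls, sub in dataset.groupby(class_col):
        if sub["subject_id"].nunique() < 2 or len(sub) < 10:
            continue
        try:
            res = fit_mixed_model(
                sub, f"{outcome} ~ {value_col}", outcome_kind,
                name=f"{name}[{cls}]")
            row = coef(res, value_col).copy()
            row["term"] = f"value slope | {cls}"
            rows.append(row)
        except Exception as exc:  # degenerate class subset: report, don't fail
            rows.append(pd.Series({"term": f"value slope | {cls}",
                                   "estimate": np.nan, "ci_lo": np.nan,
                                   "ci_hi": np.nan, "p": np.nan,
                                   "p_adj": np.nan}))
    cols = ["term", "estimate", "ci_lo", "ci_hi", "p", "p_adj"]
    table = (pd.DataFrame(rows).reset_index(drop=True)[cols]
             if rows else pd.DataFrame(columns=cols))
    return ModelResult(name=name, table=table, n_obs=len(dataset),
                       n_subjects=dataset["subject_id"].nunique(),
                       backend="per-class mixed fits")


def run_model_suite(
    frame: pd.DataFrame,
    matching_tolerance: float = 0.5,
    with_slopes: bool = True,
) -> dict:
    """Fit the seven model families on a study frame.

    Returns a dict of ModelResult keyed by model name; empty model
    datasets are skipped with the reason recorded under 'skipped'.
    """
    results: dict = {}
    skipped: dict = {}

    def _try(name, fn):
        try:
            results[name] = fn()
        except (ValueError, KeyError) as exc:
            skipped[name] = str(exc)

    choice = prepare_sequential_dataset(frame, "choice")
    choice_primary = choice[choice.prev_is_risky.astype(bool)
                            & choice.prev_class.isin([GOOD, MID, BAD])]
    _try("choice_primary", lambda: fit_mixed_model(
        choice_primary,
        "stay ~ prev_value + C(prev_class, Treatment('good'))",
        "binary", name="choice_primary"))

    mg = build_matched_subsets(choice_primary, "bad_vs_good",
                               tolerance=matching_tolerance)
    _try("choice_matched_bad_good", lambda: fit_mixed_model(
        mg, "stay ~ prev_value * C(prev_class, Treatment('good'))",
        "binary", random_slope="prev_value", name="choice_matched_bad_good"))
    if with_slopes and not mg.empty:
        results["choice_matched_bad_good_slopes"] = simple_slopes(
            mg, "stay", "prev_value", "prev_class", "binary",
            "choice_matched_bad_good_slopes")

    mn = build_matched_subsets(choice[choice.prev_class.isin([BAD, NONRISK])],
                               "bad_vs_nonrisk", tolerance=matching_tolerance)
    _try("choice_matched_bad_nonrisk", lambda: fit_mixed_model(
        mn, "stay ~ prev_value * C(prev_class, Treatment('nonrisk'))",
        "binary", random_slope="prev_value", name="choice_matched_bad_nonrisk"))

    rating = prepare_sequential_dataset(frame, "rating")
    _try("rating_primary", lambda: fit_mixed_model(
        rating,
        "rating_centered ~ value + C(outcome_class, Treatment('good'))",
        "continuous", name="rating_primary"))

    rl = prepare_sequential_dataset(frame, "rating_lagged")
    rmg = build_matched_subsets(rl[rl.prev_class.isin([BAD, GOOD])],
                                "bad_vs_good", tolerance=matching_tolerance)
    _try("rating_matched_bad_good", lambda: fit_mixed_model(
        rmg, "rating_centered ~ prev_value * C(prev_class, Treatment('good'))",
        "continuous", random_slope="prev_value", name="rating_matched_bad_good"))
    if with_slopes and not rmg.empty:
        results["rating_matched_bad_good_slopes"] = simple_slopes(
            rmg, "rating_centered", "prev_value", "prev_class", "continuous",
            "rating_matched_bad_good_slopes")
    rmn = build_matched_subsets(rl[rl.prev_class.isin([BAD, NONRISK])],
                                "bad_vs_nonrisk", tolerance=matching_tolerance)
    _try("rating_matched_bad_nonrisk", lambda: fit_mixed_model(
        rmn, "rating_centered ~ prev_value * C(prev_class, Treatment('nonrisk'))",
        "continuous", random_slope="prev_value", name="rating_matched_bad_nonrisk"))

    rt = prepare_sequential_dataset(frame, "rt")
    rt = rt[rt.prev_class.isin([GOOD, MID, BAD])]
    _try("rt", lambda: fit_mixed_model(
        rt, "log_rt ~ prev_value + C(prev_class, Treatment('good'))",
        "continuous", name="rt"))

    gc = prepare_sequential_dataset(frame, "global_choice")
    _try("global_choice", lambda: fit_mixed_model(
        gc, "stay ~ videos_consumed * C(is_risky) + expected_value",
        "binary", name="global_choice"))
    gr = prepare_sequential_dataset(frame, "global_rating")
    _try("global_rating", lambda: fit_mixed_model(
        gr, "rating_centered ~ videos_consumed * C(is_risky) + expected_value",
        "continuous", name="global_rating"))

    _try("control", lambda: fit_mixed_model(
        choice_primary,
        "stay ~ prev_value + C(prev_class, Treatment('good'))"
        " + videos_consumed + spread",
        "binary", name="control"))

    sec = prepare_sequential_dataset(frame, "secondary")
    sec = sec[sec.prev_rating.notna()]
    _try("secondary", lambda: fit_mixed_model(
        sec,
        "stay ~ prev_value + prev_rating + C(prev_class, Treatment('bad'))"
        " + prev_value:prev_rating"
        " + prev_rating:C(prev_class, Treatment('bad'))",
        "binary", name="secondary"))

    results["skipped"] = skipped
    return results


def suite_to_frame(results: dict) -> pd.DataFrame:
    """Tidy export: (model, term, estimate, ci_lo, ci_hi, p, p_adj)."""
    rows = []
    for name, res in results.items():
        if not isinstance(res, ModelResult):
            continue
        t = res.table.copy()
        t.insert(0, "model", name)
        rows.append(t)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


__all__ = [
    "classify_outcome", "session_frame", "study_frame",
    "prepare_sequential_dataset", "fit_mixed_model", "bh_adjust",
    "build_matched_subsets", "run_model_suite", "suite_to_frame",
    "simple_slopes", "ModelResult", "coef",
]
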