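"""Individual differences: subject-level coefficients, ESI scoring,
and robust partial correlations with externalizing traits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .agents import PROBLEM_SUBSCALES, SUBFACTORS, ItemDesign
from .framing import bh_adjust, prepare_sequential_dataset
from .task import BAD, GOOD, MID

_COEF_CAP = 15.0  # |logit coefficient| beyond this is treated as degenerate


def firth_logistic(X: np.ndarray, y: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Bias-reduced (Firth) logistic regression.

    Subject-level fits rest on a few dozen trials, where ordinary ML
    estimates are heavy-tailed and blow up under quasi-separation;
    Firth's penalized score keeps every subject's coefficient finite
    and nearly unbiased, which matters when coefficients feed
    between-subject correlations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = p * (1.0 - p)
        info = (X.T * w) @ X
        info_inv = np.linalg.pinv(info)
        hat = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + hat * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


@dataclass
class SubjectCoefficients:
    subject_id: str
    choice_outcome_coeff: float = np.nan   # bad-vs-good, logit; >0 = stays more after bad
    rating_outcome_coeff: float = np.nan   # bad-vs-good on centered ratings
    choice_flag: Optional[str] = None
    rating_flag: Optional[str] = None


def _subject_choice_fit(sub: pd.DataFrame) -> tuple[float, Optional[str]]:
    counts = sub.prev_class.value_counts()
    if counts.get(BAD, 0) < 1 or counts.get(GOOD, 0) < 1:
        return np.nan, "missing bad or good prior outcomes"
    if sub.stay.nunique() < 2:
        return np.nan, "no choice variation (separation)"
    try:
        import patsy

        X = patsy.dmatrix("prev_value + C(prev_class, Treatment('good'))",
                          sub, return_type="dataframe")
        bcol = [i for i, c in enumerate(X.columns) if "[T.bad]" in c][0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = float(firth_logistic(X.values, sub.stay.values)[bcol])
        if not np.isfinite(b) or abs(b) > _COEF_CAP:
            return np.nan, "degenerate fit (unbounded coefficient)"
        return b, None
    except Exception as exc:
        return np.nan, f"fit failed: {exc}"


def _subject_rating_fit(sub: pd.DataFrame) -> tuple[float, Optional[str]]:
    counts = sub.outcome_class.value_counts()
    if counts.get(BAD, 0) < 1 or counts.get(GOOD, 0) < 1:
        return np.nan, "missing bad or good outcomes"
    try:
        fit = smf.ols("rating_centered ~ value + C(outcome_class, Treatment('good'))",
                      sub).fit()
        name = [n for n in fit.params.index if "[T.bad]" in n][0]
        b = float(fit.params[name])
        if not np.isfinite(b):
            return np.nan, "rank deficient"
        return b, None
    except Exception as exc:
        return np.nan, f"fit failed: {exc}"


def fit_subject_models(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-subject fixed-effect fits mirroring the group models.

    Choice: logistic regression of the current stay/skip on the
    previous trial's actual value and outcome framing (previous risky
    stay, current risky trials). Rating: linear regression of the
    centered rating on the current trial's value and framing. The
    unstandardized bad-vs-good coefficient is extracted from each;
    separation or rank deficiency flags the subject.
    """
    choice_data = prepare_sequential_dataset(frame, "choice")
    choice_data = choice_data[choice_data.prev_is_risky.astype(bool)
                              & choice_data.prev_class.isin([GOOD, MID, BAD])]
    rating_data = prepare_sequential_dataset(frame, "rating")
    out = []
    for sid in frame.subject_id.unique():
        rec = SubjectCoefficients(subject_id=sid)
        sub_c = choice_data[choice_data.subject_id == sid]
        if len(sub_c):
            rec.choice_outcome_coeff, rec.choice_flag = _subject_choice_fit(sub_c)
        else:
            rec.choice_flag = "no eligible sequential trials"
        sub_r = rating_data[rating_data.subject_id == sid]
        if len(sub_r):
            rec.rating_outcome_coeff, rec.rating_flag = _subject_rating_fit(sub_r)
        else:
            rec.rating_flag = "no risky stays"
        out.append(rec.__dict__)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# ESI scoring

@dataclass
class TraitProfile:
    subject_id: str
    esi_total: float
    esi_total_log: float
    general_disinhibition: float
    substance_abuse: float
    callous_aggression: float
    alcohol: float
    marijuana: float
    drug: float
    alcohol_retained: bool
    marijuana_retained: bool
    drug_retained: bool


def score_esi(responses: np.ndarray, design: ItemDesign, subject_id: str = "") -> TraitProfile:
    """Sum-score the inventory.

    Total = sum over all 100 items, log-transformed as ln(total + 1) to
    improve normality while staying defined at zero. Subfactor scores
    are sums over assigned items; each problem subscale carries a
    retained flag that is true iff at least one of its items was
    endorsed (the zero-inflation retention rule).
    """
    responses = np.asarray(responses)
    if responses.shape != (100,):
        raise ValueError("expected 100 item responses")
    if np.isnan(responses.astype(float)).any():
        raise ValueError("missing item responses; subject must be flagged upstream")
    total = float(responses.sum())
    sub = {name: float(responses[design.items_for_subfactor(i)].sum())
           for i, name in enumerate(SUBFACTORS)}
    scales = {name: float(responses[design.items_for_subscale(name)].sum())
              for name in PROBLEM_SUBSCALES}
    return TraitProfile(
        subject_id=subject_id,
        esi_total=total,
        esi_total_log=float(np.log(total + 1.0)),
        general_disinhibition=sub["general_disinhibition"],
        substance_abuse=sub["substance_abuse"],
        callous_aggression=sub["callous_aggression"],
        alcohol=scales["alcohol"],
        marijuana=scales["marijuana"],
        drug=scales["drug"],
        alcohol_retained=scales["alcohol"] >= 1,
        marijuana_retained=scales["marijuana"] >= 1,
        drug_retained=scales["drug"] >= 1,
    )


# --------------------------------------------------------------------------
# Robust partial correlations

def robust_partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    tails: str = "two",
    expected_sign: int = 1,
) -> tuple[float, float, int]:
    """Percentage-bend correlation (bend constant 0.2) between x and y
    after residualizing both on the covariates by least squares.

    One-tailed p-values are halved when the observed sign matches
    `expected_sign`, else folded to 1 - p/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if covariates is not None and len(covariates):
        Z = np.asarray(covariates, dtype=float)
        mask &= np.isfinite(Z).all(axis=1)
    n = int(mask.sum())
    if n < 8:
        raise ValueError(f"too few complete cases ({n}) for a partial correlation")
    x, y = x[mask], y[mask]
    if covariates is not None and len(covariates):
        Z = sm.add_constant(np.asarray(covariates, dtype=float)[mask])
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant residuals: correlation undefined")
    res = pg.corr(x, y, method="percbend")
    r = float(res["r"].iloc[0])
    p = float(res["p_val"].iloc[0])
    if tails == "one":
        p = p / 2.0 if np.sign(r) == np.sign(expected_sign) or r == 0 else 1.0 - p / 2.0
    return r, p, n


def _dummies(demo: pd.DataFrame) -> pd.DataFrame:
    cov = pd.DataFrame(index=demo.index)
    cov["age"] = demo["age"].astype(float)
    cov["sex"] = (demo["sex"] == "female").astype(float)
    eth = pd.get_dummies(demo["ethnicity"], prefix="eth", drop_first=True)
    return pd.concat([cov, eth.astype(float)], axis=1)


def run_trait_correlations(
    coeffs: pd.DataFrame,
    profiles: pd.DataFrame,
    demographics: pd.DataFrame,
    logk: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Correlation report: primary, follow-up, and adjusted analyses.

    Primary (two-tailed): choice and rating bad-vs-good coefficients vs
    log total ESI, partialling age, sex and ethnicity. Follow-ups
    (one-tailed, expecting more reward pursuit after losses in high
    scorers; BH-adjusted over the six): the choice coefficient vs the
    three subfactors and the three problem subscales (subscales
    restricted to retained subjects). Plus the unique-contribution
    check (substance abuse partialling the other two subfactors) and,
    when k-values are supplied, the discounting-adjusted partial.
    """
    df = coeffs.merge(profiles, on="subject_id").merge(demographics, on="subject_id")
    if logk is not None:
        df = df.merge(logk, on="subject_id", how="left")
    base_cov = _dummies(df)
    rows = []

    def _run(name, x, y, extra_cov=None, tails="two", subset=None, group=None):
        d = df if subset is None else df[subset]
        cov = base_cov if subset is None else base_cov[subset]
        if extra_cov is not None:
            cov = pd.concat([cov, d[extra_cov].astype(float)], axis=1)
        try:
            r, p, n = robust_partial_correlation(
                d[x], d[y], cov, tails=tails, expected_sign=1)
            rows.append({"name": name, "group": group, "x": x, "y": y,
                         "n": n, "r": r, "p": p, "tails": tails, "note": ""})
        except ValueError as exc:
            rows.append({"name": name, "group": group, "x": x, "y": y,
                         "n": 0, "r": np.nan, "p": np.nan, "tails": tails,
                         "note": str(exc)})

    _run("choice_vs_esi_total", "choice_outcome_coeff", "esi_total_log",
         group="primary")
    _run("rating_vs_esi_total", "rating_outcome_coeff", "esi_total_log",
         group="primary")

    for sf in SUBFACTORS:
        _run(f"choice_vs_{sf}", "choice_outcome_coeff", sf,
             tails="one", group="followup")
    for sc in PROBLEM_SUBSCALES:
        _run(f"choice_vs_{sc}_problems", "choice_outcome_coeff", sc,
             tails="one", group="followup",
             subset=df[f"{sc}_retained"].astype(bool))

    _run("choice_vs_substance_abuse_unique", "choice_outcome_coeff",
         "substance_abuse",
         extra_cov=["general_disinhibition", "callous_aggression"],
         tails="one", group="unique")
    if logk is not None and {"logk_delay", "logk_prob"} <= set(df.columns):
        _run("choice_vs_esi_total_adj_discounting", "choice_outcome_coeff",
             "esi_total_log", extra_cov=["logk_delay", "logk_prob"],
             group="adjusted")
        _run("esi_vs_logk_delay", "logk_delay", "esi_total_log", group="discounting")
        _run("esi_vs_logk_prob", "logk_prob", "esi_total_log", group="discounting")

    report = pd.DataFrame(rows)
    report["p_adj"] = np.nan
    fu = report.group.eq("followup") & report.p.notna()
    if fu.any():
        report.loc[fu, "p_adj"] = bh_adjust(report.loc[fu, "p"].values)
    return report


__all__ = [
    "SubjectCoefficients", "fit_subject_models",
    "TraitProfile", "score_esi",
    "robust_partial_correlation", "run_trait_correlations",
]
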