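"""Hyperbolic delay and probability discounting.

Indifference points are read off a titration of smaller-sooner amounts
against a fixed larger-later reward, then fit with V = A / (1 + kD)
(delay, D in days) or V = A / (1 + h*theta) with theta = (1 - p) / p
(probability, odds-against). Nonsystematic response patterns are
flagged with the standard two-criterion screen (any indifference point
rising by more than 20% of the larger-later amount, or a total drop of
less than 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .agents import DiscountMenu, discounted_value, odds_against

_LOGK_BOUNDS = (-15.0, 5.0)


@dataclass
class DiscountFit:
    mode: str                      # 'delay' | 'probability'
    k: float                       # discount rate (per day, or per unit odds-against)
    log_k: float
    r_squared: float
    n_points: int
    flags: list = field(default_factory=list)


def compute_indifference_points(choices: pd.DataFrame) -> pd.DataFrame:
    """Per-condition indifference values from the binary choice table.

    The indifference point is the midpoint between the largest
    smaller-sooner amount rejected (in favor of the later/risky option)
    and the smallest accepted. Censored runs (all one response) sit at
    the grid extreme and are flagged; non-monotone runs are flagged and
    bracketed by the overall switch envelope.
    """
    out = []
    for (kind, cond), grp in choices.groupby(["kind", "condition"]):
        grp = grp.sort_values("sooner_amount")
        s = grp.sooner_amount.values
        later = grp.choose_later.values.astype(bool)
        amount = float(grp.later_amount.iloc[0])
        flag = None
        if later.all():
            indiff, flag = float(s.max()), "censored_high"
        elif not later.any():
            indiff, flag = float(s.min()), "censored_low"
        else:
            rej_max = s[later].max()       # largest S passed over for the later option
            acc_min = s[~later].min()      # smallest S accepted
            indiff = float((rej_max + acc_min) / 2.0)
            # monotone responding switches exactly once
            if (np.diff(later.astype(int)) == 1).any():
                flag = "nonmonotone"
        out.append({"kind": kind, "condition": cond, "amount": amount,
                    "indifference": indiff, "flag": flag})
    return pd.DataFrame(out)


def exact_indifference_points(
    k: float, mode: str, menu: Optional[DiscountMenu] = None
) -> pd.DataFrame:
    """Noise-free indifference points straight from the hyperbola
    (bypassing titration granularity)."""
    menu = menu or DiscountMenu()
    conds = menu.delays if mode == "delay" else menu.probabilities
    rows = []
    for c in conds:
        x = c if mode == "delay" else odds_against(c)
        rows.append({"kind": mode, "condition": c, "amount": menu.amount,
                     "indifference": discounted_value(menu.amount, k, x),
                     "flag": None})
    return pd.DataFrame(rows)


def fit_hyperbolic(points: pd.DataFrame, mode: str) -> DiscountFit:
    """Least-squares hyperbolic fit on indifference points.

    k is kept positive through a log parameterization; R-squared is
    1 - SSE/SST over the points. Degenerate point sets (no decline)
    push ln k to the lower boundary and are flagged.
    """
    pts = points[points.kind == mode] if "kind" in points else points
    if len(pts) < 3:
        raise ValueError("hyperbolic fit needs at least 3 conditions")
    v = pts.indifference.values.astype(float)
    a = pts.amount.values.astype(float)
    if mode == "delay":
        x = pts.condition.values.astype(float)
    elif mode == "probability":
        x = np.array([odds_against(p) for p in pts.condition.values])
    else:
        raise ValueError("mode must be 'delay' or 'probability'")

    def sse(logk):
        return float(((v - a / (1.0 + np.exp(logk) * x)) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=_LOGK_BOUNDS, method="bounded",
                                   options={"xatol": 1e-10})
    logk = float(res.x)
    sst = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    flags = []
    if logk <= _LOGK_BOUNDS[0] + 1e-3:
        flags.append("k_at_zero_boundary")
    if logk >= _LOGK_BOUNDS[1] - 1e-3:
        flags.append("k_at_upper_boundary")
    if sst == 0:
        flags.append("degenerate_points")
    return DiscountFit(mode=mode, k=float(np.exp(logk)), log_k=logk,
                       r_squared=r2, n_points=len(pts), flags=flags)


def johnson_bickel_flags(
    indifference: Sequence[float],
    amount: float,
    rise_frac: float = 0.2,
    drop_frac: float = 0.1,
) -> dict:
    """Nonsystematic-data screen on severity-ordered indifference points.

    C1: any point exceeds its predecessor by more than `rise_frac` of
    the larger-later amount. C2: the last point is not at least
    `drop_frac` of the amount below the first.
    """
    v = np.asarray(indifference, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two indifference points")
    c1 = bool((np.diff(v) > rise_frac * amount).any())
    c2 = bool((v[0] - v[-1]) < drop_frac * amount)
    return {"c1_rising_point": c1, "c2_insufficient_drop": c2}


def fit_subject_discounting(
    choices: pd.DataFrame, menu: Optional[DiscountMenu] = None
) -> pd.DataFrame:
    """Full per-subject pipeline: indifference points -> hyperbolic fits
    -> screen flags, for both the delay and probability tasks."""
    menu = menu or DiscountMenu()
    rows = []
    for sid, grp in choices.groupby("subject_id"):
        pts = compute_indifference_points(grp)
        for mode, order_key in (("delay", None), ("probability", None)):
            sub = pts[pts.kind == mode].copy()
            if mode == "delay":
                sub = sub.sort_values("condition")
            else:  # increasing odds-against = decreasing probability
                sub = sub.sort_values("condition", ascending=False)
            fit = fit_hyperbolic(sub, mode)
            jb = johnson_bickel_flags(sub.indifference.values, menu.amount)
            rows.append({
                "subject_id": sid, "mode": mode, "k": fit.k,
                "log_k": fit.log_k, "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "jb_c1": jb["c1_rising_point"], "jb_c2": jb["c2_insufficient_drop"],
                "fit_flags": ";".join(fit.flags),
            })
    return pd.DataFrame(rows)


__all__ = [
    "DiscountFit", "compute_indifference_points", "exact_indifference_points",
    "fit_hyperbolic", "johnson_bickel_flags", "fit_subject_discounting",
]
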