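#!/usr/bin/env python
"""Individual differences: externalizing traits and loss responses.

Extracts per-subject bad-vs-good coefficients (Firth logistic for
choices, OLS for ratings), scores the 100-item externalizing
inventory with the zero-inflation retention rule, and runs the robust
partial-correlation report (age, sex, ethnicity controlled), including
the discounting-adjusted check.
"""

from pathlib import Path

import pandas as pd

import webforage as wf

RES = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main():
    RES.mkdir(parents=True, exist_ok=True)
    study = wf.simulate_study(wf.PopulationConfig(), seed=SEED)
    an = wf.analyze_study(study, fit_models=False, with_validity=False)
    an.subject_coeffs.to_csv(RES / "subject_coefficients.csv", index=False)
    an.profiles.to_csv(RES / "trait_profiles.csv", index=False)
    an.trait_report.to_csv(RES / "trait_correlations.csv", index=False)

    truth = pd.DataFrame([{"subject_id": a.subject_id, "gamma": a.gamma,
                           "E": a.E} for a in study.agents])
    j = an.subject_coeffs.merge(truth, on="subject_id")
    ok = j.choice_outcome_coeff.notna()
    rho = j.loc[ok, ["choice_outcome_coeff", "gamma"]].corr(
        method="spearman").iloc[0, 1]
    print(f"recovered choice coefficients rank-correlate with true framing "
          f"sensitivity: rho = {rho:.2f} ({int(ok.sum())} estimable subjects)")

    rep = an.trait_report.set_index("name")
    c = rep.loc["choice_vs_esi_total"]
    r = rep.loc["rating_vs_esi_total"]
    print(f"choice coefficient vs ESI total: partial r = {c.r:+.2f} "
          f"(p = {c.p:.4f}, n = {int(c.n)})")
    print(f"rating coefficient vs ESI total: partial r = {r.r:+.2f} "
          f"(p = {r.p:.4f}) -> the dissociation: traits track reward "
          "pursuit, not reward valuation")
    fu = an.trait_report[an.trait_report.group == "followup"]
    print(fu[["name", "n", "r", "p", "p_adj"]].to_string(index=False))
    retained = an.profiles[["alcohol_retained", "marijuana_retained",
                            "drug_retained"]].mean()
    print("problem-subscale retention rates:",
          ", ".join(f"{k.split('_')[0]} {v:.0%}" for k, v in retained.items()))


if __name__ == "__main__":
    main()
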