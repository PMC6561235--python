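"""End-to-end study orchestration: simulate a cohort, run the full
analysis pipeline, and score recovery against the generative truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import discounting as disc
from .agents import (AgentParams, DiscountMenu, ItemDesign, PopulationConfig,
                     default_item_design, generate_discounting_responses,
                     generate_esi_responses, sample_population)
from .framing import run_model_suite, study_frame
from .task import SessionConfig, run_session
from .thresholds import assign_trial_thresholds, psychophysics_curve, validity_correlations
from .traits import fit_subject_models, run_trait_correlations, score_esi


@dataclass
class StudyData:
    """Everything a simulated study produces."""

    agents: list
    sessions: dict                      # subject_id -> list[TrialRecord]
    esi_responses: dict                 # subject_id -> (100,) int array
    discount_choices: pd.DataFrame
    item_design: ItemDesign
    pop_config: PopulationConfig
    session_config: SessionConfig
    seed: int
    demographics_override: Optional[pd.DataFrame] = None  # set when reloaded from disk

    @property
    def demographics(self) -> pd.DataFrame:
        if self.demographics_override is not None:
            return self.demographics_override
        return pd.DataFrame([{"subject_id": a.subject_id, "age": a.age,
                              "sex": a.sex, "ethnicity": a.ethnicity}
                             for a in self.agents])

    @property
    def true_logk(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": a.subject_id,
                              "logk_delay": a.logk_delay,
                              "logk_prob": a.logk_prob}
                             for a in self.agents])


def simulate_study(
    pop: Optional[PopulationConfig] = None,
    session: Optional[SessionConfig] = None,
    seed: int = 0,
    with_esi: bool = True,
    with_discounting: bool = True,
) -> StudyData:
    """Simulate the whole study from a single seed.

    Per-subject session seeds are spawned from the master seed so the
    study is reproducible as a unit and each session independently.
    """
    pop = pop or PopulationConfig()
    session = session or SessionConfig()
    agents = sample_population(pop, seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(3)
    session_rngs = child_seeds[0].spawn(pop.n_subjects)
    esi_rng = np.random.default_rng(child_seeds[1])
    disc_rng = np.random.default_rng(child_seeds[2])
    design = default_item_design(pop.esi_loading_E, pop.esi_loading_factor)
    sessions = {}
    esi = {}
    dchoices = []
    menu = DiscountMenu()
    for a, s in zip(agents, session_rngs):
        sessions[a.subject_id] = run_session(a, session, s)
        if with_esi:
            esi[a.subject_id] = generate_esi_responses(a, design, esi_rng)
        if with_discounting:
            dchoices.append(generate_discounting_responses(a, menu, disc_rng))
    return StudyData(
        agents=agents,
        sessions=sessions,
        esi_responses=esi,
        discount_choices=(pd.concat(dchoices, ignore_index=True)
                          if dchoices else pd.DataFrame()),
        item_design=design,
        pop_config=pop,
        session_config=session,
        seed=seed,
    )


@dataclass
class StudyAnalysis:
    threshold_sets: dict
    frame: pd.DataFrame
    models: dict = field(default_factory=dict)
    subject_coeffs: pd.DataFrame = field(default_factory=pd.DataFrame)
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_report: pd.DataFrame = field(default_factory=pd.DataFrame)
    discount_fits: pd.DataFrame = field(default_factory=pd.DataFrame)
    validity: pd.DataFrame = field(default_factory=pd.DataFrame)
    psychophysics: pd.DataFrame = field(default_factory=pd.DataFrame)


def compute_thresholds(study: StudyData) -> dict:
    cfg = study.session_config
    return {sid: assign_trial_thresholds(recs, cfg.delay_min, cfg.delay_max)
            for sid, recs in study.sessions.items()}


def compute_validity(study: StudyData, threshold_sets: dict,
                     ranking_seed: int = 0) -> pd.DataFrame:
    """Per-subject validity correlations.

    Post-test rankings are derived from the agent's true preference
    order (most-preferred gallery ranked 1), emulating the end-of-task
    questionnaire; mean ratings come from the session log.
    """
    rows = []
    for a in study.agents:
        ts = threshold_sets[a.subject_id]
        gmeans = [ts.gallery_mean.get(g, float("nan")) for g in a.galleries]
        recs = study.sessions[a.subject_id]
        ratings = []
        for g in a.galleries:
            rs = [r.rating for r in recs
                  if r.offer.gallery == g and r.rating is not None]
            ratings.append(np.mean(rs) if rs else float("nan"))
        order = np.argsort(-a.tau)  # best gallery gets rank 1
        ranks = np.empty(4)
        ranks[order] = np.arange(1, 5)
        r_rating, r_ranking, flags = validity_correlations(gmeans, ratings, ranks)
        rows.append({"subject_id": a.subject_id, "r_ratings": r_rating,
                     "r_rankings": r_ranking, "flags": ";".join(flags)})
    return pd.DataFrame(rows)


def analyze_study(
    study: StudyData,
    fit_models: bool = True,
    fit_traits: bool = True,
    fit_discounting: bool = True,
    with_validity: bool = True,
) -> StudyAnalysis:
    threshold_sets = compute_thresholds(study)
    frame = study_frame(study.sessions, threshold_sets)
    out = StudyAnalysis(threshold_sets=threshold_sets, frame=frame)
    if fit_models:
        out.models = run_model_suite(frame)
    if fit_traits:
        out.subject_coeffs = fit_subject_models(frame)
        if study.esi_responses:
            out.profiles = pd.DataFrame([
                score_esi(resp, study.item_design, sid).__dict__
                for sid, resp in study.esi_responses.items()])
    if fit_discounting and len(study.discount_choices):
        out.discount_fits = disc.fit_subject_discounting(study.discount_choices)
    if fit_traits and len(out.profiles):
        logk = None
        if len(out.discount_fits):
            logk = (out.discount_fits
                    .pivot(index="subject_id", columns="mode", values="log_k")
                    .rename(columns={"delay": "logk_delay",
                                     "probability": "logk_prob"})
                    .reset_index())
        out.trait_report = run_trait_correlations(
            out.subject_coeffs, out.profiles, study.demographics, logk)
    if with_validity:
        out.validity = compute_validity(study, threshold_sets)
        curve_input = frame.rename(columns={"is_risky": "is_risky"})[
            ["subject_id", "is_risky", "mid", "threshold", "stay"]
        ].rename(columns={"threshold": "assigned_threshold"})
        out.psychophysics = psychophysics_curve(curve_input)
    return out


def threshold_recovery(study: StudyData, threshold_sets: dict) -> pd.DataFrame:
    """Estimated gallery-mean thresholds vs the generative tau."""
    rows = []
    for a in study.agents:
        ts = threshold_sets[a.subject_id]
        for g, tau in zip(a.galleries, a.tau):
            est = ts.gallery_mean.get(g, float("nan"))
            rows.append({"subject_id": a.subject_id, "gallery": g,
                         "tau_true": float(tau), "tau_est": est,
                         "abs_error": abs(est - tau) if np.isfinite(est) else np.nan})
    return pd.DataFrame(rows)


def recovery_metrics(study: StudyData, analysis: StudyAnalysis) -> dict:
    """Headline recovery numbers for a simulated study."""
    rec = threshold_recovery(study, analysis.threshold_sets)
    metrics = {
        "threshold_mae": float(np.nanmedian(rec.abs_error)),
        "threshold_corr": float(rec[["tau_true", "tau_est"]].corr().iloc[0, 1]),
    }
    truth = pd.DataFrame([{"subject_id": a.subject_id, "gamma_true": a.gamma,
                           "E_true": a.E} for a in study.agents])
    if len(analysis.subject_coeffs):
        j = analysis.subject_coeffs.merge(truth, on="subject_id")
        ok = j.choice_outcome_coeff.notna()
        if ok.sum() >= 3:
            metrics["choice_coeff_vs_gamma_spearman"] = float(
                j.loc[ok, ["choice_outcome_coeff", "gamma_true"]]
                .corr(method="spearman").iloc[0, 1])
        metrics["n_choice_coeff_estimable"] = int(ok.sum())
    if len(analysis.discount_fits):
        j = analysis.discount_fits.merge(study.true_logk, on="subject_id")
        d = j[j["mode"] == "delay"]
        metrics["logk_delay_mae"] = float(np.median(np.abs(d.log_k - d.logk_delay)))
        p = j[j["mode"] == "probability"]
        metrics["logk_prob_mae"] = float(np.median(np.abs(p.log_k - p.logk_prob)))
    return metrics


__all__ = [
    "StudyData", "StudyAnalysis", "simulate_study", "analyze_study",
    "compute_thresholds", "compute_validity", "threshold_recovery",
    "recovery_metrics",
]
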