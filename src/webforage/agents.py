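"""Generative behavioral model for synthetic subjects.

Each agent carries ground-truth parameters (delay thresholds, framing
sensitivity, a latent externalizing score, discounting rates) so the
full analysis pipeline can be validated by parameter recovery:

* choices: logistic in beta * (threshold - presented delay), with an
  additive shift of gamma_i + eta * V_prev after a risky loss, where
  gamma_i = gamma0 + gamma_E * E_i couples framing sensitivity to the
  latent externalizing trait E;
* ratings: an ordered-latent (cumulative) model discretized at fixed
  cutpoints;
* reaction times: log-normal with post-loss slowing delta;
* questionnaire items: a two-parameter logistic item-response model
  with high-difficulty "problem" items producing zero inflation;
* discounting: softmax choices over hyperbolically discounted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import BAD, NONRISK, Offer, SessionConfig, TrialRecord, DEFAULT_GALLERIES

ETHNICITY_CODES = ("caucasian", "asian", "black", "hispanic", "other")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class AgentParams:
    """Generative truth for one synthetic subject."""

    subject_id: str
    tau: np.ndarray                     # per-gallery delay thresholds (s)
    beta: float                         # choice inverse temperature (1/s)
    gamma0: float                       # population framing main effect (logit)
    gamma_E: float                      # slope of framing effect on E
    E: float                            # latent externalizing (standardized)
    eta: float                          # value x loss interaction (logit/s)
    rating_mu: np.ndarray               # per-gallery latent rating intercepts
    rating_a: float                     # latent slope on actual value (1/s)
    rating_b: float                     # latent offset after a bad outcome
    rating_c: float                     # value x bad slope (1/s)
    sigma_r: float
    cutpoints: np.ndarray               # 3 increasing cutpoints -> ratings 1..4
    alpha0: float                       # log-seconds RT intercept
    delta: float                        # post-loss RT slowing (log scale)
    sigma_rt: float
    logk_delay: float                   # ln k, per day
    logk_prob: float                    # ln h, per unit odds-against
    choice_sharpness: float             # discounting softmax slope (1/$)
    esi_factors: np.ndarray = field(default_factory=lambda: np.zeros(3))
    age: float = 20.0
    sex: str = "female"
    ethnicity: str = "caucasian"
    galleries: Sequence[str] = DEFAULT_GALLERIES

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.rating_mu = np.asarray(self.rating_mu, dtype=float)
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.tau.shape != (4,):
            raise ValueError("tau must hold one threshold per gallery (4)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.sigma_r <= 0 or self.sigma_rt <= 0:
            raise ValueError("noise scales must be positive")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def gamma(self) -> float:
        """Effective framing coefficient gamma_i = gamma0 + gamma_E * E."""
        return self.gamma0 + self.gamma_E * self.E

    def threshold_for(self, gallery: str) -> float:
        return float(self.tau[list(self.galleries).index(gallery)])

    def rating_mu_for(self, gallery: str) -> float:
        return float(self.rating_mu[list(self.galleries).index(gallery)])


@dataclass
class PopulationConfig:
    """Distributions for sampling a cohort of synthetic subjects.

    Defaults emulate a ~100-subject undergraduate sample: thresholds
    spread across galleries, a group-level post-loss risk aversion
    (gamma0 < 0) attenuated in high-externalizing agents (gamma_E > 0),
    post-loss rating enhancement and RT slowing, and log-normal
    hyperbolic discounting rates centered on the published medians.
    """

    n_subjects: int = 105
    tau_mean: Sequence[float] = (16.5, 16.5, 16.5, 16.5)
    tau_sd: float = 4.0
    tau_bounds: Sequence[float] = (4.0, 29.0)
    beta_mean: float = 0.2
    beta_sd: float = 0.06
    beta_min: float = 0.05
    gamma0: float = -0.6
    gamma_E: float = 0.8
    eta: float = 0.05
    rating_threshold_link: float = 0.12  # couples gallery rating level to tau
    rating_mu_sd: float = 0.25
    rating_a: float = 0.02
    rating_b: float = 0.3
    rating_c: float = 0.02
    rating_E_link: float = 0.0           # E -> rating_b pathway, off by default
    sigma_r: float = 1.0
    cutpoints: Sequence[float] = (-1.2, 0.0, 1.2)
    alpha0_mean: float = float(np.log(1.5))
    alpha0_sd: float = 0.15
    delta: float = 0.15
    sigma_rt: float = 0.35
    logk_delay_mean: float = -5.26
    logk_delay_sd: float = 2.05
    logk_prob_mean: float = 0.28
    logk_prob_sd: float = 0.84
    choice_sharpness: float = 3.0
    esi_loading_E: float = 1.0
    esi_loading_factor: float = 0.8
    age_mean: float = 20.2
    age_sd: float = 1.8
    p_female: float = 0.81
    ethnicity_probs: Sequence[float] = (0.63, 0.26, 0.04, 0.03, 0.04)
    galleries: Sequence[str] = DEFAULT_GALLERIES

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("tau_sd", "beta_sd", "rating_mu_sd", "alpha0_sd",
                     "logk_delay_sd", "logk_prob_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_r <= 0 or self.sigma_rt <= 0:
            raise ValueError("noise scales must be positive")
        probs = np.asarray(self.ethnicity_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("ethnicity_probs must be a probability vector")


def sample_population(pop: PopulationConfig, seed) -> list[AgentParams]:
    """Draw a cohort of agents with known ground truth.

    E is standard normal; the effective framing coefficient of agent i
    is gamma0 + gamma_E * E_i, so gamma_E > 0 attenuates (or reverses)
    the group-level post-loss risk aversion for high-E agents.
    """
    rng = np.random.default_rng(seed)
    agents = []
    tau_mean = np.asarray(pop.tau_mean, dtype=float)
    for i in range(pop.n_subjects):
        E = float(rng.normal())
        tau = np.clip(rng.normal(tau_mean, pop.tau_sd), *pop.tau_bounds)
        mu = (pop.rating_threshold_link * (tau - tau.mean())
              + rng.normal(0.0, pop.rating_mu_sd, size=4))
        agents.append(AgentParams(
            subject_id=f"s{i:03d}",
            tau=tau,
            beta=max(pop.beta_min, float(rng.normal(pop.beta_mean, pop.beta_sd))),
            gamma0=pop.gamma0,
            gamma_E=pop.gamma_E,
            E=E,
            eta=pop.eta,
            rating_mu=mu,
            rating_a=pop.rating_a,
            rating_b=pop.rating_b + pop.rating_E_link * E,
            rating_c=pop.rating_c,
            sigma_r=pop.sigma_r,
            cutpoints=np.asarray(pop.cutpoints, dtype=float),
            alpha0=float(rng.normal(pop.alpha0_mean, pop.alpha0_sd)),
            delta=pop.delta,
            sigma_rt=pop.sigma_rt,
            logk_delay=float(rng.normal(pop.logk_delay_mean, pop.logk_delay_sd)),
            logk_prob=float(rng.normal(pop.logk_prob_mean, pop.logk_prob_sd)),
            choice_sharpness=pop.choice_sharpness,
            esi_factors=rng.normal(size=3),
            age=float(rng.normal(pop.age_mean, pop.age_sd)),
            sex="female" if rng.random() < pop.p_female else "male",
            ethnicity=ETHNICITY_CODES[int(rng.choice(
                len(ETHNICITY_CODES), p=np.asarray(pop.ethnicity_probs)))],
            galleries=pop.galleries,
        ))
    return agents


def _prev_risky_loss(prev: Optional[TrialRecord]) -> bool:
    return (prev is not None and prev.choice == "stay"
            and prev.offer.is_risky and prev.outcome_class == BAD)


def agent_decide(
    agent: AgentParams,
    offer: Offer,
    prev: Optional[TrialRecord],
    rng: np.random.Generator,
    config: Optional[SessionConfig] = None,
) -> tuple[float, str, float]:
    """Stay/skip decision on one offer.

    The presented delay is the offer's mid value (the center of the
    delay window the subject sees). The linear predictor is
    beta*(tau_g - d), shifted by gamma_i + eta*V_prev when the previous
    trial was a risky loss (V_prev = tau - realized delay of that
    trial). Decision RT is log-normal with post-loss slowing.
    """
    d = offer.mid
    L = agent.beta * (agent.threshold_for(offer.gallery) - d)
    loss = _prev_risky_loss(prev)
    if loss:
        v_prev = agent.threshold_for(prev.offer.gallery) - prev.realized_delay
        L += agent.gamma + agent.eta * v_prev
    p_stay = float(_logistic(L))
    choice = "stay" if rng.random() < p_stay else "skip"
    rt = float(np.exp(agent.alpha0 + agent.delta * loss
                      + rng.normal(0.0, agent.sigma_rt)))
    return p_stay, choice, rt


def travel_time(agent: AgentParams, config: SessionConfig, rng: np.random.Generator) -> float:
    """Travel-task duration: clicks x log-normal per-click latency."""
    lat = np.exp(np.log(config.click_seconds) + rng.normal(0.0, 0.2, config.travel_clicks))
    return float(lat.sum())


def agent_rate(agent: AgentParams, trial: TrialRecord, rng: np.random.Generator) -> int:
    """Rate the just-watched video on 1-4 via an ordered-latent draw."""
    if trial.choice != "stay" or trial.realized_delay is None:
        raise ValueError("ratings are only produced on stay trials")
    v = agent.threshold_for(trial.offer.gallery) - trial.realized_delay
    bad = trial.outcome_class == BAD
    latent = (agent.rating_mu_for(trial.offer.gallery)
              + agent.rating_a * v
              + agent.rating_b * bad
              + agent.rating_c * v * bad
              + rng.normal(0.0, agent.sigma_r))
    return 1 + int(np.sum(latent > agent.cutpoints))


# --------------------------------------------------------------------------
# Externalizing Spectrum Inventory (item-response generator)

SUBFACTORS = ("general_disinhibition", "substance_abuse", "callous_aggression")
PROBLEM_SUBSCALES = ("alcohol", "marijuana", "drug")


@dataclass(frozen=True)
class ItemDesign:
    """Assignment of 100 binary items to subfactors and problem subscales.

    Problem-subscale items (within substance abuse) carry high
    difficulty so most agents endorse none of them, reproducing the
    zero-inflation the retention rule exists for.
    """

    subfactor: np.ndarray        # (100,) int codes into SUBFACTORS
    subscale: np.ndarray         # (100,) object: '' or a PROBLEM_SUBSCALES entry
    difficulty: np.ndarray       # (100,) item difficulty c_j
    loading_E: np.ndarray        # (3,) a_f
    loading_factor: np.ndarray   # (3,) b_f

    def __post_init__(self) -> None:
        for arr in (self.subfactor, self.subscale, self.difficulty):
            if len(arr) != 100:
                raise ValueError("item design must cover exactly 100 items")
        sub_ok = np.isin(self.subscale[self.subscale != ""], PROBLEM_SUBSCALES)
        if not sub_ok.all():
            raise ValueError("unknown problem subscale label")
        if ((self.subscale != "") & (self.subfactor != 1)).any():
            raise ValueError("problem subscales must sit inside substance abuse")

    def items_for_subfactor(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.subfactor == f)

    def items_for_subscale(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.subscale == name)


def default_item_design(loading_E: float = 1.0, loading_factor: float = 0.8) -> ItemDesign:
    """100 items: 40 disinhibition, 36 substance abuse (6 per problem
    subscale), 24 callous aggression."""
    subfactor = np.concatenate([
        np.zeros(40, dtype=int), np.ones(36, dtype=int), np.full(24, 2, dtype=int)])
    subscale = np.array([""] * 100, dtype=object)
    subscale[58:64] = "alcohol"
    subscale[64:70] = "marijuana"
    subscale[70:76] = "drug"
    difficulty = np.empty(100)
    ordinary = subscale == ""
    difficulty[ordinary] = np.linspace(0.5, 2.5, int(ordinary.sum()))
    difficulty[~ordinary] = np.linspace(3.6, 4.4, int((~ordinary).sum()))
    return ItemDesign(
        subfactor=subfactor,
        subscale=subscale,
        difficulty=difficulty,
        loading_E=np.full(3, loading_E),
        loading_factor=np.full(3, loading_factor),
    )


def generate_esi_responses(
    agent: AgentParams, design: ItemDesign, rng: np.random.Generator
) -> np.ndarray:
    """Binary item responses: P(endorse j) = logistic(a_f E + b_f F_f - c_j)."""
    a = design.loading_E[design.subfactor]
    b = design.loading_factor[design.subfactor]
    f = agent.esi_factors[design.subfactor]
    p = _logistic(a * agent.E + b * f - design.difficulty)
    return (rng.random(100) < p).astype(int)


# --------------------------------------------------------------------------
# Delay / probability discounting task

@dataclass(frozen=True)
class DiscountMenu:
    """Binary-choice menu: a titration grid of smaller-sooner amounts
    against a fixed larger-later (or risky) amount per condition."""

    amount: float = 10.0
    delays: Sequence[float] = (1.0, 2.0, 7.0, 14.0, 30.0, 90.0, 180.0)   # days
    probabilities: Sequence[float] = (0.95, 0.9, 0.75, 0.5, 0.25, 0.1)
    grid: Sequence[float] = tuple(np.round(np.arange(0.5, 10.01, 0.5), 2))

    def __post_init__(self) -> None:
        amounts = list(self.grid) + [self.amount]
        if min(amounts) < 0.5 or max(amounts) > 10.0:
            raise ValueError("amounts must lie in [$0.50, $10]")


def odds_against(p: float) -> float:
    """theta = (1 - p) / p, the transform putting probability
    discounting in hyperbolic form."""
    return (1.0 - p) / p


def discounted_value(amount: float, k: float, x: float) -> float:
    """Hyperbolic present value A / (1 + k x), x = delay or odds-against."""
    return amount / (1.0 + k * x)


def generate_discounting_responses(
    agent: AgentParams, menu: DiscountMenu, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate the binary choice table for one agent.

    P(choose later/risky) = logistic(sharpness * (discounted A - S)).
    """
    k = float(np.exp(agent.logk_delay))
    h = float(np.exp(agent.logk_prob))
    rows = []
    for kind, conditions, rate in (("delay", menu.delays, k),
                                   ("probability", menu.probabilities, h)):
        for cond in conditions:
            x = cond if kind == "delay" else odds_against(cond)
            dv = discounted_value(menu.amount, rate, x)
            for s in menu.grid:
                p_later = float(_logistic(agent.choice_sharpness * (dv - s)))
                rows.append({
                    "subject_id": agent.subject_id,
                    "kind": kind,
                    "condition": cond,
                    "sooner_amount": s,
                    "later_amount": menu.amount,
                    "choose_later": int(rng.random() < p_later),
                })
    return pd.DataFrame(rows)


__all__ = [
    "AgentParams", "PopulationConfig", "sample_population",
    "agent_decide", "agent_rate", "travel_time",
    "ItemDesign", "default_item_design", "generate_esi_responses",
    "DiscountMenu", "generate_discounting_responses",
    "odds_against", "discounted_value",
    "SUBFACTORS", "PROBLEM_SUBSCALES", "ETHNICITY_CODES",
]
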