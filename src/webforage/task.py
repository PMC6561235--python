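"""Simulator for the risk variant of the Web-Surf foraging task.

Subjects cycle through four video galleries in a fixed order under a
40-minute clock. Each encounter presents an offer of three possible
delays (identical on non-risky trials); the subject stays through the
delay for a short video reward, or skips to the next gallery. On risky
trials the realized delay is hidden until the subject commits to stay.
Receipt of the low delay is a "good" outcome, the high delay a "bad"
outcome (a risky loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

GOOD, MID, BAD, NONRISK, NONE = "good", "mid", "bad", "nonrisk", "none"
OUTCOME_CLASSES = (GOOD, MID, BAD, NONRISK, NONE)

DEFAULT_GALLERIES = ("kittens", "dance", "landscapes", "bike_accidents")


@dataclass(frozen=True)
class SessionConfig:
    """Task parameters for one session.

    Delays are integer seconds in [delay_min, delay_max]; risky offers
    present three equally spaced delays (spread = high - low must be
    even so the mid delay is an integer). Outcome probabilities over
    (low, mid, high) default to uniform thirds: subjects are never told
    them, and the expected-value formula downstream assumes equal
    likelihood.
    """

    session_minutes: float = 40.0
    galleries: Sequence[str] = DEFAULT_GALLERIES
    delay_min: int = 3
    delay_max: int = 30
    risky_fraction: float = 0.6
    spread_choices: Sequence[int] = (4, 8, 12, 16, 20)
    outcome_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
    travel_clicks: int = 5
    click_seconds: float = 0.6
    video_seconds: float = 4.0
    rating_seconds: float = 1.0

    def __post_init__(self) -> None:
        if self.delay_min < 1:
            raise ValueError("delay_min must be >= 1")
        if self.delay_max <= self.delay_min:
            raise ValueError("delay_max must exceed delay_min")
        if not 0.0 <= self.risky_fraction <= 1.0:
            raise ValueError("risky_fraction must lie in [0, 1]")
        if self.travel_clicks < 1:
            raise ValueError("travel_clicks must be >= 1")
        if len(self.galleries) != 4:
            raise ValueError("exactly four galleries are required")
        for s in self.spread_choices:
            if s % 2 != 0:
                raise ValueError(
                    f"spread {s} is odd: non-integer mid delays are not allowed"
                )
            if s <= 0:
                raise ValueError("spreads must be positive")
            if self.delay_min + s > self.delay_max:
                raise ValueError(
                    f"spread {s} leaves no feasible low delay in "
                    f"[{self.delay_min}, {self.delay_max}]"
                )
        probs = np.asarray(self.outcome_probs, dtype=float)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("outcome_probs must be three non-negative values summing to 1")

    @property
    def session_seconds(self) -> float:
        return self.session_minutes * 60.0


@dataclass(frozen=True)
class Offer:
    """One serial deal: a gallery and three possible integer delays."""

    gallery: str
    low: int
    mid: int
    high: int

    def __post_init__(self) -> None:
        if not (self.low <= self.mid <= self.high):
            raise ValueError("offer delays must satisfy low <= mid <= high")
        if self.low < self.high and not (self.low < self.mid < self.high):
            raise ValueError("risky offers require low < mid < high")

    @property
    def is_risky(self) -> bool:
        return self.low < self.high

    @property
    def spread(self) -> int:
        return self.high - self.low

    @property
    def delays(self) -> tuple[int, int, int]:
        return (self.low, self.mid, self.high)

    @property
    def mean_delay(self) -> float:
        return (self.low + self.mid + self.high) / 3.0


@dataclass
class TrialRecord:
    """One offer encounter.

    `realized_delay`, `outcome_class` and `rating` are None on skip
    trials: the true delay of a risky offer is revealed only when the
    subject stays, and ratings are collected only after a video.
    """

    subject_id: str
    trial_index: int
    offer: Offer
    choice: str  # "stay" | "skip"
    realized_delay: Optional[int]
    outcome_class: Optional[str]
    rating: Optional[int]
    decision_rt: float
    clock_start: float
    clock_end: float

    def __post_init__(self) -> None:
        if self.choice not in ("stay", "skip"):
            raise ValueError(f"choice must be stay/skip, got {self.choice!r}")
        if self.choice == "stay":
            if self.realized_delay is None or self.rating is None:
                raise ValueError("stay trials require realized_delay and rating")
            if self.realized_delay not in self.offer.delays:
                raise ValueError("realized delay must be one of the offered delays")
            if self.outcome_class not in (GOOD, MID, BAD, NONRISK):
                raise ValueError(f"bad outcome class {self.outcome_class!r} on stay")
            if not 1 <= self.rating <= 4:
                raise ValueError("rating must be an integer 1-4")
        else:
            if self.realized_delay is not None or self.rating is not None:
                raise ValueError("skip trials carry no realized delay or rating")
            if self.outcome_class not in (NONE, None):
                raise ValueError("skip trials have outcome class 'none'")
            self.outcome_class = NONE


def generate_offer(rng: np.random.Generator, config: SessionConfig, gallery: str) -> Offer:
    """Draw one offer for `gallery`.

    Risky with probability ``config.risky_fraction``; a risky offer
    samples a spread from ``spread_choices`` and then a low delay
    uniformly so that high = low + spread stays within range; the mid
    delay is the arithmetic midpoint. Non-risky offers sample a single
    delay uniformly and repeat it three times.
    """
    if rng.random() < config.risky_fraction:
        spread = int(config.spread_choices[rng.integers(len(config.spread_choices))])
        lo_max = config.delay_max - spread
        if lo_max < config.delay_min:
            raise ValueError(f"no feasible low delay for spread {spread}")
        low = int(rng.integers(config.delay_min, lo_max + 1))
        return Offer(gallery, low, low + spread // 2, low + spread)
    d = int(rng.integers(config.delay_min, config.delay_max + 1))
    return Offer(gallery, d, d, d)


def realize_outcome(
    rng: np.random.Generator,
    offer: Offer,
    outcome_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[int, str]:
    """Realize the delay of a stayed offer and classify its framing.

    On risky trials the delay is drawn from {low, mid, high} (uniform by
    default); the low delay is a good outcome, the high delay a bad one.
    Non-risky trials always deliver the known delay.
    """
    if not offer.is_risky:
        return offer.mid, NONRISK
    idx = rng.choice(3, p=np.asarray(outcome_probs, dtype=float))
    delay = offer.delays[idx]
    return delay, (GOOD, MID, BAD)[idx]


def run_session(agent, config: SessionConfig, seed) -> list[TrialRecord]:
    """Simulate a full session for one synthetic subject.

    Galleries cycle in the fixed order. Each trial consumes decision
    time, plus (on stays) the realized delay, the video, and rating
    input, plus the travel task (clicks x per-click latency drawn from
    the agent's latency model). A new trial starts whenever the clock
    has not yet exceeded the session length, so the final trial may
    overrun it. Identical (agent, config, seed) give identical logs.
    """
    from . import agents as _agents  # deferred: agents depends on this module

    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    clock = 0.0
    prev: Optional[TrialRecord] = None
    gallery_idx = 0
    trial_index = 0
    while clock < config.session_seconds:
        gallery = config.galleries[gallery_idx % 4]
        offer = generate_offer(rng, config, gallery)
        _, choice, rt = _agents.agent_decide(agent, offer, prev, rng, config=config)
        clock_start = round(clock, 6)
        elapsed = rt
        realized = outcome = rating = None
        if choice == "stay":
            realized, outcome = realize_outcome(rng, offer, config.outcome_probs)
            elapsed += realized + config.video_seconds + config.rating_seconds
        elapsed += _agents.travel_time(agent, config, rng)
        clock = clock_start + elapsed
        rec = TrialRecord(
            subject_id=agent.subject_id,
            trial_index=trial_index,
            offer=offer,
            choice=choice,
            realized_delay=realized,
            outcome_class=outcome,
            rating=1,  # placeholder; replaced below for stays
            decision_rt=round(rt, 6),
            clock_start=clock_start,
            clock_end=round(clock, 6),
        ) if choice == "stay" else TrialRecord(
            subject_id=agent.subject_id,
            trial_index=trial_index,
            offer=offer,
            choice=choice,
            realized_delay=None,
            outcome_class=NONE,
            rating=None,
            decision_rt=round(rt, 6),
            clock_start=clock_start,
            clock_end=round(clock, 6),
        )
        if choice == "stay":
            rec.rating = _agents.agent_rate(agent, rec, rng)
        records.append(rec)
        prev = rec
        gallery_idx += 1
        trial_index += 1
    return records


__all__ = [
    "SessionConfig",
    "Offer",
    "TrialRecord",
    "generate_offer",
    "realize_outcome",
    "run_session",
    "GOOD",
    "MID",
    "BAD",
    "NONRISK",
    "NONE",
    "OUTCOME_CLASSES",
    "DEFAULT_GALLERIES",
]
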