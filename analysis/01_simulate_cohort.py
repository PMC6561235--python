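#!/usr/bin/env python
"""Simulate the study cohort: 105 synthetic subjects, 40-minute
foraging sessions, questionnaires, and discounting tasks.

Writes session logs and generative ground truth under results/cohort/.
Later analysis steps reload these files, so the whole chain runs off
one deterministic artifact set.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import webforage as wf
from webforage import io as wio

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    study = wf.simulate_study(wf.PopulationConfig(), seed=SEED)
    records = [r for recs in study.sessions.values() for r in recs]
    wio.write_session_log(records, OUT / "sessions.csv")
    wio.truth_frame(study.agents).to_csv(OUT / "truth.csv", index=False)
    esi = pd.DataFrame(study.esi_responses).T
    esi.index.name = "subject_id"
    esi.columns = [f"item_{i:03d}" for i in range(esi.shape[1])]
    esi.reset_index().to_csv(OUT / "esi_items.csv", index=False)
    study.discount_choices.to_csv(OUT / "discounting_choices.csv", index=False)
    study.demographics.to_csv(OUT / "demographics.csv", index=False)

    n_trials = len(records)
    stay = np.mean([r.choice == "stay" for r in records])
    risky = np.mean([r.offer.is_risky for r in records])
    print(f"simulated {len(study.agents)} subjects, {n_trials} encounters "
          f"({n_trials / len(study.agents):.0f} per subject)")
    print(f"stay rate {stay:.2f}, risky-offer fraction {risky:.2f}")
    print(f"artifacts -> {OUT}")


if __name__ == "__main__":
    main()
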