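#!/usr/bin/env python
"""Simulate the study-shaped cohort and record its generative ground truth.

Saline vs paroxetine, n = 12/group, 4 baseline + 12 dosing + 13
discontinuation days of 10 s PIR epochs.  Writes the renewal-theory
expectations (dark/light percent-asleep and bout-bin shares per period)
that later scripts should recover, plus basic cohort facts.
"""

import json
from pathlib import Path

import cagerhythm as cr

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    design = cr.default_study_design()
    group_params = {g: cr.default_sim_params(g) for g in ("saline", "paroxetine")}
    cohort = cr.simulate_cohort(group_params, design, SEED)

    truth = {
        group: {
            f"{phase}_{period}": cr.ground_truth_summary(params, phase, period)
            for phase in ("light", "dark")
            for period in ("baseline", "dosing", "discontinuation")
        }
        for group, params in group_params.items()
    }
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    n_epochs = sum(len(t) for t in cohort.traces.values())
    print(f"simulated {len(cohort.traces)} animals, {n_epochs:,} epochs "
          f"({design.n_days('sal01')} days each), master seed {SEED}")
    for group, params in group_params.items():
        gt = cr.ground_truth_summary(params, "dark", "dosing")
        print(f"  {group:<11} expected dosing dark sleep "
              f"{gt['pct_asleep']:5.2f}% of phase time")
    print(f"wrote {OUT / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
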