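#!/usr/bin/env python
"""Generate the synthetic experiment at full study scale.

20 participants, two scenes (active / passive), 150 trials per scene
(5 locations x 2 patterns x 15 repetitions) at 90 Hz, with blinks, step
artifacts and gaze drift injected at the default rates.  Writes the raw
long-format traces and the per-trial ground truth.
"""

import argparse
from pathlib import Path

from pupilvr.synth import SynthConfig, generate_experiment
from pupilvr.trace_io import write_trials

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = SynthConfig(seed=args.seed)
    records, truth = generate_experiment(cfg)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    write_trials(records, scratch / "traces.csv")
    truth.to_frame().to_csv(scratch / "ground_truth.csv", index=False)

    tdf = truth.to_frame()
    n_blink = int((tdf["n_blinks"] > 0).sum())
    n_step = int((tdf["n_artifacts"] > 0).sum())
    n_drift = int(tdf["gaze_drift"].sum())
    print(f"generated {len(records)} trials for {cfg.n_subjects} subjects "
          f"(seed {cfg.seed})")
    print(f"injected artifacts: {n_blink} trials with blinks, "
          f"{n_step} with step artifacts, {n_drift} with gaze drift")
    print(f"wrote {scratch / 'traces.csv'} and {scratch / 'ground_truth.csv'}")


if __name__ == "__main__":
    main()
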