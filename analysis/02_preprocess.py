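#!/usr/bin/env python
"""Run the artifact-rejection cascade on the simulated traces.

Applies blink interpolation, baseline correction, 4-Hz zero-phase
filtering, then the velocity / PCA-distance / gaze rejection rules and the
30% participant-exclusion rule.  Writes the cleaned traces and the
rejection report, and prints the per-scene rejection ratios.
"""

from pathlib import Path

import pandas as pd

from pupilvr.preprocess import run_preprocessing
from pupilvr.trace_io import read_trials, write_report, write_trials

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    records = read_trials(scratch / "traces.csv")
    clean, report = run_preprocessing(records)
    write_trials(clean, scratch / "clean.csv")
    write_report(report, results / "rejection_report.csv")

    print(f"{len(clean)}/{len(records)} trials survive the cascade")
    print("rejections by stage:", report.stage_counts)
    ratios = (
        report.trials.assign(rejected=report.trials["stage"] != "")
        .groupby("scene")["rejected"].mean()
    )
    for scene, ratio in ratios.items():
        print(f"  {scene}: {ratio:.1%} of trials rejected")
    excluded = report.participants.loc[report.participants.excluded, "subject"]
    print(f"excluded participants: {list(excluded) or 'none'}")


if __name__ == "__main__":
    main()
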