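#!/usr/bin/env python
"""Three-way repeated-measures ANOVAs on the extracted features.

For each of the early component, late-component AUC, and mean vertical
gaze: aggregate trials to subject-by-cell means, run the
scene x location x pattern rmANOVA with Greenhouse-Geisser handling, and
run Holm-corrected post hoc pairwise comparisons on location.  Writes one
ANOVA table and one post hoc table per feature.
"""

from pathlib import Path

from pupilvr.stats import aggregate_cells, posthoc_pairwise, rm_anova
from pupilvr.trace_io import read_features, write_report

ROOT = Path(__file__).resolve().parents[1]

FEATURES = {"early": "early_mm", "auc": "auc_mm", "gaze_y": "mean_gaze_y_deg"}


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    feats = read_features(ROOT / "scratch" / "features.csv")

    for name, column in FEATURES.items():
        table = aggregate_cells(feats, column)
        res = rm_anova(table, feature=name)
        write_report(res, results / f"anova_{name}.csv")
        posthoc = posthoc_pairwise(table, "location")
        posthoc.to_csv(results / f"posthoc_location_{name}.csv", index=False)

        print(f"\n=== {name} ({column}), n = {table.n_subjects} subjects ===")
        cols = ["effect", "df_num_reported", "df_den_reported", "F", "p", "partial_eta2"]
        print(res.table[cols].round(4).to_string(index=False))
        sig = posthoc[posthoc.p_holm < 0.05]
        if len(sig):
            print("significant location pairs (Holm):")
            print(sig[["level_a", "level_b", "mean_diff", "t", "p_holm"]].round(4)
                  .to_string(index=False))
        else:
            print("no significant location pairs after Holm correction")


if __name__ == "__main__":
    main()
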