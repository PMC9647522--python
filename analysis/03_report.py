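"""Condition-level summaries and significance tests.

Aggregates the per-organelle event records and per-ROI remaining-area
fractions from 02_analyze.py into mean ± SEM tables and the wild-type vs
knockout remaining-area contrast, and plots the summary bars.
Writes results/summary.csv, results/tests.csv and results/remaining_area.png.
"""

from pathlib import Path

import pandas as pd

from mitoholo import stats_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    events = pd.read_csv(RESULTS / "events.csv")
    remaining = pd.read_csv(RESULTS / "remaining_area.csv")

    summaries = []
    for metric in ("residual_potential", "delay_s"):
        sub = events.dropna(subset=[metric])
        if len(sub):
            summaries += stats_report.group_summary(sub[metric], sub["condition"], metric=metric)
    summaries += stats_report.group_summary(
        remaining["remaining_area"], remaining["condition"], metric="remaining_area_fraction"
    )
    summary_df = stats_report.summaries_to_frame(summaries)
    summary_df.to_csv(RESULTS / "summary.csv", index=False)
    print(summary_df.to_string(index=False))

    wt = remaining.loc[remaining["condition"] == "WT_FERUTININ", "remaining_area"]
    ko = remaining.loc[remaining["condition"] == "KO_FERUTININ", "remaining_area"]
    contrast = stats_report.compare_groups({"WT": wt.to_numpy(), "KO": ko.to_numpy()}, test="t_test")
    anova = stats_report.compare_groups(
        {c: g["remaining_area"].to_numpy() for c, g in remaining.groupby("condition")},
        test="one_way_anova",
    )
    tests_df = stats_report.tests_to_frame([contrast, anova])
    tests_df.to_csv(RESULTS / "tests.csv", index=False)
    print("\n" + tests_df.to_string(index=False))

    ra_summaries = [s for s in summaries if s.metric == "remaining_area_fraction"]
    stats_report.plot_summary_bars(ra_summaries, RESULTS / "remaining_area.png")
    print("\nsummary -> results/summary.csv; tests -> results/tests.csv; "
          "figure -> results/remaining_area.png")


if __name__ == "__main__":
    main()
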