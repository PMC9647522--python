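"""Condition-level summaries and significance tests.

Measurements are aggregated per ROI/track (the unit of analysis of the
assay: n = mitochondrial regions or organelles, N = experiments; per-movie
nesting is reported but not modeled). Summaries are mean ± SEM; contrasts
use a one-way ANOVA or a two-sided t-test (equal-variance by default, Welch
by flag) with the conventional star codes *p<0.05, **p<0.01, ***p<0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TERMINAL_WINDOW = 3


@dataclass(frozen=True)
class GroupSummary:
    group: str
    metric: str
    n: int
    mean: float
    sem: float
    flags: str = ""


@dataclass(frozen=True)
class TestResult:
    test: str  # {"one_way_anova", "t_test"}
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    stars: str


def star_code(p: float) -> str:
    """Significance stars: *p<0.05, **p<0.01, ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def remaining_area(area_fraction: np.ndarray, terminal_window: int = DEFAULT_TERMINAL_WINDOW) -> float:
    """Mean area fraction over the final frames — the remaining-area statistic.

    Near 0 when organelles permeabilized and vanished from the RI channel,
    near 1 when they depolarized but stayed intact.
    """
    a = np.asarray(area_fraction, dtype=float)
    if terminal_window < 1 or terminal_window > len(a):
        raise ValueError(f"terminal window {terminal_window} exceeds trace length {len(a)}")
    return float(a[-terminal_window:].mean())


def group_summary(values, labels, metric: str = "") -> list[GroupSummary]:
    """Per-group mean and SEM (= sd / sqrt(n), sample sd with ddof=1).

    A single-valued group gets SEM 0 by the sd=0 convention, flagged "n=1".
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("no values to summarize")
    out = []
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size == 0:
            raise ValueError(f"empty group {g!r}")
        if v.size == 1:
            out.append(GroupSummary(str(g), metric, 1, float(v[0]), 0.0, flags="n=1"))
        else:
            sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
            out.append(GroupSummary(str(g), metric, int(v.size), float(v.mean()), sem))
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def compare_groups(
    groups: dict[str, np.ndarray],
    test: str = "t_test",
    equal_var: bool = True,
) -> TestResult:
    """One-way ANOVA across >=2 groups, or a two-sided t-test for 2 groups."""
    names = tuple(groups.keys())
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(v.size == 0 for v in data):
        raise ValueError("every group needs at least one value")
    if all(np.ptp(v) == 0 for v in data) and len({float(v[0]) for v in data}) == 1:
        raise ValueError("zero variance in all groups: test undefined")
    if test == "one_way_anova":
        if len(data) < 2:
            raise ValueError("ANOVA requires at least two groups")
        stat, p = stats.f_oneway(*data)
    elif test == "t_test":
        if len(data) != 2:
            raise ValueError("t-test requires exactly two groups")
        stat, p = stats.ttest_ind(data[0], data[1], equal_var=equal_var)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(test=test, groups=names, statistic=float(stat), p_value=float(p), stars=star_code(float(p)))


def tests_to_frame(results: list[TestResult]) -> pd.DataFrame:
    rows = [
        dict(test=r.test, groups=" vs ".join(r.groups), statistic=r.statistic, p_value=r.p_value, stars=r.stars)
        for r in results
    ]
    return pd.DataFrame(rows)


def plot_summary_bars(summaries: list[GroupSummary], path) -> None:
    """Bar-with-SEM plot of group summaries (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    xs = np.arange(len(summaries))
    ax.bar(xs, [s.mean for s in summaries], yerr=[s.sem for s in summaries], capsize=4)
    ax.set_xticks(xs)
    ax.set_xticklabels([s.group for s in summaries], rotation=30, ha="right")
    ax.set_ylabel(summaries[0].metric if summaries else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_traces(traces, path, field: str = "tmrm_norm") -> None:
    """Overlay of per-ROI traces (normalized TMRM or area fraction)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    for tr in traces:
        y = getattr(tr, field)
        if y is None:
            continue
        ax.plot(tr.times, y, lw=0.8, alpha=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(field)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
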