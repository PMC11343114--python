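"""Per-animal aggregation and group statistics.

The animal is the statistical unit throughout: cell- or spot-level tables
are first averaged within animal, and groups are compared with unpaired
two-sided t-tests (Student by default, Welch by flag).  Summaries are
reported as mean ± SEM with percent change relative to the reference
group; no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "aggregate_per_animal",
    "unpaired_t_test",
    "summarize",
    "percent_change",
    "build_report",
    "ALPHA",
]

#: significance level of the report (two-sided)
ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    percent_change: float
    variant: str = "student"

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def summarize(values) -> tuple[float, float, int]:
    """Mean, SEM (sample sd / √n; NaN for n < 2) and n."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no values")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return mean, sem, n


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """100 · (comparison − reference) / reference."""
    if reference_mean == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def unpaired_t_test(
    values_a, values_b, variant: str = "student",
    metric: str = "", group_a: str = "A", group_b: str = "B",
) -> GroupComparison:
    """Two-sided unpaired t-test between two groups of per-animal values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            # identical degenerate groups: no evidence of difference
            res_t, res_df, res_p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            raise ValueError("zero variance in both groups")
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
        res_t, res_p = float(res.statistic), float(res.pvalue)
        res_df = float(res.df)
    mean_a, sem_a, _ = summarize(a)
    mean_b, sem_b, _ = summarize(b)
    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        values_a=a, values_b=b,
        mean_a=mean_a, mean_b=mean_b, sem_a=sem_a, sem_b=sem_b,
        t=res_t, df=res_df, p=res_p,
        percent_change=percent_change(mean_a, mean_b) if mean_a != 0 else float("nan"),
        variant=variant,
    )


def aggregate_per_animal(
    table: pd.DataFrame,
    value_col: str,
    animal_col: str = "animal",
    keep_cols: tuple[str, ...] = ("group", "region", "age"),
) -> pd.DataFrame:
    """One value per animal: the mean over that animal's records.

    The subsequent group mean is therefore the *unweighted* mean of
    animal means, not the pooled record mean.
    """
    if animal_col not in table.columns:
        raise ValueError(f"records lack an {animal_col!r} column")
    keep = [c for c in keep_cols if c in table.columns]
    grouped = table.groupby([animal_col] + keep, sort=True)[value_col].mean().reset_index()
    return grouped.rename(columns={value_col: "value"})


def build_report(
    animal_table: pd.DataFrame,
    group_pairs: list[tuple[str, str]] | None = None,
    variant: str = "student",
    out_dir: str | Path | None = None,
    plot: bool = False,
    config_hash: str = "",
) -> pd.DataFrame:
    """Figure-style summary: one row per (metric, region, age, group pair).

    ``animal_table`` columns: animal, group, metric, value, optionally
    region and age.  Output ordering and float formatting are fixed, so
    regenerating the report from the same tables is byte-identical.
    """
    required = {"animal", "group", "metric", "value"}
    if not required <= set(animal_table.columns):
        raise ValueError(f"animal table needs columns {sorted(required)}")
    df = animal_table.copy()
    for c in ("region", "age"):
        if c not in df.columns:
            df[c] = "all"
    groups = sorted(df["group"].unique())
    if group_pairs is None:
        group_pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]

    rows = []
    for (metric, region, age), sub in df.groupby(["metric", "region", "age"], sort=True):
        for ga, gb in group_pairs:
            va = sub.loc[sub["group"] == ga, "value"].to_numpy()
            vb = sub.loc[sub["group"] == gb, "value"].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                continue
            try:
                cmp_ = unpaired_t_test(va, vb, variant=variant, metric=metric,
                                       group_a=ga, group_b=gb)
            except ValueError as e:
                warnings.warn(f"{metric}/{region}/{age} {ga} vs {gb}: {e}")
                continue
            rows.append({
                "metric": metric, "region": region, "age": age,
                "group_a": ga, "group_b": gb,
                "n_a": len(va), "n_b": len(vb),
                "mean_a": cmp_.mean_a, "sem_a": cmp_.sem_a,
                "mean_b": cmp_.mean_b, "sem_b": cmp_.sem_b,
                "t": cmp_.t, "df": cmp_.df, "p": cmp_.p,
                "percent_change": cmp_.percent_change,
                "significant": cmp_.significant,
            })
    report = pd.DataFrame(rows, columns=[
        "metric", "region", "age", "group_a", "group_b", "n_a", "n_b",
        "mean_a", "sem_a", "mean_b", "sem_b", "t", "df", "p",
        "percent_change", "significant"])
    report = report.sort_values(["metric", "region", "age", "group_a", "group_b"],
                                kind="mergesort").reset_index(drop=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "group_report.csv"
        with open(path, "w", newline="") as fh:
            if config_hash:
                fh.write(f"# config={config_hash}\n")
            fh.write("# unpaired two-sided t-tests, alpha=0.05, "
                     "no multiple-testing correction applied\n")
            report.to_csv(fh, index=False, float_format="%.6g")
        if plot:
            _plot_report(df, report, out)
    return report


def _plot_report(animal_table: pd.DataFrame, report: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, sub in animal_table.groupby("metric", sort=True):
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        groups = sorted(sub["group"].unique())
        for i, g in enumerate(groups):
            v = sub.loc[sub["group"] == g, "value"].to_numpy()
            mean, sem, _ = summarize(v)
            ax.bar(i, mean, width=0.6, color="0.8", edgecolor="k",
                   yerr=0 if np.isnan(sem) else sem, capsize=4)
            ax.plot(np.full(v.size, i) + np.linspace(-0.15, 0.15, v.size), v,
                    "o", color="k", ms=4)
        ax.set_xticks(range(len(groups)), groups)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(out / f"{metric}.svg")
        plt.close(fig)
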