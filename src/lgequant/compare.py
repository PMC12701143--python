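"""Multi-task statistical aggregation and report exports.

Up to 20 tasks can be compared at once.  Clinical results are collected
into a long-format table (one row per case × task) that preserves case
identity, so per-case trajectories across tasks — e.g. scar percentage
for n = 2..7 — can be tracked as lines over a boxplot.  Cases can be
filtered by their artifact label before aggregation, and each case can
be assigned the candidate task whose value lies closest to a reference
(gold) task.

Summary statistics use the linear-interpolation quartile convention and
the unbiased (ddof=1) standard deviation; boxplot whiskers follow the
1.5·IQR rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import InputError, UsageError
from .scar import ClinicalResults, TaskResult

__all__ = [
    "SUBGROUPS",
    "ResultsTable",
    "aggregate",
    "closest_to_reference",
    "export_report",
]

SUBGROUPS = ("all", "artifact", "no_artifact")
FLOAT_FORMAT = "%.6f"


@dataclass
class ResultsTable:
    """Long-format clinical results: one row per (case, task)."""

    frame: pd.DataFrame

    COLUMNS = ("case", "task", "artifact") + ClinicalResults.FIELDS

    @staticmethod
    def from_results(
        results: list[TaskResult], artifact_labels: dict[str, bool] | None = None
    ) -> "ResultsTable":
        artifact_labels = artifact_labels or {}
        rows = []
        for res in results:
            row = {
                "case": res.case_id,
                "task": res.task.label,
                "artifact": bool(artifact_labels.get(res.case_id, False)),
            }
            row.update(res.clinical.as_dict())
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(ResultsTable.COLUMNS))
        frame = frame.sort_values(["case", "task"], kind="stable").reset_index(drop=True)
        if frame.duplicated(["case", "task"]).any():
            raise InputError("duplicate (case, task) rows in results table")
        if frame["task"].nunique() > 20:
            raise UsageError("at most 20 tasks can be compared")
        return ResultsTable(frame)

    def subgroup(self, which: str) -> pd.DataFrame:
        if which not in SUBGROUPS:
            raise UsageError(f"unknown subgroup {which!r}; expected one of {SUBGROUPS}")
        if which == "artifact":
            return self.frame[self.frame["artifact"]]
        if which == "no_artifact":
            return self.frame[~self.frame["artifact"]]
        return self.frame


def aggregate(
    table: ResultsTable, parameter: str, subgroup: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-task summary statistics of one clinical parameter.

    Returns ``(stats, long)``: a per-task table of mean/median/SD/
    quartiles/n over the included cases, and the long-format slice of
    the results table the stats were computed from.  An empty subgroup
    yields n = 0 rows, not an error.
    """
    if parameter not in ClinicalResults.FIELDS:
        raise UsageError(f"unknown clinical parameter {parameter!r}")
    sub = table.subgroup(subgroup)
    long = sub[["case", "task", "artifact", parameter]].reset_index(drop=True)
    records = []
    for task in sorted(table.frame["task"].unique()):
        vals = sub.loc[sub["task"] == task, parameter].to_numpy(dtype=float)
        if vals.size == 0:
            records.append(
                dict(task=task, parameter=parameter, subgroup=subgroup, n=0,
                     mean=np.nan, median=np.nan, sd=np.nan, q1=np.nan, q3=np.nan)
            )
            continue
        records.append(
            dict(
                task=task,
                parameter=parameter,
                subgroup=subgroup,
                n=int(vals.size),
                mean=float(np.mean(vals)),
                median=float(np.median(vals)),
                sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                q1=float(np.percentile(vals, 25)),  # linear interpolation
                q3=float(np.percentile(vals, 75)),
            )
        )
    return pd.DataFrame(records), long


def closest_to_reference(
    table: ResultsTable,
    reference_task: str,
    candidate_tasks: list[str],
    parameter: str,
) -> pd.DataFrame:
    """Per case, the candidate task closest to the reference value.

    Ties are broken by candidate order and flagged.  Cases without a
    reference value are skipped and recorded with a warning row
    (``task`` = None).
    """
    if parameter not in ClinicalResults.FIELDS:
        raise UsageError(f"unknown clinical parameter {parameter!r}")
    frame = table.frame
    pivot = frame.pivot(index="case", columns="task", values=parameter)
    rows = []
    for case in pivot.index:
        if reference_task not in pivot.columns or pd.isna(pivot.loc[case, reference_task]):
            rows.append(dict(case=case, task=None, reference_value=np.nan,
                             value=np.nan, abs_diff=np.nan, tie=False,
                             warning="missing reference value"))
            continue
        ref = float(pivot.loc[case, reference_task])
        best, best_diff = None, np.inf
        diffs = []
        for cand in candidate_tasks:
            if cand not in pivot.columns or pd.isna(pivot.loc[case, cand]):
                continue
            d = abs(float(pivot.loc[case, cand]) - ref)
            diffs.append(d)
            if d < best_diff:
                best, best_diff = cand, d
        if best is None:
            rows.append(dict(case=case, task=None, reference_value=ref,
                             value=np.nan, abs_diff=np.nan, tie=False,
                             warning="no candidate values"))
            continue
        tie = sum(np.isclose(d, best_diff, rtol=0, atol=0) for d in diffs) > 1
        rows.append(dict(case=case, task=best, reference_value=ref,
                         value=float(pivot.loc[case, best]),
                         abs_diff=best_diff, tie=bool(tie), warning=""))
    return pd.DataFrame(rows, columns=["case", "task", "reference_value",
                                       "value", "abs_diff", "tie", "warning"])


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def export_report(
    table: ResultsTable,
    out_dir: Path,
    parameter: str = "scar_percent",
    reference_task: str | None = None,
    subgroup: str = "all",
) -> dict[str, Path]:
    """Write the full report bundle to ``out_dir``.

    Deterministic file names; CSVs use UTF-8, a header row and 6-decimal
    floats, so re-running on unchanged inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths: dict[str, Path] = {}
    paths["results"] = out_dir / "results.csv"
    _write_csv(table.frame, paths["results"])

    stats, long = aggregate(table, parameter, subgroup=subgroup)
    paths["group_stats"] = out_dir / "group_stats.csv"
    _write_csv(stats, paths["group_stats"])
    paths["long"] = out_dir / "long.csv"
    _write_csv(long, paths["long"])

    tasks = sorted(table.frame["task"].unique())
    if reference_task is not None:
        candidates = [t for t in tasks if t != reference_task]
        closest = closest_to_reference(table, reference_task, candidates, parameter)
    else:
        closest = pd.DataFrame(
            columns=["case", "task", "reference_value", "value", "abs_diff", "tie", "warning"]
        )
    paths["closest"] = out_dir / "closest_to_reference.csv"
    _write_csv(closest, paths["closest"])

    paths["boxplot"] = out_dir / f"boxplot_{parameter}.png"
    _boxplot_with_tracking(long, parameter, tasks, paths["boxplot"])
    return paths


def _boxplot_with_tracking(
    long: pd.DataFrame, parameter: str, tasks: list[str], path: Path
) -> None:
    """Multi-boxplot with one faint line per case tracked across tasks."""
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(tasks)), 4.5))
    data = [
        long.loc[long["task"] == t, parameter].to_numpy(dtype=float) for t in tasks
    ]
    if any(len(d) for d in data):
        ax.boxplot(
            [d if len(d) else [np.nan] for d in data],
            tick_labels=tasks,
            whis=1.5,
        )
        for case, grp in long.groupby("case"):
            xs = [tasks.index(t) + 1 for t in grp["task"]]
            order = np.argsort(xs)
            ax.plot(
                np.array(xs)[order],
                grp[parameter].to_numpy(dtype=float)[order],
                color="gray",
                alpha=0.4,
                linewidth=0.8,
            )
    ax.set_ylabel(parameter)
    ax.set_xlabel("task")
    fig.autofmt_xdate(rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
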