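"""Error analysis of DBH estimates against a reference stem table.

For each height interval the suite reports, over the n matched trees with a
successful fit:

* mean absolute error  (1/n) * sum |dbh_est - dbh_true|            [cm]
* mean relative error  (1/n) * sum |dbh_est - dbh_true|/dbh_true   [%]
* sample variances (divisor n-1) of those absolute quantities — and, because
  the convention is genuinely ambiguous, also of the *signed* relative error
* RMSE  sqrt((1/n) * sum (dbh_est - dbh_true)^2)                   [cm]
* Pearson correlation between per-tree credibility and |error|
* sample standard deviation of credibility

The interval with the smallest mean absolute error (ties: smaller RMSE, then
the lower interval) is selected as the final estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dbh_fitting import FitStatus, HeightInterval
from .tree_clustering import TreeInstance

__all__ = [
    "MatchResult",
    "IntervalSummary",
    "ErrorReport",
    "match_trees",
    "per_tree_table",
    "summarize_errors",
    "select_best_interval",
    "build_report",
    "write_report",
    "read_report",
]

PER_TREE_COLUMNS = ["tree_id", "interval", "dbh_est_cm", "dbh_true_cm",
                    "abs_error_cm", "rel_error_pct", "credibility", "status"]

SUMMARY_COLUMNS = ["interval", "n", "mean_abs_error_cm", "var_abs_error",
                   "mean_rel_error_pct", "var_rel_error", "var_rel_error_signed",
                   "rmse_cm", "corr_credibility_abs_error", "credibility_sd"]


@dataclass
class MatchResult:
    pairs: list[tuple[TreeInstance, pd.Series]]
    unmatched_instances: list[TreeInstance]
    unmatched_truth: pd.DataFrame


def match_trees(instances: list[TreeInstance], truth: pd.DataFrame,
                max_dist: float = 1.0) -> MatchResult:
    """Greedy nearest-centroid matching of clusters to reference stems.

    Candidate (instance, stem) pairs within ``max_dist`` in (x, y) are taken
    globally closest-first, each instance and each stem used at most once;
    pairs are returned sorted by tree_id.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if len(instances) == 0 or len(truth) == 0:
        return MatchResult([], list(instances), truth.copy())
    cents = np.array([t.centroid_xy for t in instances])
    txy = truth[["x", "y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(cents[:, None, :] - txy[None, :, :], axis=2)
    ii, jj = np.nonzero(dist <= max_dist)
    inst_ids = np.array([t.instance_id for t in instances])
    order = np.lexsort((jj, inst_ids[ii], dist[ii, jj]))  # closest-first, stable
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[TreeInstance, pd.Series]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((instances[i], truth.iloc[j]))
    pairs.sort(key=lambda p: p[1]["tree_id"])
    unmatched_instances = [t for i, t in enumerate(instances) if i not in used_i]
    unmatched_truth = truth.iloc[[j for j in range(len(truth)) if j not in used_j]]
    return MatchResult(pairs, unmatched_instances, unmatched_truth.copy())


def per_tree_table(matches: MatchResult) -> pd.DataFrame:
    """Flatten matched pairs and their per-interval estimates into one table.

    Relative errors are stored *signed* (percent); absolute values are taken
    only when aggregating, so error-distribution plots keep the sign.
    """
    rows = []
    for inst, truth_row in matches.pairs:
        for interval, est in sorted(inst.dbh_estimates.items(),
                                    key=lambda kv: kv[0].zmin):
            true = float(truth_row["dbh_cm"])
            if est.status is FitStatus.OK:
                err = est.dbh_cm - true
                rows.append([truth_row["tree_id"], interval.label, est.dbh_cm, true,
                             abs(err), 100.0 * err / true,
                             est.circle.credibility, est.status.value])
            else:
                rows.append([truth_row["tree_id"], interval.label, np.nan, true,
                             np.nan, np.nan, np.nan, est.status.value])
    return pd.DataFrame(rows, columns=PER_TREE_COLUMNS)


@dataclass
class IntervalSummary:
    interval: str
    n: int
    mean_abs_error_cm: float
    var_abs_error: float
    mean_rel_error_pct: float
    var_rel_error: float
    var_rel_error_signed: float
    rmse_cm: float
    corr_credibility_abs_error: float
    credibility_sd: float


def summarize_errors(per_tree: pd.DataFrame, interval: str | HeightInterval
                     ) -> IntervalSummary:
    """Aggregate one interval's rows of the per-tree table (ok fits only)."""
    label = interval.label if isinstance(interval, HeightInterval) else interval
    df = per_tree[(per_tree["interval"] == label) & (per_tree["status"] == "ok")]
    n = len(df)
    if n < 2:
        raise ValueError(f"interval {label}: need >= 2 successful fits, got {n}")
    signed = (df["dbh_est_cm"] - df["dbh_true_cm"]).to_numpy(dtype=float)
    abs_err = np.abs(signed)
    rel_signed = df["rel_error_pct"].to_numpy(dtype=float)
    cred = df["credibility"].to_numpy(dtype=float)
    if np.ptp(cred) == 0:
        warnings.warn(f"interval {label}: credibility has zero variance; "
                      "correlation undefined", stacklevel=2)
        corr = np.nan
    elif np.ptp(abs_err) == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(cred, abs_err)[0, 1])
    return IntervalSummary(
        interval=label,
        n=n,
        mean_abs_error_cm=float(abs_err.mean()),
        var_abs_error=float(abs_err.var(ddof=1)),
        mean_rel_error_pct=float(np.abs(rel_signed).mean()),
        var_rel_error=float(np.abs(rel_signed).var(ddof=1)),
        var_rel_error_signed=float(rel_signed.var(ddof=1)),
        rmse_cm=float(np.sqrt((signed**2).mean())),
        corr_credibility_abs_error=corr,
        credibility_sd=float(cred.std(ddof=1)),
    )


def select_best_interval(summaries: list[IntervalSummary]) -> str:
    """The interval minimising mean absolute error (ties: RMSE, then zmin)."""
    if not summaries:
        raise ValueError("need at least one interval summary")
    def sort_key(s: IntervalSummary):
        zmin = float(s.interval.split("-")[0])
        return (s.mean_abs_error_cm, s.rmse_cm, zmin)
    return min(summaries, key=sort_key).interval


@dataclass
class ErrorReport:
    per_tree: pd.DataFrame
    per_interval: pd.DataFrame
    selected_interval: str | None = None
    n_unmatched_instances: int = 0
    n_unmatched_truth: int = 0


def build_report(matches: MatchResult) -> ErrorReport:
    """Full error report from matched instances carrying DBH estimates."""
    per_tree = per_tree_table(matches)
    summaries = []
    for label in per_tree["interval"].unique() if len(per_tree) else []:
        try:
            summaries.append(summarize_errors(per_tree, label))
        except ValueError:
            continue
    per_interval = pd.DataFrame([s.__dict__ for s in summaries],
                                columns=SUMMARY_COLUMNS)
    selected = select_best_interval(summaries) if summaries else None
    return ErrorReport(per_tree, per_interval, selected,
                       len(matches.unmatched_instances), len(matches.unmatched_truth))


def write_report(report: ErrorReport, out_dir, plots: bool = False) -> None:
    """Write per-tree and summary CSVs (and optional diagnostic plots).

    The plots mirror the usual DBH-validation figures: estimate-vs-truth
    scatter with the quadrant bisector, the credibility distribution and the
    error distributions per interval.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_tree.to_csv(out / "per_tree.csv", index=False)
    per_interval = report.per_interval.copy()
    per_interval["selected"] = per_interval["interval"] == report.selected_interval
    per_interval.to_csv(out / "summary.csv", index=False)
    if plots and len(report.per_tree):
        _write_plots(report, out)


def _write_plots(report: ErrorReport, out) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = report.per_tree[report.per_tree["status"] == "ok"]
    fig, axes = plt.subplots(2, 2, figsize=(11, 9))
    ax = axes[0, 0]
    for label, grp in ok.groupby("interval"):
        ax.scatter(grp["dbh_true_cm"], grp["dbh_est_cm"], s=14, label=label, alpha=0.7)
    lims = [min(ok["dbh_true_cm"].min(), ok["dbh_est_cm"].min()),
            max(ok["dbh_true_cm"].max(), ok["dbh_est_cm"].max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlim(lims); ax.set_ylim(lims)
    ax.set_xlabel("reference DBH (cm)"); ax.set_ylabel("estimated DBH (cm)")
    ax.legend(); ax.set_title("estimate vs reference")
    ax = axes[0, 1]
    for label, grp in ok.groupby("interval"):
        ax.hist(grp["credibility"], bins=20, range=(0, 1), alpha=0.5, label=label)
    ax.set_xlabel("credibility C"); ax.set_title("credibility distribution"); ax.legend()
    ax = axes[1, 0]
    for label, grp in ok.groupby("interval"):
        ax.plot(grp["tree_id"], grp["abs_error_cm"], ".", label=label, alpha=0.7)
    ax.set_xlabel("tree"); ax.set_ylabel("|error| (cm)"); ax.set_title("absolute error")
    ax = axes[1, 1]
    for label, grp in ok.groupby("interval"):
        ax.plot(grp["tree_id"], grp["rel_error_pct"], ".", label=label, alpha=0.7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("tree"); ax.set_ylabel("relative error (%)"); ax.set_title("relative error")
    fig.tight_layout()
    fig.savefig(out / "report.png", dpi=110)
    plt.close(fig)


def read_report(out_dir) -> ErrorReport:
    """Round-trip counterpart of :func:`write_report` (CSV parts only)."""
    from pathlib import Path

    out = Path(out_dir)
    per_tree = pd.read_csv(out / "per_tree.csv")
    if len(per_tree) == 0:
        per_tree = pd.DataFrame(columns=PER_TREE_COLUMNS)
    summary = pd.read_csv(out / "summary.csv")
    selected = None
    if len(summary) and summary["selected"].any():
        selected = str(summary.loc[summary["selected"], "interval"].iloc[0])
    per_interval = summary.drop(columns=["selected"]) if "selected" in summary else summary
    return ErrorReport(per_tree, per_interval, selected)
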