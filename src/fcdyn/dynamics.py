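"""Topological-stability statistics over masked window trajectories.

The stability of a metric trajectory A_1..A_W is its sample variance
(N - 1 denominator) over the windows picked out by a temporal mask.
Group-level summaries average trajectories across subjects, and the
task-masked variances are compared with full-duration variances by a
two-sided paired-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TemporalMask


class UndefinedVarianceError(ValueError):
    """Fewer than two usable windows under the mask."""


@dataclass
class VarianceResult:
    """Sample variance of a trajectory over a masked window set."""

    V: float
    mu: float
    N: int
    mask_source: str


def masked_variance(
    trajectory: np.ndarray, mask: TemporalMask | None = None
) -> VarianceResult:
    """Sample variance (N-1 denominator) over masked, finite windows."""
    a = np.asarray(trajectory, dtype=float)
    if mask is not None:
        if mask.selected.size != a.size:
            raise ValueError(
                f"mask length {mask.selected.size} != trajectory length {a.size}"
            )
        a = a[mask.selected]
        source = mask.source
    else:
        source = "all"
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise UndefinedVarianceError(
            f"variance needs >= 2 finite windows, got {a.size}"
        )
    return VarianceResult(
        V=float(a.var(ddof=1)), mu=float(a.mean()), N=int(a.size), mask_source=source
    )


def group_average(trajectories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard error over subjects.

    ``trajectories`` is (n_subjects, W); returns (mean, SEM) each of
    length W, with SEM = sd / sqrt(n_subjects).
    """
    a = np.asarray(trajectories, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a subjects x windows array")
    n = a.shape[0]
    mean = a.mean(axis=0)
    sem = a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(a.shape[1])
    return mean, sem


def paired_variance_test(
    v_task: np.ndarray, v_all: np.ndarray
) -> tuple[float, float]:
    """Two-sided paired t-test of full-duration minus task-masked variances.

    Positive t means variances are lower under the task mask.  Zero-spread
    differences give (inf-signed t, p = 0) for a constant nonzero
    difference and (0, 1) for identical pairs, flagged by the caller via
    ``np.isfinite``.
    """
    v_task = np.asarray(v_task, dtype=float)
    v_all = np.asarray(v_all, dtype=float)
    if v_task.shape != v_all.shape or v_task.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    n = v_task.size
    if n < 2:
        raise ValueError("need at least 2 subject pairs")
    diff = v_all - v_task
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    res = stats.ttest_rel(v_all, v_task)
    return float(res.statistic), float(res.pvalue)


def variance_table(
    global_tables: dict[str, pd.DataFrame],
    mask: TemporalMask,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject, per-metric, per-threshold masked vs full variances.

    ``global_tables`` maps subject id -> the wide table produced by
    :func:`fcdyn.metrics.metrics_over_series`.
    """
    rows = []
    for subject, df in global_tables.items():
        metric_cols = metrics or [
            c for c in df.columns if c not in ("window", "threshold")
        ]
        for thr, sub in df.groupby("threshold"):
            sub = sub.sort_values("window")
            for metric in metric_cols:
                traj = sub[metric].to_numpy()
                try:
                    v_task = masked_variance(traj, mask).V
                    v_all = masked_variance(traj).V
                except UndefinedVarianceError:
                    continue
                rows.append(
                    {
                        "subject": subject,
                        "metric": metric,
                        "threshold": float(thr),
                        "V_task": v_task,
                        "V_all": v_all,
                    }
                )
    return pd.DataFrame(rows)


def variance_comparison(
    var_table: pd.DataFrame, bonferroni: bool = False
) -> pd.DataFrame:
    """Paired t-test per metric on threshold-averaged subject variances.

    Variances are averaged over thresholds within subject before
    pairing (a per-threshold breakdown is available from
    :func:`variance_table` directly).  ``bonferroni`` multiplies p-values
    by the number of metrics tested.
    """
    rows = []
    metrics = sorted(var_table["metric"].unique())
    for metric in metrics:
        sub = var_table[var_table["metric"] == metric]
        per_subject = sub.groupby("subject")[["V_task", "V_all"]].mean()
        if len(per_subject) < 2:
            continue
        t, p = paired_variance_test(
            per_subject["V_task"].to_numpy(), per_subject["V_all"].to_numpy()
        )
        if bonferroni:
            p = min(1.0, p * len(metrics))
        rows.append(
            {
                "metric": metric,
                "n_subjects": len(per_subject),
                "t": t,
                "p": p,
                "mean_V_task": float(per_subject["V_task"].mean()),
                "mean_V_all": float(per_subject["V_all"].mean()),
            }
        )
    return pd.DataFrame(rows)
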