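"""qPCR relative quantification and clinical statistics.

Implements the Livak-Schmittgen 2^-ddCt workflow (per-sample dCq against a
reference assay, ddCq against a calibrator, fold change), spike-in recovery
quality control, median dichotomisation of expression, the Kaplan-Meier
product-limit estimator, the two-group log-rank test, and Cohen's kappa for
inter-rater agreement.

Cq conventions: replicate Cq values are aggregated by arithmetic mean;
values at the run-length sentinel (45 cycles) are treated as undetected and
excluded from means; a sample whose target replicates are all undetected is
dropped with a warning.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .simgen.cohort import MAX_CYCLES

__all__ = [
    "delta_cq",
    "fold_change",
    "spikein_recovery",
    "dichotomize_median",
    "km_estimate",
    "logrank",
    "kappa",
    "load_example_cohort",
    "dfi_records",
]


def load_example_cohort() -> pd.DataFrame:
    """Bundled example cohort of 32 early-stage NSCLC patients.

    Columns include histology, stage, relapse and death indicators, and
    disease-free (DFS) and overall (OS) survival in months.
    """
    with resources.files("evquant").joinpath("data/example_cohort.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# 2^-ddCt quantification


def delta_cq(
    table: pd.DataFrame,
    target: str = "target",
    reference: str = "reference",
    max_cycles: float = MAX_CYCLES,
) -> pd.Series:
    """Per-sample dCq = mean(Cq_target) - mean(Cq_reference).

    Undetected replicates (Cq >= ``max_cycles``) are excluded from the
    means.  A sample with no detected target replicate is dropped with a
    warning; a sample with no detected reference raises an error naming it.
    """
    out = {}
    for sample_id, sub in table.groupby("sample_id", sort=False):
        t = sub.loc[(sub["assay"] == target) & (sub["cq"] < max_cycles), "cq"]
        r = sub.loc[(sub["assay"] == reference) & (sub["cq"] < max_cycles), "cq"]
        if r.empty:
            raise ValueError(f"sample {sample_id!r} has no detected reference measurement")
        if t.empty:
            warnings.warn(f"sample {sample_id!r}: all target replicates undetected; dropped")
            continue
        out[sample_id] = float(t.mean() - r.mean())
    return pd.Series(out, name="delta_cq")


def fold_change(dcq: pd.Series, calibrator_dcq: float) -> pd.Series:
    """Relative expression 2^-(dCq - calibrator_dCq) per sample."""
    if not np.isfinite(calibrator_dcq):
        raise ValueError("calibrator_dcq must be finite")
    return (2.0 ** -(pd.Series(dcq, dtype=float) - calibrator_dcq)).rename("fold_change")


def control_calibrator(dcq: pd.Series, groups: pd.Series) -> float:
    """Default calibrator: median dCq of the control group."""
    ctrl = dcq[groups.reindex(dcq.index) == "control"]
    if ctrl.empty:
        raise ValueError("empty control set")
    return float(ctrl.median())


def spikein_recovery(
    table: pd.DataFrame,
    reference_cq: float | None = None,
    floor: float = 0.25,
    ceiling: float = 2.0,
    max_cycles: float = MAX_CYCLES,
) -> pd.DataFrame:
    """Per-sample spike-in recovery ``2^(reference_cq - Cq_spikein)``.

    ``reference_cq`` defaults to the mean detected spike-in Cq across the
    run.  Samples outside ``[floor, ceiling]`` are flagged (not dropped):
    low recovery indicates extraction loss, recovery well above 1 an
    anomalous over-recovery.
    """
    sp = table.loc[table["assay"] == "spikein"]
    if sp.empty:
        raise ValueError("no spike-in assay in table")
    per_sample = sp.groupby("sample_id", sort=False)["cq"].apply(
        lambda s: s[s < max_cycles].mean()
    )
    if reference_cq is None:
        reference_cq = float(per_sample.dropna().mean())
    rec = 2.0 ** (reference_cq - per_sample)
    return pd.DataFrame(
        {
            "recovery": rec,
            "flagged": (rec < floor) | (rec > ceiling) | rec.isna(),
        }
    )


def dichotomize_median(values: pd.Series, reference) -> pd.Series:
    """Label samples 'low' (< median of reference) or 'high' (>= median).

    Values exactly at the cut-off are assigned 'high'; such ties are
    reported with a warning.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference must be non-empty")
    cut = float(np.median(ref))
    vals = pd.Series(values, dtype=float)
    n_tie = int((vals == cut).sum())
    if n_tie:
        warnings.warn(f"{n_tie} value(s) exactly at the median cut-off assigned 'high'")
    return pd.Series(np.where(vals < cut, "low", "high"), index=vals.index, name="expression_group")


# ---------------------------------------------------------------------------
# survival


def _check_survival(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns a step function as a DataFrame with one row per distinct
    observed time: at-risk count, events, censorings, and the survival
    estimate S(t) (right-continuous; starts at 1, non-increasing).
    """
    t, e = _check_survival(time, event)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    times = np.unique(t)
    n = len(t)
    rows = []
    s = 1.0
    for ti in times:
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        c = int(np.sum((t == ti) & (e == 0)))
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append((ti, at_risk, d, c, s))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"])


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p-value).

    Requires exactly two groups and at least one event overall.  The
    statistic is invariant to relabelling the groups.
    """
    t, e = _check_survival(time, event)
    g = np.asarray(group)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly two groups")
    is_a = g == labels[0]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        raise ValueError("no events observed")
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & is_a).sum())
        d_j = int(((t == ti) & (e == 1)).sum())
        d1_j = int(((t == ti) & (e == 1) & is_a).sum())
        exp1 = d_j * n1_j / n_j
        o_minus_e += d1_j - exp1
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def dfi_records(cohort: pd.DataFrame) -> pd.DataFrame:
    """Disease-free-interval records from a cohort table.

    Relapse is the DFI event; death without relapse is treated as
    censoring.  Returns (time_months, event) from the DFS column and the
    relapse indicator.
    """
    return pd.DataFrame(
        {
            "time_months": cohort["dfs_months"].astype(float),
            "event": cohort["relapse"].astype(int),
        }
    )


# ---------------------------------------------------------------------------
# inter-rater agreement


def kappa(matrix) -> tuple[float, float]:
    """Cohen's kappa and percent agreement from a square contingency table.

    Rows are one rater's categories, columns the other's.  Returns
    ``(kappa, percent_agreement)`` with agreement in percent.  When the
    expected agreement is 1 (degenerate marginals) kappa is undefined and
    NaN is returned with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(m < 0) or np.any(m != np.round(m)):
        raise ValueError("matrix must hold non-negative integer counts")
    total = m.sum()
    if total <= 0:
        raise ValueError("matrix total must be positive")
    p_o = np.trace(m) / total
    p_e = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / total**2)
    if p_e >= 1.0:
        warnings.warn("expected agreement is 1; kappa undefined")
        return float("nan"), float(p_o * 100)
    k = (p_o - p_e) / (1.0 - p_e)
    return float(k), float(p_o * 100)
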