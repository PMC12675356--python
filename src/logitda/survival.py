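"""Prognostic-marker screen: median split, Kaplan-Meier, log-rank, BH.

Each screened gene dichotomizes the cohort at its expression median
(high = value >= median, interpolated median for even n), the two groups
are compared with the standard log-rank test, and BH adjustment runs across
exactly the screened gene set.  Direction (high_better / low_better) is
read off the Kaplan-Meier curves, since the log-rank statistic is unsigned.
Ties between an event and a censoring at the same time follow the usual
convention: events precede censorings.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .datatypes import ClinicalTable, ExpressionMatrix, ValidationError
from .de import bh_adjust


def median_split(values: np.ndarray) -> np.ndarray:
    """1 = high (value >= interpolated median), 0 = low; errors if degenerate."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("median split needs >= 2 values")
    if np.unique(x).size == 1:
        raise ValidationError("all values identical: degenerate median split")
    med = np.median(x)
    groups = (x >= med).astype(int)
    if groups.all() or not groups.any():
        raise ValidationError("median split produced an empty group")
    return groups


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve as (time, survival) step pairs."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValidationError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(
    times_a: np.ndarray, events_a: np.ndarray, times_b: np.ndarray, events_b: np.ndarray
) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square, p-value)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank test needs at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _km_survival_at(times: np.ndarray, events: np.ndarray, t0: float) -> float:
    curve = km_estimate(times, events)
    below = curve[curve["time"] <= t0]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


def prognostic_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Median-split log-rank screen over a gene set, BH-adjusted.

    Rows sorted by padj then pvalue; ``direction`` says which expression
    group has the higher KM survival at the median follow-up time.
    """
    if not clinical.has_survival:
        raise ValidationError("clinical table lacks os_time/os_event columns")
    genes = list(genes) if genes is not None else expr.gene_ids
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")

    samples = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    sub = clinical.table.loc[samples]
    ok = sub["os_time"].notna() & sub["os_event"].notna()
    samples = [s for s, k in zip(samples, ok) if k]
    times = clinical.table.loc[samples, "os_time"].to_numpy(dtype=float)
    events = clinical.table.loc[samples, "os_event"].to_numpy(dtype=int)
    t_mid = float(np.median(times))

    rows = []
    for g in genes:
        vals = expr.values.loc[g, samples].to_numpy(dtype=float)
        grp = median_split(vals)
        hi, lo = grp == 1, grp == 0
        chisq, pval = logrank_test(times[hi], events[hi], times[lo], events[lo])
        s_hi = _km_survival_at(times[hi], events[hi], t_mid)
        s_lo = _km_survival_at(times[lo], events[lo], t_mid)
        rows.append(
            {
                "gene": g,
                "logrank_chisq": chisq,
                "pvalue": pval,
                "direction": "high_better" if s_hi >= s_lo else "low_better",
                "n_high": int(hi.sum()),
                "n_low": int(lo.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out = out.sort_values(["padj", "pvalue", "gene"], kind="mergesort").reset_index(drop=True)
    return out[["gene", "logrank_chisq", "pvalue", "padj", "direction", "n_high", "n_low"]]
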