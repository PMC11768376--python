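"""Correlation-based screening of candidate evaluation indicators.

Highly collinear indicators double-count the same information in an
entropy-weighted evaluation, so candidates are screened by pairwise
Pearson correlation before ranking.  Two modes are offered:

* ``paper`` (default): keep the fixed retained set
  {ET, Y, WUE, NPFP, TSS, VC} established for this trial;
* ``auto``: a deterministic greedy rule — scan indicators in a priority
  order and drop any whose |r| with an already-retained indicator
  reaches a threshold (default 0.8).

The greedy rule is a general-purpose heuristic; on the trial fixtures it
is stricter than the fixed set (e.g. it cannot keep both TSS and VC,
whose correlation exceeds 0.99), which is why the fixed set is the
default for reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import SCREENED_INDICATORS, IndicatorTable

__all__ = ["CorrelationReport", "pearson_matrix", "prune_indicators", "screen"]

DEFAULT_THRESHOLD = 0.8


@dataclass
class CorrelationReport:
    """Pairwise Pearson r and p-values, plus the pruning outcome."""

    r: pd.DataFrame
    p: pd.DataFrame
    retained: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # indicator -> partner


def pearson_matrix(table: IndicatorTable) -> CorrelationReport:
    """Pairwise Pearson correlations with two-sided p-values.

    p-values come from the exact t transform with m-2 degrees of
    freedom.  Requires at least three objects and no constant column.
    """
    df = table.values
    m = df.shape[0]
    if m < 3:
        raise ValueError(f"need at least 3 objects for correlation, got {m}")
    for col in df.columns:
        if df[col].nunique() <= 1:
            raise ValueError(f"constant indicator column: {col!r}")

    r = df.corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    # two-sided p via t = r*sqrt((m-2)/(1-r^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((m - 2) / np.clip(1.0 - rv**2, 0.0, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    return CorrelationReport(r=pd.DataFrame(rv, index=r.index, columns=r.columns), p=p)


def prune_indicators(
    report: CorrelationReport,
    threshold: float = DEFAULT_THRESHOLD,
    keep_priority: list[str] | None = None,
) -> list[str]:
    """Greedy pruning: drop an indicator if |r| >= threshold with a keeper.

    Indicators are scanned in ``keep_priority`` order (default: column
    order of the correlation matrix); the first is always retained, and
    each subsequent one is dropped exactly when its absolute correlation
    with any already-retained indicator reaches the threshold.
    Deterministic given the priority order, and idempotent.
    The report's ``retained``/``dropped`` fields are filled in place.
    """
    if not 0 < threshold:
        raise ValueError("threshold must be positive")
    cols = list(report.r.columns)
    if keep_priority is None:
        keep_priority = cols
    missing = [c for c in cols if c not in keep_priority]
    if missing:
        raise ValueError(f"keep_priority does not cover indicator(s): {missing}")

    retained: list[str] = []
    dropped: dict[str, str] = {}
    for cand in keep_priority:
        if cand not in cols:
            continue
        partner = next(
            (k for k in retained if abs(report.r.loc[cand, k]) >= threshold), None
        )
        if partner is None:
            retained.append(cand)
        else:
            dropped[cand] = partner
    # restore original column order in the retained list
    retained = [c for c in cols if c in retained]
    report.retained = retained
    report.dropped = dropped
    return retained


def screen(
    table: IndicatorTable,
    mode: str = "paper",
    threshold: float = DEFAULT_THRESHOLD,
    keep_priority: list[str] | None = None,
) -> tuple[IndicatorTable, CorrelationReport]:
    """Screen a candidate table and return (screened table, report)."""
    report = pearson_matrix(table)
    if mode == "paper":
        retained = [c for c in table.indicator_ids if c in SCREENED_INDICATORS]
        report.retained = retained
        report.dropped = {c: "fixed-set" for c in table.indicator_ids
                          if c not in retained}
    elif mode == "auto":
        if keep_priority is None:
            first = [c for c in SCREENED_INDICATORS if c in table.indicator_ids]
            rest = [c for c in table.indicator_ids if c not in first]
            keep_priority = first + rest
        retained = prune_indicators(report, threshold, keep_priority)
    else:
        raise ValueError(f"unknown screening mode {mode!r}")
    return table.subset(retained), report
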