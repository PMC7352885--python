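"""Kaplan-Meier estimation, log-rank (Mantel-Cox) testing, and the
signature-projection workflow (cluster a cohort on signature genes, compare
the clusters' survival).

Estimation and testing are delegated to lifelines behind this module's
surface; the headline p-value uses the chi-square reference distribution
(df = 1), the Mantel-Cox convention.  Tied event times follow the standard
product-limit convention: all tied events share one risk-set row, and
subjects censored at an event time count as at risk for that time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort_stats import TestResult
from .errors import (
    DegeneratePartitionError,
    InvalidRecordError,
    MissingSignatureError,
    UndefinedTestError,
)
from .omics_stats import ExpressionMatrix, hierarchical_cluster, knn_impute


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time in days, event flag (1 = death observed,
    0 = censored) and an optional stratum label."""

    sample_id: str
    time: float
    event: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise InvalidRecordError(
                f"time must be finite and > 0 ({self.sample_id}: {self.time!r})")
        if self.event not in (0, 1):
            raise InvalidRecordError(f"event must be 0 or 1 ({self.sample_id})")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray           # distinct event times, ascending
    at_risk: np.ndarray         # subjects at risk just before each time
    events: np.ndarray          # events at each time
    survival: np.ndarray        # S(t) just after each time
    censor_times: np.ndarray    # times of censored subjects

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "time": [r.time for r in records],
        "event": [r.event for r in records],
        "stratum": [r.stratum for r in records],
    })


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""
    if len(records) == 0:
        raise InvalidRecordError("need >= 1 record")
    df = _frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    times = with_events.index.to_numpy(dtype=float)
    surv = np.asarray([kmf.survival_function_at_times(t).iloc[0] for t in times])
    return KMCurve(
        times=times,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
        events=with_events["observed"].to_numpy(dtype=int),
        survival=surv,
        censor_times=df.loc[df["event"] == 0, "time"].to_numpy(dtype=float),
    )


def logrank_test(records: Sequence[SurvivalRecord],
                 strata: tuple[str, str] | None = None) -> TestResult:
    """Two-group log-rank (Mantel-Cox) test.

    The chi-square statistic sums observed-minus-expected events over event
    times with the hypergeometric variance; df = 1.  Both strata must contain
    at least one event.
    """
    df = _frame(records)
    if strata is None:
        strata = tuple(sorted(df["stratum"].unique()))
    if len(strata) != 2:
        raise UndefinedTestError(f"need exactly 2 strata, got {strata}")
    a = df[df["stratum"] == strata[0]]
    b = df[df["stratum"] == strata[1]]
    if len(a) == 0 or len(b) == 0:
        raise UndefinedTestError(f"empty stratum among {strata}")
    if a["event"].sum() == 0 or b["event"].sum() == 0:
        raise UndefinedTestError("each stratum must contain >= 1 event")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return TestResult(statistic=float(res.test_statistic), degrees_of_freedom=1.0,
                      p_value=float(res.p_value), n=len(df))


def signature_projection(
    expr: ExpressionMatrix,
    signature_genes: Sequence[str],
    records: Sequence[SurvivalRecord],
    k: int = 2,
    knn_k: int = 10,
) -> tuple[pd.Series, TestResult, dict[int, KMCurve]]:
    """Stratify a cohort by its expression of a gene signature and compare survival.

    The matrix is restricted to the signature genes, missing values are filled
    by kNN imputation, samples are clustered (Euclidean distance, complete
    linkage) and cut into ``k`` groups, and the groups' survival is compared
    by the log-rank test (between the two largest clusters when k > 2).
    Returns cluster labels per sample, the log-rank result and one KM curve
    per compared cluster.
    """
    missing = [g for g in signature_genes if g not in expr.values.index]
    if missing:
        raise MissingSignatureError(missing)
    sub = expr.subset_genes(list(signature_genes))
    if sub.mask.to_numpy().any():
        sub, _ = knn_impute(sub, k=knn_k)
    _, labels = hierarchical_cluster(sub, distance="euclidean",
                                     axis="samples", k=k)
    counts = labels.value_counts()
    if (counts > 0).sum() < 2:
        raise DegeneratePartitionError("clustering produced < 2 nonempty clusters")
    top = list(counts.index[:2])

    by_sample = {r.sample_id: r for r in records}
    relabeled = [
        SurvivalRecord(sample_id=sid, time=by_sample[sid].time,
                       event=by_sample[sid].event, stratum=str(labels[sid]))
        for sid in labels.index
        if sid in by_sample and labels[sid] in top
    ]
    result = logrank_test(relabeled, strata=(str(top[0]), str(top[1])))
    curves = {int(c): km_estimate([r for r in relabeled if r.stratum == str(c)])
              for c in top}
    return labels, result, curves


def km_table(curve: KMCurve) -> pd.DataFrame:
    """KM curve as a flat table (time, at_risk, events, survival)."""
    return pd.DataFrame({
        "time": curve.times,
        "at_risk": curve.at_risk,
        "events": curve.events,
        "survival": curve.survival,
    })
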