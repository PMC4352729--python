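"""Median-split survival validation: Kaplan-Meier product-limit curves and the
two-group log-rank test, implemented from first principles.

The validation procedure mirrors the standard biomarker check: dichotomize
patients at the median of a gene's expression, estimate the two survival
curves, and compare them with the log-rank chi-square(1) statistic built from
observed-minus-expected event counts with hypergeometric variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time on study, event indicator, and an optional
    expression covariate used for the median split."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs in survival table")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length mismatch")
        if (self.time < 0).any():
            raise ValueError("negative survival times")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)


def read_survival_table(path: str | Path) -> SurvivalTable:
    """TSV with columns: sample, time, event, and optionally expression."""
    df = pd.read_csv(path, sep="\t")
    cov = df["expression"].to_numpy() if "expression" in df.columns else None
    return SurvivalTable(sample_ids=[str(s) for s in df["sample"]],
                         time=df["time"].to_numpy(),
                         event=df["event"].to_numpy(),
                         covariate=cov)


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    data = {"sample": table.sample_ids, "time": table.time,
            "event": table.event}
    if table.covariate is not None:
        data["expression"] = table.covariate
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    observed: float = float("nan")   # group-1 observed events
    expected: float = float("nan")   # group-1 expected events under H0
    variance: float = float("nan")


def median_split(table: SurvivalTable,
                 covariate: np.ndarray | None = None) -> np.ndarray:
    """Assign each sample to the low (0) or high (1) expression group.

    Values strictly above the median go high; ties at the median go low.
    """
    cov = table.covariate if covariate is None else np.asarray(covariate, float)
    if cov is None:
        raise ValueError("survival table has no covariate to split on")
    finite = np.isfinite(cov)
    if finite.sum() < 4:
        raise ValueError("need >= 4 samples with a finite covariate")
    med = float(np.median(cov[finite]))
    groups = (cov > med).astype(int)
    if groups[finite].min() == groups[finite].max():
        raise ValueError("degenerate median split: all covariates equal")
    return groups


def kaplan_meier(table: SurvivalTable) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame with one row per distinct event time: ``time``,
    ``n_at_risk``, ``n_events``, ``survival``.  S(t) steps only at event
    times; censored subjects leave the risk set without a step.
    """
    if len(table) == 0:
        raise ValueError("empty survival table")
    order = np.argsort(table.time, kind="stable")
    times, events = table.time[order], table.event[order]
    rows = []
    surv = 1.0
    n_at_risk = len(times)
    for t in np.unique(times):
        at_this = times == t
        d = int(events[at_this].sum())
        if d > 0:
            surv *= 1.0 - d / n_at_risk
            rows.append((float(t), n_at_risk, d, surv))
        n_at_risk -= int(at_this.sum())
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "survival"])


def survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate a Kaplan-Meier step function at time ``t``."""
    past = km[km["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(table: SurvivalTable, groups: np.ndarray) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the group-1 event count is compared with its
    hypergeometric expectation given the risk sets; the squared standardized
    sum is referred to chi-square with 1 df.  Subjects censored exactly at an
    event time count as at risk for that time.
    """
    groups = np.asarray(groups, dtype=int)
    n0, n1 = int((groups == 0).sum()), int((groups == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("log-rank test needs two nonempty groups")
    time, event = table.time, table.event
    o = e = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = int(at_risk.sum())
        n1_t = int((at_risk & (groups == 1)).sum())
        dying = (time == t) & (event == 1)
        d_t = int(dying.sum())
        d1_t = int((dying & (groups == 1)).sum())
        o += d1_t
        e += d_t * n1_t / n_t
        if n_t > 1:
            v += (d_t * (n1_t / n_t) * (1 - n1_t / n_t)
                  * (n_t - d_t) / (n_t - 1))
    if v == 0.0:
        return LogRankResult(0.0, 1.0, (n0, n1), o, e, v)
    stat = (o - e) ** 2 / v
    p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(float(stat), p, (n0, n1), o, e, v)


def median_split_logrank(table: SurvivalTable) -> LogRankResult:
    """The full validation step: median dichotomization then log-rank."""
    return logrank_test(table, median_split(table))
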