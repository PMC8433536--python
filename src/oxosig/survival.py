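"""Kaplan–Meier estimation, log-rank testing, and scanned-cutoff survival splits.

The cutoff scan ("Kaplan scan") tests every distinct value of a continuous
per-sample covariate — here the C>A substitution fraction — as a two-group
split (high group = covariate ≥ cutoff) with a log-rank test, subject to a
minimum group size, and reports the best split with a Bonferroni correction
over the number of cutoffs actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from lifelines import KaplanMeierFitter

from .variant_io import SurvivalRecord


class UndefinedTestError(ValueError):
    """The requested test has no defined statistic (e.g. no events at all)."""


@dataclass
class KMEstimate:
    """Product-limit survival estimate with right censoring."""

    times: np.ndarray  #: ordered observed event times
    survival: np.ndarray  #: S(t) just after each event time
    at_risk: np.ndarray  #: number at risk just before each event time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=float)


@dataclass
class KaplanScanResult:
    cutoffs: np.ndarray
    raw_p: np.ndarray  #: per-cutoff log-rank p, aligned with ``cutoffs``
    statistics: np.ndarray
    best_cutoff: float
    best_raw_p: float
    bonferroni_p: float
    n_high: int
    n_low: int

    @property
    def n_cutoffs(self) -> int:
        return len(self.cutoffs)


def _arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=np.int64)
    return times, events


def km_estimate(records: list[SurvivalRecord]) -> KMEstimate:
    """Kaplan–Meier product-limit estimate over the records."""
    if not records:
        raise ValueError("need at least one record")
    times, events = _arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    t = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[t, "KM_estimate"].to_numpy()
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    return KMEstimate(t, surv, at_risk)


def _logrank_sums(
    times: np.ndarray, events: np.ndarray, member: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-minus-expected and hypergeometric variance for group 1.

    ``member`` is a boolean (n_samples,) vector or (n_samples, n_splits)
    matrix of group-1 membership; returns per-split (O−E, V) summed over
    distinct event times, with the standard tie handling.
    """
    member = np.atleast_2d(np.asarray(member, dtype=float).T).T  # (n, k)
    order = np.argsort(times, kind="stable")
    t_s, e_s, m_s = times[order], events[order], member[order]
    n = len(t_s)

    # suffix sums give the at-risk counts just before each time
    suffix = np.cumsum(m_s[::-1], axis=0)[::-1]

    # first index of each distinct time that carries >= 1 event
    distinct, first = np.unique(t_s, return_index=True)
    oe = np.zeros(m_s.shape[1])
    var = np.zeros(m_s.shape[1])
    for f, t in zip(first, distinct):
        at_time = slice(f, np.searchsorted(t_s, t, side="right"))
        ev = e_s[at_time] == 1
        d = int(ev.sum())
        if d == 0:
            continue
        n_risk = n - f
        n1 = suffix[f]
        d1 = m_s[at_time][ev].sum(axis=0)
        frac = n1 / n_risk
        oe += d1 - d * frac
        if n_risk > 1:
            var += d * frac * (1 - frac) * (n_risk - d) / (n_risk - 1)
    return oe, var


def logrank_test(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value.

    Ties are handled with the hypergeometric variance formula.
    """
    times_a, events_a = _arrays(group_a)
    times_b, events_b = _arrays(group_b)
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    if events.sum() == 0:
        raise UndefinedTestError("no events in either group; log-rank undefined")
    member = np.zeros(len(times), dtype=bool)
    member[: len(times_a)] = True
    oe, var = _logrank_sums(times, events, member)
    if var[0] == 0:
        return 0.0, 1.0
    stat = float(oe[0] ** 2 / var[0])
    return stat, float(scipy.stats.chi2.sf(stat, df=1))


def kaplan_scan(
    records: list[SurvivalRecord],
    covariate: str = "ca_fraction",
    min_group: int = 8,
) -> KaplanScanResult:
    """Scan every admissible covariate cutoff for the best log-rank split.

    Each distinct covariate value that induces a high group (covariate ≥
    cutoff) and low group (covariate < cutoff) both of size ≥ ``min_group``
    is tested; the Bonferroni multiplier is the number of cutoffs actually
    tested.  The best cutoff attains the minimum raw p (first such value on
    ties).
    """
    times, events = _arrays(records)
    x = np.array([float(r.covariates[covariate]) for r in records])
    if events.sum() == 0:
        raise UndefinedTestError("no events; scan undefined")

    values = np.unique(x)
    n_high = (x[:, None] >= values[None, :]).sum(axis=0)
    admissible = (n_high >= min_group) & (len(x) - n_high >= min_group)
    cutoffs = values[admissible]
    if len(cutoffs) == 0:
        raise UndefinedTestError("no cutoff satisfies the minimum group size")

    member = x[:, None] >= cutoffs[None, :]
    oe, var = _logrank_sums(times, events, member)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = np.where(var > 0, oe**2 / np.where(var > 0, var, 1.0), 0.0)
    raw_p = scipy.stats.chi2.sf(stats, df=1)
    raw_p = np.where(var > 0, raw_p, 1.0)

    best = int(np.argmin(raw_p))
    best_cutoff = float(cutoffs[best])
    best_raw = float(raw_p[best])
    bonf = min(1.0, best_raw * len(cutoffs))
    nh = int((x >= best_cutoff).sum())
    return KaplanScanResult(
        cutoffs=cutoffs,
        raw_p=raw_p,
        statistics=stats,
        best_cutoff=best_cutoff,
        best_raw_p=best_raw,
        bonferroni_p=bonf,
        n_high=nh,
        n_low=len(x) - nh,
    )
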