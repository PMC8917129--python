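"""Kaplan-Meier survival and evaporation-corrected food consumption.

Mortality is recorded daily per cage over a short exposure window (5 days
by default) with administrative censoring at the horizon; group differences
use the k-sample log-rank test (full covariance form) with pairwise
Benjamini-Hochberg-adjusted post hocs. Food intake is the daily feeder mass
change minus the evaporation control, divided by the bees alive that day;
cage-level cumulative per-bee intake is compared across treatments with
Kruskal-Wallis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .stats_core import TestResult

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "logrank",
    "consumption_series",
    "compare_consumption",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate over integer event times (days)."""

    times: np.ndarray      # event times with at least one death
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray   # S(t) just after each event time
    initial_n: int = 0

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


def kaplan_meier(deaths_per_day, initial_n: int, horizon: int | None = None) -> SurvivalCurve:
    """Product-limit estimator from daily death counts.

    ``deaths_per_day`` maps day (1-based) to deaths, or is a sequence for
    days 1..len. Survivors at the horizon are administratively censored.
    """
    if isinstance(deaths_per_day, dict):
        items = sorted(deaths_per_day.items())
    else:
        items = list(enumerate(np.asarray(deaths_per_day, dtype=int), start=1))
    if horizon is not None:
        items = [(d, c) for d, c in items if d <= horizon]
    times, at_risk, deaths, surv = [], [], [], []
    n = int(initial_n)
    s = 1.0
    for day, d in items:
        d = int(d)
        if d < 0 or d > n:
            raise ValueError(f"day {day}: deaths {d} exceed at-risk {n}")
        if d > 0:
            s *= 1.0 - d / n
            times.append(day)
            at_risk.append(n)
            deaths.append(d)
            surv.append(s)
        n -= d
    return SurvivalCurve(
        np.array(times, dtype=float),
        np.array(at_risk, dtype=int),
        np.array(deaths, dtype=int),
        np.array(surv, dtype=float),
        initial_n=int(initial_n),
    )


def _group_day_table(groups: dict, horizon: int | None):
    """(day, group) at-risk and death counts from per-group daily deaths."""
    days = set()
    norm = {}
    for g, (deaths_per_day, n0) in groups.items():
        if isinstance(deaths_per_day, dict):
            items = dict(deaths_per_day)
        else:
            items = dict(enumerate(np.asarray(deaths_per_day, dtype=int), start=1))
        if horizon is not None:
            items = {d: c for d, c in items.items() if d <= horizon}
        norm[g] = (items, int(n0))
        days |= set(items)
    return norm, sorted(days)


def _logrank_omnibus(groups: dict, horizon: int | None) -> TestResult:
    labels = sorted(groups, key=str)
    norm, days = _group_day_table(groups, horizon)
    k = len(labels)
    at_risk = {g: norm[g][1] for g in labels}
    oe = np.zeros(k)
    cov = np.zeros((k, k))
    any_event = False
    for day in days:
        n_g = np.array([at_risk[g] for g in labels], dtype=float)
        d_g = np.array([norm[g][0].get(day, 0) for g in labels], dtype=float)
        n_tot, d_tot = n_g.sum(), d_g.sum()
        if d_tot > 0 and n_tot > 1:
            any_event = True
            e_g = n_g * d_tot / n_tot
            oe += d_g - e_g
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
            p = n_g / n_tot
            cov += factor * (np.diag(p) - np.outer(p, p))
        for g, d in zip(labels, d_g):
            at_risk[g] -= int(d)
    if not any_event:
        return TestResult(0.0, 1.0, k - 1, "logrank", degenerate=True)
    # V is singular (rows sum to 0): use the pseudo-inverse
    stat = float(oe @ np.linalg.pinv(cov) @ oe)
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(stat, p, k - 1, "logrank")


def logrank(groups: dict, horizon: int | None = None) -> tuple[TestResult, pd.DataFrame]:
    """k-sample log-rank test with pairwise BH-adjusted post hocs.

    ``groups`` maps a label to (daily deaths, initial n). The omnibus
    statistic is (O-E)' V^- (O-E) over pooled event times with the
    hypergeometric covariance, referred to chi-square with k-1 df. Returns
    the omnibus result and a pairwise posthoc table.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    labels = sorted(groups, key=str)
    omnibus = _logrank_omnibus(groups, horizon)
    rows, raw = [], []
    for a, b in itertools.combinations(labels, 2):
        sub = _logrank_omnibus({a: groups[a], b: groups[b]}, horizon)
        rows.append([a, b, sub.statistic, sub.p_value])
        raw.append(sub.p_value)
    adj = stats_core.adjust_p(raw, "benjamini-hochberg") if raw else []
    posthoc = pd.DataFrame(
        [r + [a_, "benjamini-hochberg"] for r, a_ in zip(rows, adj)],
        columns=stats_core.POSTHOC_COLUMNS,
    )
    return omnibus, posthoc


def consumption_series(
    feeder_log: pd.DataFrame,
    evaporation: pd.Series | pd.DataFrame,
    survival_log: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cage daily per-bee consumption and its cumulative sum.

    ``feeder_log`` columns: cage, day, mass_consumed (raw feeder mass
    change, g). ``evaporation``: per-day evaporation-control mass change
    (Series indexed by day, or DataFrame with day/mass columns).
    ``survival_log`` columns: cage, day, alive. Corrected consumption is
    max(0, raw - evaporation) / alive; gaps in the day sequence are an error.
    """
    if isinstance(evaporation, pd.DataFrame):
        evaporation = evaporation.set_index("day")["mass"]
    out = []
    alive_lut = survival_log.set_index(["cage", "day"])["alive"]
    for cage, sub in feeder_log.groupby("cage"):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy()
        expect = np.arange(days.min(), days.max() + 1)
        gaps = sorted(set(expect) - set(days))
        if gaps:
            raise ValueError(f"cage {cage}: missing day(s) {gaps}")
        cumulative = 0.0
        for _, row in sub.iterrows():
            day = row["day"]
            evap = float(evaporation.get(day, 0.0))
            corrected = row["mass_consumed"] - evap
            if corrected < 0:
                warnings.warn(
                    f"cage {cage} day {day}: evaporation exceeds feeder change; "
                    "clipping consumption to 0"
                )
                corrected = 0.0
            alive = int(alive_lut.loc[(cage, day)])
            per_bee = corrected / alive if alive > 0 else 0.0
            cumulative += per_bee
            out.append(
                {
                    "cage": cage,
                    "day": day,
                    "raw_mass": row["mass_consumed"],
                    "corrected_mass": corrected,
                    "alive": alive,
                    "per_bee": per_bee,
                    "cumulative_per_bee": cumulative,
                }
            )
    return pd.DataFrame(out)


def compare_consumption(
    series: pd.DataFrame, cage_treatments: pd.Series
) -> TestResult:
    """Kruskal-Wallis on cage-level cumulative per-bee consumption.

    The cage is the experimental unit (bees share a feeder); the final
    cumulative per-bee value of each cage enters the test.
    """
    finals = series.sort_values("day").groupby("cage")["cumulative_per_bee"].last()
    treatments = cage_treatments.loc[finals.index]
    counts = treatments.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >=2 treatments with >=2 cages each")
    return stats_core.kruskal_wallis(finals.to_numpy(), treatments.to_numpy())
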