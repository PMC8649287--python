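"""Incidence tables with exact Poisson confidence intervals.

Rates are reported per 1000 person-years with Garwood (exact,
chi-square-inversion) intervals: for a count k,

    lower = chi2.ppf(alpha/2, 2k) / 2      (0 when k = 0)
    upper = chi2.ppf(1 - alpha/2, 2k + 2) / 2

A normal-approximation-on-log variant is available behind a flag for
comparison.  Person-time for each outcome runs to that outcome's first
event or censoring (death censors non-fatal outcomes upstream in the
generator/pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["IncidenceCell", "exact_poisson_ci", "incidence_table"]


@dataclass
class IncidenceCell:
    outcome: str
    group: str
    events: int
    person_years: float
    rate: float       # per 1000 person-years
    ci_low: float
    ci_high: float


def exact_poisson_ci(count: int, confidence: float = 0.95, method: str = "exact"):
    """Confidence interval for a Poisson mean.

    ``method='exact'`` gives the Garwood interval by chi-square
    inversion; ``method='normal_log'`` the normal approximation on the
    log scale.  Returns ``(lower_mean, upper_mean)``.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    alpha = 1.0 - confidence
    if method == "exact":
        lower = 0.0 if count == 0 else sps.chi2.ppf(alpha / 2, 2 * count) / 2.0
        upper = sps.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    elif method == "normal_log":
        if count == 0:
            return 0.0, float(sps.chi2.ppf(1 - alpha / 2, 2) / 2.0)
        z = sps.norm.ppf(1 - alpha / 2)
        lower = count * np.exp(-z / np.sqrt(count))
        upper = count * np.exp(z / np.sqrt(count))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(lower), float(upper)


def incidence_table(
    outcomes: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    confidence: float = 0.95,
    method: str = "exact",
) -> pd.DataFrame:
    """Per-group, per-outcome incidence with exact Poisson CIs.

    ``outcomes`` is long format (subject_id, outcome, time_years,
    event); ``groups`` maps subject_id to an exposure-group label
    (a Series indexed by subject_id, or a DataFrame with subject_id and
    group columns).  Each cell holds the first-event count, the
    person-time at risk for that outcome, and the rate per 1000
    person-years with its CI.
    """
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("subject_id")["group"]
    df = outcomes.copy()
    df["group"] = df["subject_id"].map(groups)
    if df["group"].isna().any():
        raise ValueError("groups do not cover every subject in the outcome table")
    rows = []
    for (outcome, group), cell in df.groupby(["outcome", "group"], sort=False):
        events = int(cell["event"].sum())
        py = float(cell["time_years"].sum())
        if py <= 0:
            raise ValueError(f"zero person-time in cell ({outcome}, {group})")
        lo, hi = exact_poisson_ci(events, confidence, method=method)
        rows.append(
            {
                "outcome": outcome,
                "group": group,
                "events": events,
                "person_years": py,
                "rate_per_1000py": events / py * 1000.0,
                "ci_low": lo / py * 1000.0,
                "ci_high": hi / py * 1000.0,
            }
        )
    return pd.DataFrame(rows)
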