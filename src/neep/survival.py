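"""First-principles survival statistics.

Kaplan-Meier product-limit estimation, the two-group logrank test and the
O/E-ratio effect sizes used by the threshold screen. These scalar
implementations are the reference semantics; the vectorized sweep engine in
:mod:`neep.screen` must agree with them split by split.

Conventions (standard in the field):

* censored observations tied with deaths at time t are still at risk at t;
* the logrank variance at death time j is the hypergeometric
  ``V_j = n_1j n_2j d_j (n_j - d_j) / (n_j^2 (n_j - 1))``;
* the hazard ratio is the observed/expected ratio estimator
  ``(O_H/E_H) / (O_L/E_L)``, not a Cox fit — the screen deliberately
  avoids proportional-hazards regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

__all__ = ["KMCurve", "LogrankResult", "GroupEffect",
           "km_estimate", "logrank", "group_effect",
           "DEFAULT_HORIZONS"]

#: 1, 2 and 5 years expressed in days.
DEFAULT_HORIZONS = (365.0, 730.0, 1825.0)

_P_FLOOR = np.finfo(float).tiny


def _as_group(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("empty group")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and nonnegative")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("events must be 0 or 1")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray   # distinct death times, ascending
    survival: np.ndarray      # S(t) just after each death time
    at_risk: np.ndarray       # number at risk just before each death time
    n: int                    # group size

    def survival_at(self, t: float) -> float:
        """S(t): step function, 1 before the first death, last value
        carried forward beyond follow-up."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""
    t, e = _as_group(times, events)
    death_times = np.unique(t[e == 1])
    surv = []
    s = 1.0
    at_risk = []
    for tj in death_times:
        nj = int(np.sum(t >= tj))
        dj = int(np.sum((t == tj) & (e == 1)))
        s *= 1.0 - dj / nj
        surv.append(s)
        at_risk.append(nj)
    return KMCurve(event_times=death_times,
                   survival=np.array(surv),
                   at_risk=np.array(at_risk, dtype=int),
                   n=int(t.size))


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    observed_low: float
    expected_low: float
    observed_high: float
    expected_high: float
    variance_sum: float
    degenerate: bool = False


def logrank(group_low, group_high) -> LogrankResult:
    """Two-group logrank test.

    ``group_low`` and ``group_high`` are ``(times, events)`` pairs. At each
    distinct death time the observed deaths in the low group are compared
    with the hypergeometric expectation; the squared standardized sum is
    referred to the chi-square distribution with 1 df. A zero total
    variance (no informative death time) yields p = 1 with
    ``degenerate=True``.
    """
    t1, e1 = _as_group(*group_low)
    t2, e2 = _as_group(*group_high)
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    if e.sum() == 0:
        raise ValueError("at least one death is required")
    death_times = np.unique(t[e == 1])

    O1 = E1 = V = 0.0
    for tj in death_times:
        n1 = int(np.sum(t1 >= tj))
        n2 = int(np.sum(t2 >= tj))
        nj = n1 + n2
        dj = int(np.sum((t == tj) & (e == 1)))
        O1 += int(np.sum((t1 == tj) & (e1 == 1)))
        E1 += dj * n1 / nj
        if nj > 1:
            V += n1 * n2 * dj * (nj - dj) / (nj ** 2 * (nj - 1))

    total_deaths = float(e.sum())
    if V <= 1e-12:
        return LogrankResult(0.0, 1.0, O1, E1, total_deaths - O1,
                             total_deaths - E1, V, degenerate=True)
    chi = (O1 - E1) ** 2 / V
    p = float(max(_chi2.sf(chi, 1), _P_FLOOR))
    return LogrankResult(float(chi), p, float(O1), float(E1),
                         total_deaths - O1, total_deaths - E1, float(V))


@dataclass(frozen=True)
class GroupEffect:
    """Effect sizes for a low/high split: hazard ratio of high over low
    (O/E form) and per-group mortality 1 - S(t) at fixed horizons."""

    hazard_ratio: float
    mortality_low: tuple[float, ...]
    mortality_high: tuple[float, ...]
    horizons: tuple[float, ...]
    continuity_corrected: bool = False


def group_effect(group_low, group_high,
                 horizons: Sequence[float] = DEFAULT_HORIZONS) -> GroupEffect:
    """Hazard ratio (high over low) and mortality rates at fixed horizons.

    When either group has zero observed deaths, 0.5 is added to all four
    O/E tallies before forming the ratio (flagged via
    ``continuity_corrected``).
    """
    horizons = tuple(float(h) for h in horizons)
    if any(h <= 0 for h in horizons):
        raise ValueError("horizons must be positive")
    lr = logrank(group_low, group_high)
    o_l, e_l = lr.observed_low, lr.expected_low
    o_h, e_h = lr.observed_high, lr.expected_high
    corrected = False
    if o_l == 0 or o_h == 0:
        o_l, e_l, o_h, e_h = (x + 0.5 for x in (o_l, e_l, o_h, e_h))
        corrected = True
    hr = (o_h / e_h) / (o_l / e_l)

    km_low = km_estimate(*group_low)
    km_high = km_estimate(*group_high)
    mort_low = tuple(1.0 - km_low.survival_at(h) for h in horizons)
    mort_high = tuple(1.0 - km_high.survival_at(h) for h in horizons)
    return GroupEffect(float(hr), mort_low, mort_high, horizons, corrected)
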