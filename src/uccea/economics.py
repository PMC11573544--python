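"""Incremental cost-effectiveness analysis: ICER, NMB and price thresholds.

The willingness-to-pay (WTP) threshold defaults to $38,223 per QALY — three
times China's 2022 per-capita GDP, the benchmark used by Chinese
pharmacoeconomic guidelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .markov import Outcomes

__all__ = ["WTP_DEFAULT", "IncrementalResult", "incremental", "net_monetary_benefit",
           "price_threshold_search"]

WTP_DEFAULT = 38_223.0

_EPS = 1e-9


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison of two strategies (a minus b).

    ``label`` classifies the quadrant: ``"icer"`` (more costly, more
    effective — the ratio applies), ``"dominant"`` (cheaper, no less
    effective), ``"dominated"`` (costlier, less effective),
    ``"dominated_no_gain"`` (costlier, no QALY gain), or
    ``"sw_tradeoff"`` (cheaper and less effective; the ratio is read as a
    threshold — savings per QALY forgone — and the strategy is
    cost-effective when it is at least the WTP).
    """

    delta_ly: float
    delta_qaly: float
    delta_cost: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    wtp: float
    cost_effective: bool
    label: str

    def to_dict(self) -> dict:
        return {
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "delta_cost": self.delta_cost,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "wtp": self.wtp,
            "cost_effective": self.cost_effective,
            "label": self.label,
        }


def net_monetary_benefit(delta_cost: float, delta_qaly: float,
                         wtp: float = WTP_DEFAULT) -> float:
    """Incremental NMB = WTP * dQALY - dCost; positive means cost-effective."""
    return wtp * delta_qaly - delta_cost


def incremental(a: Outcomes, b: Outcomes, wtp: float = WTP_DEFAULT) -> IncrementalResult:
    """Incremental comparison of strategy ``a`` against comparator ``b``."""
    dl = a.ly - b.ly
    dq = a.qaly - b.qaly
    dc = a.cost - b.cost
    icer_q: float | None = None
    icer_l: float | None = None
    if dq > _EPS and dc > _EPS:
        icer_q = dc / dq
        label = "icer"
        ce = icer_q <= wtp
    elif dc <= _EPS and dq >= -_EPS and (abs(dc) > _EPS or abs(dq) > _EPS):
        label = "dominant"
        ce = True
    elif abs(dq) <= _EPS and dc > _EPS:
        label = "dominated_no_gain"
        ce = False
    elif dq < -_EPS and dc >= -_EPS:
        label = "dominated"
        ce = False
    elif dq < -_EPS and dc < -_EPS:
        icer_q = dc / dq  # savings per QALY forgone
        label = "sw_tradeoff"
        ce = icer_q >= wtp
    else:  # both deltas ~ 0
        label = "dominant"
        ce = True
    if dl > _EPS and dc > _EPS:
        icer_l = dc / dl
    return IncrementalResult(dl, dq, dc, icer_q, icer_l, wtp, ce, label)


def price_threshold_search(icer_at: Callable[[float], float], target_wtp: float,
                           bracket: tuple = (0.0, 1.0), tol_usd: float = 1.0,
                           max_iter: int = 200) -> float:
    """Price reduction (fraction of list price) needed to hit a target ICER.

    ``icer_at(m)`` must return the ICER with the drug's unit price scaled by
    multiplier ``m``; it must be increasing in ``m`` over ``bracket``.
    Bisection runs until ``|ICER - target| < tol_usd``.  Returns
    ``1 - multiplier``; 0 when the strategy already meets the target at the
    bracket's upper end.
    """
    lo, hi = bracket
    if not 0.0 <= lo < hi:
        raise ValueError("bracket must satisfy 0 <= lo < hi")
    icer_hi = icer_at(hi)
    if icer_hi <= target_wtp:
        return 0.0
    icer_lo = icer_at(lo)
    if icer_lo > target_wtp:
        raise ValueError(
            "bracket does not straddle the target: "
            f"ICER({lo:g}) = {icer_lo:,.2f}, ICER({hi:g}) = {icer_hi:,.2f}, "
            f"target = {target_wtp:,.2f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        icer_mid = icer_at(mid)
        if math.isfinite(icer_mid) and abs(icer_mid - target_wtp) < tol_usd:
            return 1.0 - mid
        if icer_mid > target_wtp:
            hi = mid
        else:
            lo = mid
    return 1.0 - 0.5 * (lo + hi)
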