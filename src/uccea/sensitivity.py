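"""One-way (tornado) and probabilistic sensitivity analysis with CEAC.

One-way analysis re-runs the pipeline at each parameter's low and high
bound (published range where available, otherwise +/-20% of base) holding
everything else at base, and ranks parameters by ICER spread.

Probabilistic analysis draws all parameters jointly and independently from
distributions built by method of moments — mean at the base value and
sd = (high - low) / (2 * 1.96), treating the range as a 95% CI (Gamma for
costs, Beta for utilities) — re-evaluates the model per draw, and records
paired (delta cost, delta QALY).  The cost-effectiveness acceptability
curve is the fraction of draws with positive incremental net monetary
benefit as a function of WTP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .economics import IncrementalResult

__all__ = ["ParamSpec", "TornadoEntry", "PSAResult", "build_distribution",
           "owsa", "psa", "ceac"]

#: range -> sd divisor when the range is read as a 95% CI
CI_DIVISOR = 2.0 * 1.96


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range and sampling distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str  # "gamma" | "beta"
    role: str = "other"  # "cost" | "utility" | "other"
    range_is_pm20: bool = False  # True when low/high are the +/-20% fallback

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.distribution not in ("gamma", "beta"):
            raise ValueError(f"{self.name}: distribution must be gamma or beta")
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires a range within [0, 1]")
        if self.distribution == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma requires non-negative values")

    @classmethod
    def pm20(cls, name: str, base: float, distribution: str,
             role: str = "other") -> "ParamSpec":
        """Fallback spec for a parameter published without a range."""
        return cls(name, base, 0.8 * base, 1.2 * base, distribution, role, True)


def build_distribution(spec: ParamSpec) -> Callable:
    """Sampler ``f(rng, size) -> ndarray`` matched to the spec by moments.

    Gamma: shape = mean^2/sd^2, scale = sd^2/mean.  Beta: standard moment
    inversion from (mean, sd).  A zero-width range yields a point mass.
    """
    mean = spec.base
    sd = (spec.high - spec.low) / CI_DIVISOR
    if sd == 0.0:
        return lambda rng, size=None: (np.full(size, mean) if size is not None
                                       else mean)
    if spec.distribution == "gamma":
        if mean <= 0:
            raise ValueError(f"{spec.name}: gamma needs a positive mean")
        shape = mean ** 2 / sd ** 2
        scale = sd ** 2 / mean
        return lambda rng, size=None: rng.gamma(shape, scale, size)
    # beta
    var = sd ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"{spec.name}: beta moments infeasible (sd {sd:.4g} too large "
            f"for mean {mean:.4g})")
    nu = mean * (1.0 - mean) / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return lambda rng, size=None: rng.beta(a, b, size)


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at a parameter's bounds.  Dominance cases are recorded as signed
    infinities (label retained), never silently dropped."""

    name: str
    icer_at_low: float
    icer_at_high: float
    label_low: str
    label_high: str

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_sentinel(res: IncrementalResult) -> tuple[float, str]:
    if res.label == "icer" and res.icer_per_qaly is not None:
        return res.icer_per_qaly, "icer"
    if res.label in ("dominant", "sw_tradeoff"):
        return -math.inf, res.label
    return math.inf, res.label


def owsa(evaluate: Callable[[dict], IncrementalResult],
         specs: list[ParamSpec]) -> list[TornadoEntry]:
    """One-way sensitivity analysis.

    ``evaluate(overrides)`` re-runs the pipeline with the named parameters
    set to the given values (all others at base).  Entries come back sorted
    by descending ICER spread (tornado order).
    """
    entries = []
    for spec in specs:
        lo_res = evaluate({spec.name: spec.low})
        hi_res = evaluate({spec.name: spec.high})
        lo, lab_lo = _icer_sentinel(lo_res)
        hi, lab_hi = _icer_sentinel(hi_res)
        entries.append(TornadoEntry(spec.name, lo, hi, lab_lo, lab_hi))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.name, e.icer_at_low, e.icer_at_high, e.spread) for e in entries],
        columns=["param", "low_icer", "high_icer", "spread"])


@dataclass
class PSAResult:
    """Paired incremental draws from the probabilistic sensitivity analysis."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_redrawn: int = 0
    param_draws: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.delta_cost.shape != self.delta_qaly.shape:
            raise ValueError("delta arrays must have equal length")
        if not (np.all(np.isfinite(self.delta_cost))
                and np.all(np.isfinite(self.delta_qaly))):
            raise ValueError("PSA draws must be finite")

    @property
    def n(self) -> int:
        return self.delta_cost.size

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive incremental net monetary benefit."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def psa(evaluate: Callable[[dict], IncrementalResult], specs: list[ParamSpec],
        n: int = 5000, seed: int = 0, max_redraws: int = 100) -> PSAResult:
    """Monte Carlo PSA: ``n`` joint draws, full model re-evaluation per draw.

    Parameters are drawn independently.  A draw that makes the model fail
    is logged and redrawn so the requested ``n`` is exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samplers = [(spec.name, build_distribution(spec)) for spec in specs]
    dc = np.empty(n)
    dq = np.empty(n)
    rows = []
    redrawn = 0
    for i in range(n):
        for _ in range(max_redraws + 1):
            draw = {name: float(f(rng)) for name, f in samplers}
            try:
                res = evaluate(draw)
                break
            except (ValueError, FloatingPointError, ZeroDivisionError):
                redrawn += 1
        else:
            raise RuntimeError(f"draw {i} failed {max_redraws} redraw attempts")
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
        rows.append(draw)
    return PSAResult(dc, dq, seed, redrawn, pd.DataFrame(rows))


def ceac(result: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    prob = [(result.prob_cost_effective(w)) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})
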