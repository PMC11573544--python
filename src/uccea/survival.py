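"""Parametric survival families, right-censored MLE fitting and AIC selection.

Five families are supported, each in a standard parameterization with time
measured in **months**:

===========  =====================  ==========================================
family       parameters             survival function S(t)
===========  =====================  ==========================================
exponential  ``rate`` (1/month)     ``exp(-rate * t)``
weibull      ``shape``, ``scale``   ``exp(-(t/scale)**shape)``
lognormal    ``mu``, ``sigma``      ``1 - Phi((log t - mu) / sigma)``
loglogistic  ``alpha``, ``beta``    ``1 / (1 + (t/alpha)**beta)``
gompertz     ``shape``, ``rate``    ``exp(-(rate/shape) * (exp(shape*t) - 1))``
===========  =====================  ==========================================

All scale/rate/shape parameters are strictly positive except the lognormal
location ``mu``, which is unrestricted.  The Gompertz shape is restricted to
positive values so that S(t) -> 0 as t -> infinity; the exponential is its
shape -> 0 limit.

Fitting maximizes the right-censored log-likelihood

    sum_{events} log f(t_i)  +  sum_{censored} log S(t_i)

by Nelder-Mead on log-transformed positive parameters, from five
deterministic moment-style starting points.  Model choice uses the Akaike
information criterion, AIC = 2k - 2 log L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .ipd import IPD

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "FitResult",
    "survival",
    "log_survival",
    "log_pdf",
    "loglik",
    "fit_mle",
    "fit_covariance",
    "select_by_aic",
    "median_survival",
]

# Fixed family order; also the final tie-break in AIC selection.
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("alpha", "beta"),
    "gompertz": ("shape", "rate"),
}

_TINY = 1e-300


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(
            f"unsupported family {family!r}; supported: {', '.join(FAMILIES)}"
        )


def _check_params(family: str, params: dict) -> tuple:
    _check_family(family)
    names = PARAM_NAMES[family]
    missing = set(names) - set(params)
    if missing:
        raise ValueError(f"{family} requires parameters {names}, missing {missing}")
    vals = tuple(float(params[k]) for k in names)
    for name, v in zip(names, vals):
        if not math.isfinite(v):
            raise ValueError(f"{family} parameter {name} is not finite")
        if name != "mu" and v <= 0:
            raise ValueError(f"{family} parameter {name} must be > 0, got {v}")
    return vals


def log_survival(family: str, params: dict, t) -> np.ndarray:
    """log S(t); vectorized over t (t >= 0)."""
    vals = _check_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if family == "exponential":
        (rate,) = vals
        return -rate * t
    if family == "weibull":
        shape, scale = vals
        return -((t / scale) ** shape)
    if family == "lognormal":
        mu, sigma = vals
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, _TINY)) - mu) / sigma, -np.inf)
        return special.log_ndtr(-z)
    if family == "loglogistic":
        alpha, beta = vals
        return -np.log1p((t / alpha) ** beta)
    # gompertz
    shape, rate = vals
    return -(rate / shape) * np.expm1(shape * t)


def survival(family: str, params: dict, t) -> np.ndarray:
    """S(t) in [0, 1]; S(0) = 1 for every family."""
    return np.exp(log_survival(family, params, t))


def log_pdf(family: str, params: dict, t) -> np.ndarray:
    """log f(t) for t > 0 (density of the event-time distribution)."""
    vals = _check_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("log_pdf requires t > 0")
    logt = np.log(t)
    if family == "exponential":
        (rate,) = vals
        return math.log(rate) - rate * t
    if family == "weibull":
        shape, scale = vals
        return (
            math.log(shape)
            - shape * math.log(scale)
            + (shape - 1.0) * logt
            - (t / scale) ** shape
        )
    if family == "lognormal":
        mu, sigma = vals
        z = (logt - mu) / sigma
        return -0.5 * z * z - logt - math.log(sigma) - 0.5 * math.log(2 * math.pi)
    if family == "loglogistic":
        alpha, beta = vals
        u = beta * (logt - math.log(alpha))
        # f = (beta/alpha)(t/alpha)^(beta-1) / (1+(t/alpha)^beta)^2
        return (
            math.log(beta)
            - logt
            + u
            - 2.0 * np.logaddexp(0.0, u)
        )
    # gompertz: h(t) = rate * exp(shape*t)
    shape, rate = vals
    return math.log(rate) + shape * t - (rate / shape) * np.expm1(shape * t)


def loglik(family: str, params: dict, times, events) -> float:
    """Right-censored log-likelihood of ``params`` for the given records."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ll = 0.0
    ev = events == 1
    if ev.any():
        ll += float(np.sum(log_pdf(family, params, times[ev])))
    if (~ev).any():
        ll += float(np.sum(log_survival(family, params, times[~ev])))
    return ll


@dataclass
class FitResult:
    """A fitted parametric survival model.

    ``aic = 2k - 2 loglik`` with ``k = len(params)``.  ``converged`` is True
    when at least one optimizer start terminated successfully.
    """

    family: str
    params: dict
    loglik: float
    aic: float
    n: int
    converged: bool
    n_events: int = 0
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_params(cls, family: str, params: dict, n: int = 0) -> "FitResult":
        """Wrap externally supplied parameters (e.g. a calibrated model)."""
        _check_params(family, params)
        return cls(family, dict(params), math.nan, math.nan, n, True)

    def survival(self, t) -> np.ndarray:
        return survival(self.family, self.params, t)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# MLE fitting


def _to_params(family: str, theta: np.ndarray) -> dict:
    """Map unconstrained optimizer coordinates to the natural parameters."""
    names = PARAM_NAMES[family]
    out = {}
    for name, x in zip(names, theta):
        out[name] = x if name == "mu" else math.exp(x)
    return out


def _from_params(family: str, params: dict) -> np.ndarray:
    names = PARAM_NAMES[family]
    return np.array(
        [params[n] if n == "mu" else math.log(params[n]) for n in names]
    )


def _starts(family: str, times: np.ndarray, events: np.ndarray) -> list[dict]:
    """Five deterministic moment-style starting points per family."""
    ev_t = times[events == 1]
    mean_t = float(ev_t.mean())
    med_t = float(np.median(ev_t))
    log_ev = np.log(ev_t)
    mu0 = float(log_ev.mean())
    sig0 = float(max(log_ev.std(), 0.05))
    rate0 = events.sum() / times.sum()  # exact exponential MLE
    if family == "exponential":
        return [{"rate": rate0 * m} for m in (1.0, 0.3, 3.0, 0.1, 10.0)]
    if family == "weibull":
        return [
            {"shape": s, "scale": mean_t * m}
            for s, m in ((1.0, 1.0), (0.7, 1.0), (1.5, 1.0), (1.0, 0.4), (2.5, 1.0))
        ]
    if family == "lognormal":
        return [
            {"mu": mu0 + dm, "sigma": sig0 * ms}
            for dm, ms in ((0, 1), (0, 0.5), (0, 2), (0.7, 1), (-0.7, 1))
        ]
    if family == "loglogistic":
        # logistic sd = sigma*pi/sqrt(3) on the log scale => beta ~ pi/(sig*sqrt 3)
        b0 = max(math.pi / (sig0 * math.sqrt(3.0)), 0.2)
        return [
            {"alpha": med_t * am, "beta": b0 * bm}
            for am, bm in ((1, 1), (1, 0.5), (1, 2), (0.5, 1), (2, 1))
        ]
    # gompertz: start near the exponential limit and fan out in shape
    return [
        {"shape": s, "rate": rate0 * m}
        for s, m in ((0.01, 1.0), (0.001, 1.0), (0.05, 1.0), (0.2, 0.5), (0.005, 3.0))
    ]


def fit_mle(ipd: IPD, family: str, n_starts: int = 5) -> FitResult:
    """Maximum-likelihood fit of one parametric family to right-censored IPD.

    Requires at least 10 records with at least 3 observed events.  The
    optimizer runs from up to ``n_starts`` deterministic starting points and
    keeps the best converged solution; ``converged=False`` (with diagnostics)
    is returned only when every start fails.
    """
    _check_family(family)
    times, events = ipd.times, ipd.events
    if len(ipd) < 10:
        raise ValueError("need at least 10 records to fit a parametric model")
    if ipd.n_events < 3:
        raise ValueError("no events" if ipd.n_events == 0 else "need at least 3 events")

    if family == "exponential":
        # closed-form MLE: rate = events / total follow-up time
        rate = ipd.n_events / float(times.sum())
        ll = loglik(family, {"rate": rate}, times, events)
        return FitResult(family, {"rate": rate}, ll, 2.0 - 2.0 * ll, len(ipd), True,
                         ipd.n_events)

    def nll(theta: np.ndarray) -> float:
        params = _to_params(family, theta)
        try:
            val = -loglik(family, params, times, events)
        except (OverflowError, FloatingPointError):
            return math.inf
        return val if math.isfinite(val) else math.inf

    best = None
    messages = []
    for start in _starts(family, times, events)[:n_starts]:
        theta0 = _from_params(family, start)
        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        messages.append(str(res.message))
        if res.success and math.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        return FitResult(family, {}, math.nan, math.nan, len(ipd), False,
                         ipd.n_events, {"messages": messages})
    params = _to_params(family, best.x)
    ll = -float(best.fun)
    k = len(PARAM_NAMES[family])
    return FitResult(family, params, ll, 2.0 * k - 2.0 * ll, len(ipd), True,
                     ipd.n_events)


def fit_all(ipd: IPD, families=FAMILIES) -> list[FitResult]:
    """Fit every requested family to the same records."""
    return [fit_mle(ipd, fam) for fam in families]


def fit_covariance(fit: FitResult, ipd: IPD, rel_step: float = 1e-4) -> np.ndarray:
    """Estimated covariance of the MLE on the log-parameter scale.

    Central finite-difference Hessian of the negative log-likelihood at the
    optimum, inverted.  Used only by the optional survival-uncertainty switch
    of the probabilistic sensitivity analysis.
    """
    theta = _from_params(fit.family, fit.params)
    k = theta.size

    def nll(th):
        return -loglik(fit.family, _to_params(fit.family, th), ipd.times, ipd.events)

    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return np.linalg.inv(H)


def select_by_aic(fits: list[FitResult]) -> FitResult:
    """Best converged fit by minimum AIC.

    Ties are broken by fewer parameters, then by the fixed family order of
    :data:`FAMILIES`.
    """
    converged = [f for f in fits if f.converged and math.isfinite(f.aic)]
    if not converged:
        raise ValueError("no converged fit to select from")
    return min(
        converged,
        key=lambda f: (f.aic, len(PARAM_NAMES[f.family]), FAMILIES.index(f.family)),
    )


def median_survival(fit: FitResult, t_max: float = 1e6) -> float:
    """Time (months) at which S(t) = 0.5.

    Closed forms: exponential ln2/rate; Weibull scale*(ln2)^(1/shape);
    lognormal exp(mu); log-logistic alpha; Gompertz log1p(shape*ln2/rate)/shape.
    """
    if not fit.converged:
        raise ValueError("median_survival requires a converged fit")
    p = fit.params
    fam = fit.family
    ln2 = math.log(2.0)
    if fam == "exponential":
        m = ln2 / p["rate"]
    elif fam == "weibull":
        m = p["scale"] * ln2 ** (1.0 / p["shape"])
    elif fam == "lognormal":
        m = math.exp(p["mu"])
    elif fam == "loglogistic":
        m = p["alpha"]
    elif fam == "gompertz":
        m = math.log1p(p["shape"] * ln2 / p["rate"]) / p["shape"]
    else:  # pragma: no cover
        _check_family(fam)
    if m > t_max:
        raise ValueError(f"survival does not reach 0.5 within {t_max:g} months")
    return m
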