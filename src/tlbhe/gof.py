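"""Goodness-of-fit statistics, information criteria and reference fits.

The comparison tables report, for each candidate model, the minimized
negative log-likelihood together with AIC/CAIC/BIC/HQIC and the KS, Cramer-
von Mises and Anderson-Darling statistics evaluated at the fitted
parameters.  Reference fits are provided for the exponential, Weibull
(``theta beta x^{beta-1} e^{-theta x^beta}``) and baseline Burr-Hatke
exponential distributions alongside the TL-BHE itself.

KS p-values use the asymptotic Kolmogorov distribution at sqrt(n)*D with
no adjustment for estimated parameters; this is approximate but matches
the convention of the comparison tables this module mirrors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Callable, NamedTuple

import numpy as np
from scipy import optimize, special

from . import distribution as dist
from . import estimation
from .distribution import Params
from .estimation import Sample, _as_sorted

__all__ = [
    "GofReport",
    "InformationCriteria",
    "ks_statistic",
    "cvm_statistic",
    "ad_statistic",
    "information_criteria",
    "fit_exponential",
    "fit_weibull",
    "fit_bhe",
    "fit_tlbhe",
    "compare_models",
]

_CLIP_LO, _CLIP_HI = 1e-300, 1.0 - 1e-12


class InformationCriteria(NamedTuple):
    aic: float
    caic: float
    bic: float
    hqic: float


@dataclass
class GofReport:
    model: str
    estimates: dict
    nll: float
    aic: float
    caic: float
    bic: float
    hqic: float
    ks: float
    ks_pvalue: float
    cvm: float
    ad: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return asdict(self)


def _clip_warn(F: np.ndarray) -> np.ndarray:
    n_bad = int(np.sum((F <= 0.0) | (F >= 1.0)))
    if n_bad:
        warnings.warn(f"{n_bad} fitted cdf values clipped away from {{0,1}}", RuntimeWarning)
    return np.clip(F, _CLIP_LO, _CLIP_HI)


def ks_statistic(s, cdf_fn: Callable) -> tuple[float, float]:
    """Kolmogorov-Smirnov D and its asymptotic p-value."""
    x = _as_sorted(s)
    n = x.size
    F = np.asarray(cdf_fn(x), dtype=float)
    i = np.arange(1, n + 1)
    D = float(max((i / n - F).max(), (F - (i - 1) / n).max()))
    p = float(special.kolmogorov(math.sqrt(n) * D))
    return D, p


def cvm_statistic(s, cdf_fn: Callable) -> float:
    """Cramer-von Mises W^2 = 1/(12n) + sum (F_i - (2i-1)/(2n))^2."""
    x = _as_sorted(s)
    n = x.size
    F = np.asarray(cdf_fn(x), dtype=float)
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((F - (2 * i - 1) / (2.0 * n)) ** 2))


def ad_statistic(s, cdf_fn: Callable) -> float:
    """Anderson-Darling A^2 = -n - (1/n) sum (2i-1)[log F_i + log(1-F_{n+1-i})]."""
    x = _as_sorted(s)
    n = x.size
    F = _clip_warn(np.asarray(cdf_fn(x), dtype=float))
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2 * i - 1) * (np.log(F) + np.log1p(-F[::-1]))) / n)


def information_criteria(nll: float, k: int, n: int) -> InformationCriteria:
    """AIC, CAIC (= AICc), BIC and HQIC from the minimized nll."""
    if k > 0 and n <= k + 1:
        raise ValueError("CAIC requires n > k + 1")
    aic = 2.0 * k + 2.0 * nll
    caic = aic + (2.0 * k * (k + 1) / (n - k - 1) if k > 0 else 0.0)
    bic = k * math.log(n) + 2.0 * nll
    hqic = 2.0 * k * math.log(math.log(n)) + 2.0 * nll
    return InformationCriteria(aic, caic, bic, hqic)


def _report(model: str, estimates: dict, nll: float, k: int, s, cdf_fn) -> GofReport:
    x = _as_sorted(s)
    n = x.size
    ic = information_criteria(nll, k, n)
    D, p = ks_statistic(x, cdf_fn)
    return GofReport(
        model=model,
        estimates=estimates,
        nll=float(nll),
        aic=ic.aic,
        caic=ic.caic,
        bic=ic.bic,
        hqic=ic.hqic,
        ks=D,
        ks_pvalue=p,
        cvm=cvm_statistic(x, cdf_fn),
        ad=ad_statistic(x, cdf_fn),
        n=n,
        k=k,
    )


def fit_exponential(s) -> GofReport:
    """Closed-form exponential MLE: lambda = n / sum(x)."""
    x = _as_sorted(s)
    n = x.size
    lam = n / x.sum()
    nll = -(n * math.log(lam) - lam * x.sum())
    return _report("Exp", {"lambda": lam}, nll, 1, x, lambda v: -np.expm1(-lam * np.asarray(v)))


def fit_weibull(s) -> GofReport:
    """Weibull MLE in the ``theta beta x^{beta-1} e^{-theta x^beta}`` form.

    Profiled: theta(beta) = n / sum(x^beta), then 1-d search over log beta.
    """
    x = _as_sorted(s)
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: Weibull shape is unidentifiable")
    slx = np.log(x).sum()

    def profile_nll(lb):
        b = math.exp(lb)
        sxb = np.sum(x**b)
        th = n / sxb
        return -(n * math.log(th) + n * lb + (b - 1.0) * slx - th * sxb)

    res = optimize.minimize_scalar(profile_nll, bounds=(-5, 5), method="bounded",
                                   options=dict(xatol=1e-12))
    b = math.exp(res.x)
    th = n / np.sum(x**b)
    return _report(
        "Weibull",
        {"theta": th, "beta": b},
        float(res.fun),
        2,
        x,
        lambda v: -np.expm1(-th * np.asarray(v, float) ** b),
    )


def fit_bhe(s) -> GofReport:
    """Baseline BHE 1-d MLE of the density ``pi e^{-pi x}(2+pi x)/(1+pi x)^2``."""
    x = _as_sorted(s)
    n = x.size

    def nll(lp):
        pi = math.exp(lp)
        px = pi * x
        return -(n * math.log(pi) - px.sum() + np.log(2.0 + px).sum() - 2.0 * np.log1p(px).sum())

    lm = math.log(1.0 / x.mean())
    res = optimize.minimize_scalar(nll, bounds=(lm - 10, lm + 10), method="bounded",
                                   options=dict(xatol=1e-12))
    pi = math.exp(res.x)
    return _report("BHE", {"pi": pi}, float(res.fun), 1, x, lambda v: dist.bhe_cdf(v, pi))


def fit_tlbhe(s, **kw) -> GofReport:
    r = estimation.fit_ml(s, **kw)
    p = r.params
    return _report(
        "TL-BHE",
        {"pi": p.pi, "alpha": p.alpha},
        r.objective_value,
        2,
        s,
        lambda v: dist.cdf(v, p),
    )


_FITTERS = {
    "tlbhe": fit_tlbhe,
    "bhe": fit_bhe,
    "weibull": fit_weibull,
    "exp": fit_exponential,
}


def compare_models(s, models=("tlbhe", "bhe", "weibull", "exp")) -> list[GofReport]:
    """Fit each requested model and return its GofReport, AIC-sorted."""
    reports = []
    for m in models:
        key = m.lower()
        if key not in _FITTERS:
            raise ValueError(f"unknown model {m!r}; choose from {sorted(_FITTERS)}")
        reports.append(_FITTERS[key](s))
    return sorted(reports, key=lambda r: r.aic)
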