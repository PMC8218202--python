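"""Monotherapy dose-response modelling.

Single-agent responses are modelled with the four-parameter log-logistic
curve that is standard for percent-inhibition screens,

    y(x) = d_min + (d_max - d_min) / (1 + (m / x)**lam),

where ``d_min`` is the zero-dose asymptote, ``d_max`` the infinite-dose
asymptote, ``m`` the inflection dose (relative IC50) and ``lam`` the Hill
slope.  From the fitted curve we derive

* the relative IC50 (``m``) and, when the curve crosses 50% inhibition
  inside the tested range, the absolute IC50;
* RI (relative inhibition), the normalized area under the curve on the
  log10-dose axis, interpretable as an average percent inhibition over the
  tested concentration range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MonotherapyCurve",
    "SingleAgentSensitivity",
    "InvalidInputError",
    "fit_curve",
    "predict_response",
    "compute_ri",
    "absolute_ic50",
    "single_agent_sensitivity",
]

# Fit bounds: Hill slope in (0.05, 10], inflection within 1e2 of the tested
# range, asymptotes inside the +/-200% quality window with headroom.
LAM_MIN = 0.05
LAM_MAX = 10.0
ASYMPTOTE_LO = -200.0
ASYMPTOTE_HI = 300.0
FLAT_RESPONSE_RANGE = 1.0  # pp; below this the block is treated as inert


class InvalidInputError(ValueError):
    """Raised when an operation receives input outside its contract."""


@dataclass(frozen=True)
class MonotherapyCurve:
    """Fitted four-parameter log-logistic dose-response model.

    ``d_min`` is the response as dose -> 0 and ``d_max`` as dose -> inf;
    for growth-stimulating (decreasing) curves ``d_min > d_max`` and
    ``decreasing`` is set.  ``flat`` marks degenerate fits where the
    observed response spread was below :data:`FLAT_RESPONSE_RANGE`.
    """

    d_min: float
    d_max: float
    m: float
    lam: float
    c_lo: float
    c_hi: float
    fit_rss: float = 0.0
    flat: bool = False
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.c_lo >= self.c_hi:
            raise InvalidInputError("c_lo must be < c_hi")
        if self.lam <= 0:
            raise InvalidInputError("Hill slope must be positive")

    @property
    def decreasing(self) -> bool:
        return (not self.flat) and self.d_min > self.d_max

    def __call__(self, x) -> np.ndarray | float:
        return predict_response(self, x)


@dataclass(frozen=True)
class SingleAgentSensitivity:
    """RI plus relative/absolute IC50 of one fitted monotherapy."""

    ri: float
    ic50_relative: float
    ic50_absolute: float | None
    ic50_absolute_in_range: bool


def _loglogistic(x, d_min, d_max, log10_m, lam):
    """Vectorized model evaluation; x = 0 maps to d_min."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, d_min, dtype=float)
    pos = x > 0
    # (m/x)^lam computed in log space to avoid overflow at extreme doses
    z = lam * (log10_m - np.log10(x[pos])) * math.log(10.0)
    out[pos] = d_min + (d_max - d_min) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return out


def predict_response(curve: MonotherapyCurve, x) -> np.ndarray | float:
    """Evaluate the fitted curve at dose ``x`` (scalar or array).

    ``x = 0`` returns ``d_min`` (drug absent); negative doses are invalid.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("concentrations must be non-negative")
    if curve.flat:
        out = np.full(arr.shape, curve.d_min, dtype=float)
    else:
        out = _loglogistic(arr, curve.d_min, curve.d_max, math.log10(curve.m), curve.lam)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def fit_curve(
    concentrations: Sequence[float],
    responses: Sequence[float],
    *,
    unit: str = "uM",
    flat_tol: float = FLAT_RESPONSE_RANGE,
    block_id: str | None = None,
    pin_d_min: float | None = None,
) -> MonotherapyCurve:
    """Least-squares fit of the log-logistic model to (dose, response) pairs.

    Doses equal to zero are treated as the untreated-control anchor and
    enter the fit at dose 0 (predicted ``d_min``).  Requires at least two
    distinct positive doses with finite responses.

    ``pin_d_min`` fixes the zero-dose asymptote (used by the ZIP
    potency-shift fits, where a combination slice starts from the partner
    drug's monotherapy effect).
    """
    ctx = f" in block {block_id}" if block_id else ""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"dose/response length mismatch{ctx}")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError(f"non-finite responses{ctx}")
    if np.any(x < 0):
        raise InvalidInputError(f"negative concentrations{ctx}")
    pos = x > 0
    distinct = np.unique(x[pos])
    if distinct.size < 2:
        raise InvalidInputError(
            f"need at least 2 distinct positive concentrations{ctx}"
        )

    c_lo, c_hi = float(distinct[0]), float(distinct[-1])
    spread = float(y.max() - y.min())
    if spread < flat_tol and pin_d_min is None:
        mean = float(y.mean())
        rss = float(np.sum((y - mean) ** 2))
        return MonotherapyCurve(
            d_min=mean, d_max=mean, m=math.sqrt(c_lo * c_hi), lam=1.0,
            c_lo=c_lo, c_hi=c_hi, fit_rss=rss, flat=True, unit=unit,
        )

    lo_m = math.log10(c_lo / 100.0)
    hi_m = math.log10(c_hi * 100.0)

    ymin, ymax = float(y.min()), float(y.max())
    # initial m: dose whose response is nearest the half-effect level
    half = (ymin + ymax) / 2.0
    xp, yp = x[pos], y[pos]
    m0 = float(xp[np.argmin(np.abs(yp - half))])
    m0 = min(max(m0, 10 ** lo_m), 10 ** hi_m)

    if pin_d_min is None:
        def resid(p):
            return _loglogistic(x, p[0], p[1], p[2], p[3]) - y

        p0 = [ymin, ymax, math.log10(m0), 1.0]
        lower = [ASYMPTOTE_LO, ASYMPTOTE_LO, lo_m, LAM_MIN]
        upper = [ASYMPTOTE_HI, ASYMPTOTE_HI, hi_m, LAM_MAX]
    else:
        def resid(p):
            return _loglogistic(x, pin_d_min, p[0], p[1], p[2]) - y

        p0 = [ymax if ymax > pin_d_min else ymin, math.log10(m0), 1.0]
        lower = [ASYMPTOTE_LO, lo_m, LAM_MIN]
        upper = [ASYMPTOTE_HI, hi_m, LAM_MAX]

    p0 = np.clip(p0, lower, upper)
    sol = least_squares(resid, p0, bounds=(lower, upper), method="trf")
    rss = float(np.sum(sol.fun ** 2))
    if pin_d_min is None:
        d0, d1, logm, lam = sol.x
    else:
        d0 = pin_d_min
        d1, logm, lam = sol.x
    return MonotherapyCurve(
        d_min=float(d0), d_max=float(d1), m=float(10 ** logm), lam=float(lam),
        c_lo=c_lo, c_hi=c_hi, fit_rss=rss, flat=False, unit=unit,
    )


def compute_ri(curve: MonotherapyCurve, c_lo: float | None = None,
               c_hi: float | None = None) -> float:
    """RI: normalized area under the curve on the log10-dose axis.

    RI = 1/(log10 c_hi - log10 c_lo) * int y(10^t) dt, t over the tested
    log10 range.  Uses the analytic antiderivative of the log-logistic on
    the log axis, so the result is exact for the fitted model.
    """
    c_lo = curve.c_lo if c_lo is None else float(c_lo)
    c_hi = curve.c_hi if c_hi is None else float(c_hi)
    if not (c_lo > 0 and c_hi > 0):
        raise InvalidInputError("integration range must be positive")
    if c_lo >= c_hi:
        raise InvalidInputError("integration range must have positive width")
    if curve.flat:
        return curve.d_min
    t_lo, t_hi = math.log10(c_lo), math.log10(c_hi)
    k = curve.lam * math.log(10.0)
    t_m = math.log10(curve.m)
    # int 1/(1+exp(-k(t-t_m))) dt = log(1+exp(k(t-t_m)))/k
    F = lambda t: np.logaddexp(0.0, k * (t - t_m)) / k
    frac = (F(t_hi) - F(t_lo)) / (t_hi - t_lo)
    return float(curve.d_min + (curve.d_max - curve.d_min) * frac)


def absolute_ic50(curve: MonotherapyCurve, level: float = 50.0) -> tuple[float | None, bool]:
    """Dose at which the fitted curve reaches ``level`` percent inhibition.

    Returns ``(dose, in_range)``; ``(None, False)`` when the curve never
    attains the level or the crossing lies outside the tested range.
    """
    if curve.flat:
        return None, False
    lo, hi = sorted((curve.d_min, curve.d_max))
    if not (lo < level < hi):
        return None, False
    ratio = (level - curve.d_min) / (curve.d_max - level)
    x = curve.m * ratio ** (1.0 / curve.lam)
    in_range = curve.c_lo <= x <= curve.c_hi
    return (float(x), True) if in_range else (None, False)


def single_agent_sensitivity(curve: MonotherapyCurve) -> SingleAgentSensitivity:
    """Bundle RI with the relative and absolute IC50 of a fitted curve."""
    ic50_abs, in_range = absolute_ic50(curve)
    return SingleAgentSensitivity(
        ri=compute_ri(curve),
        ic50_relative=curve.m,
        ic50_absolute=ic50_abs,
        ic50_absolute_in_range=in_range,
    )
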