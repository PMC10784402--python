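"""First-order degradation kinetics for soil incubation series.

Fits ``C(t) = C0 * exp(-k t)`` to residual-concentration time series by
nonlinear least squares on the untransformed scale (log-linearisation is
available but breaks down at zero or near-LOQ concentrations), and derives
the half-life ``t_1/2 = ln 2 / k``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from ._errors import FitFailureError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["IncubationSeries", "KineticFit", "fit_first_order", "half_life"]


@dataclass(frozen=True)
class IncubationSeries:
    """Residual concentrations of a compound over an incubation.

    ``times`` are days since spiking (strictly increasing, >= 0);
    ``concentrations`` are mg/kg dry soil.
    """

    times: np.ndarray
    concentrations: np.ndarray
    layer_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        t, c = self.times, self.concentrations
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidInputError("times and concentrations must be equal-length 1-D")
        if len(t) < 4:
            raise InvalidInputError(f"need >= 4 observations, got {len(t)}")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be non-negative and strictly increasing")
        if np.any(c < 0):
            raise InvalidInputError("concentrations must be >= 0")


@dataclass(frozen=True)
class KineticFit:
    """First-order fit: rate ``k`` (1/d), initial level ``c0`` (mg/kg),
    half-life (d), coefficient of determination and decay significance."""

    k: float
    c0: float
    r_squared: float
    p_value: float
    half_life: float
    k_se: float = float("nan")
    c0_se: float = float("nan")
    meta: dict = field(default_factory=dict, compare=False)


def half_life(k: float) -> float:
    """Half-life ``ln 2 / k`` in days; undefined for k <= 0."""
    if k <= 0:
        raise InvalidInputError(f"half-life undefined for k <= 0 (got {k})")
    return math.log(2.0) / k


def fit_first_order(
    series: IncubationSeries,
    loq: float | None = None,
    method: Literal["nls", "loglinear"] = "nls",
) -> KineticFit:
    """Fit ``C(t) = c0 * exp(-k t)`` to an incubation series.

    Observations below ``loq`` are excluded (not substituted) and logged.
    ``p_value`` is from an F-test of the exponential-decay model against
    the constant-mean model, so a flat series — no evidence of decay —
    yields a large p-value regardless of its level.

    Raises
    ------
    FitFailureError
        If all concentrations are zero or the optimiser does not converge.
    """
    t = series.times
    c = series.concentrations
    if loq is not None:
        keep = c >= loq
        dropped = int((~keep).sum())
        if dropped:
            logger.info("excluding %d observation(s) below LOQ=%g", dropped, loq)
        t, c = t[keep], c[keep]
    if len(t) < 4:
        raise FitFailureError("fewer than 4 usable observations after LOQ filtering")
    if np.all(c == 0):
        raise FitFailureError("all concentrations are zero; decay model undefined")

    # start values from a log-linear regression on the positive subset
    pos = c > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(c[pos]), 1)
        k0 = max(-slope, 0.0)
        c00 = math.exp(intercept)
    else:
        k0, c00 = 0.01, float(c.max())

    if method == "loglinear":
        if not np.all(pos):
            raise InvalidInputError("log-linear mode requires strictly positive data")
        design = np.column_stack([t, np.ones_like(t)])
        resid_log = np.log(c) - design @ np.array([slope, intercept])
        dof = len(t) - 2
        sigma2 = float(resid_log @ resid_log) / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(design.T @ design)
        k_hat, c0_hat = max(-slope, 0.0), math.exp(intercept)
        k_se = math.sqrt(max(cov[0, 0], 0.0))
        c0_se = c0_hat * math.sqrt(max(cov[1, 1], 0.0))
        meta = {"estimator": "loglinear"}
    elif method == "nls":
        def model(tt: np.ndarray, c0: float, k: float) -> np.ndarray:
            return c0 * np.exp(-k * tt)

        try:
            popt, pcov = optimize.curve_fit(
                model,
                t,
                c,
                p0=[max(c00, 1e-12), k0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            resid = c - c00 * np.exp(-k0 * t)
            raise FitFailureError(
                f"first-order fit did not converge: {exc}",
                residual_norm=float(np.linalg.norm(resid)),
            ) from exc
        c0_hat, k_hat = float(popt[0]), float(popt[1])
        c0_se = float(math.sqrt(max(pcov[0, 0], 0.0)))
        k_se = float(math.sqrt(max(pcov[1, 1], 0.0)))
        meta = {"estimator": "nls"}
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    fitted = c0_hat * np.exp(-k_hat * t)
    resid = c - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # decay significance: exponential model vs constant mean (1 extra param)
    n = len(t)
    if ss_res <= 0:
        p_value = 0.0 if ss_tot > ss_res else 1.0
    elif ss_tot <= ss_res:
        p_value = 1.0
    else:
        f_stat = (ss_tot - ss_res) / 1.0 / (ss_res / (n - 2))
        p_value = float(stats.f.sf(f_stat, 1, n - 2))

    return KineticFit(
        k=k_hat,
        c0=c0_hat,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        p_value=p_value,
        half_life=half_life(k_hat) if k_hat > 0 else math.inf,
        k_se=k_se,
        c0_se=c0_se,
        meta=meta | {"n_used": n},
    )
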