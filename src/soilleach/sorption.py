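"""Batch-equilibrium sorption analysis.

Estimates pesticide retention parameters from adsorption and single-point
desorption assays: the amount sorbed per unit soil mass from the solution
depletion mass balance, linear (``x/m = K_d * C_eq``) and Freundlich
(``x/m = K_f * C_eq**n``) isotherm fits, adsorption/desorption percentages,
the apparent hysteresis index ``HI = K_d24 / K_d - 1``, organic-carbon
normalisation, and the pH-dependent ionisation of weak acids and bases.

The linear fit is constrained through the origin because the isotherm has
no intercept term; an unconstrained mode exists for diagnostics only.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from ._errors import FitFailureError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SorptionObservation",
    "IsothermFit",
    "RetentionSummary",
    "sorbed_amount",
    "single_point_desorption",
    "fit_linear_isotherm",
    "fit_freundlich_isotherm",
    "percent_adsorption",
    "percent_desorption",
    "hysteresis_index",
    "oc_normalize",
    "protonated_fraction",
    "retention_summary",
]


@dataclass(frozen=True)
class SorptionObservation:
    """One batch-equilibrium tube.

    Parameters
    ----------
    c_init : float
        Initial solution concentration (mg/L).
    c_eq : float
        Equilibrium solution concentration after the 24-h shake (mg/L).
    volume : float
        Solution volume added to the tube (L).
    soil_mass : float
        Dry soil mass (kg).
    carryover_volume : float
        Solution retained in the soil pellet after the adsorption
        supernatant is removed (L); it carries dissolved pesticide into
        the desorption step and must be credited in that mass balance.
    """

    c_init: float
    c_eq: float
    volume: float
    soil_mass: float
    carryover_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise InvalidInputError(f"volume must be > 0, got {self.volume}")
        if self.soil_mass <= 0:
            raise InvalidInputError(f"soil_mass must be > 0, got {self.soil_mass}")
        if self.carryover_volume < 0:
            raise InvalidInputError("carryover_volume must be >= 0")
        if not 0 <= self.c_eq <= self.c_init:
            raise InvalidInputError(
                f"require 0 <= c_eq <= c_init, got c_eq={self.c_eq}, c_init={self.c_init}"
            )


@dataclass(frozen=True)
class IsothermFit:
    """Fitted isotherm parameters with diagnostics.

    ``k_y`` is the affinity coefficient: L/kg for the linear model,
    (mg/kg)(mg/L)^-n for the Freundlich model.  ``n`` is the adsorption
    energy exponent (exactly 1 for the linear model).
    """

    model: Literal["linear", "freundlich"]
    k_y: float
    n: float
    r_squared: float
    k_y_se: float
    n_se: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.k_y < 0:
            raise InvalidInputError("k_y must be >= 0")
        if self.model == "linear" and self.n != 1.0:
            raise InvalidInputError("linear model requires n == 1")


@dataclass(frozen=True)
class RetentionSummary:
    """Derived retention indices for one soil layer."""

    pct_ads: float
    pct_ads_24: float
    pct_des: float
    hi: float
    k_oc: float | None = None
    k_foc: float | None = None


def sorbed_amount(obs: SorptionObservation) -> float:
    """Amount sorbed per unit soil mass (mg/kg) from solution depletion.

    ``(c_init - c_eq) * volume / soil_mass``; never negative given the
    observation invariants.
    """
    return (obs.c_init - obs.c_eq) * obs.volume / obs.soil_mass


def single_point_desorption(
    obs: SorptionObservation,
    c_eq_des: float,
    fresh_volume: float | None = None,
) -> tuple[float, float]:
    """Sorbed amount remaining after one 24-h desorption step.

    After adsorption the supernatant is replaced with ``fresh_volume`` of
    clean background electrolyte, but the pellet retains
    ``obs.carryover_volume`` of solution at the adsorption equilibrium
    concentration.  The carryover is assumed fully mixed with the fresh
    solution before the desorption shake, so the mass released from the
    solid is

        ``c_eq_des * (fresh_volume + carryover) - c_eq_ads * carryover``

    Parameters
    ----------
    obs : SorptionObservation
        The adsorption-step observation for the same tube.
    c_eq_des : float
        Solution concentration after the desorption shake (mg/L).
    fresh_volume : float, optional
        Clean solution volume added for desorption (L); defaults to the
        adsorption volume.

    Returns
    -------
    (x_m_24, released_mass)
        Remaining sorbed amount (mg/kg) and the mass released from the
        solid (mg).
    """
    if c_eq_des < 0:
        raise InvalidInputError("c_eq_des must be >= 0")
    v = obs.volume if fresh_volume is None else fresh_volume
    if v <= 0:
        raise InvalidInputError("fresh_volume must be > 0")
    released = c_eq_des * (v + obs.carryover_volume) - obs.c_eq * obs.carryover_volume
    x_m_24 = sorbed_amount(obs) - released / obs.soil_mass
    return x_m_24, released


def _as_points(points: Sequence) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("points must be a sequence of (c_eq, x_m) pairs")
    return arr[:, 0], arr[:, 1]


def fit_linear_isotherm(points: Sequence, through_origin: bool = True) -> IsothermFit:
    """Least-squares linear isotherm ``x/m = K_d * C_eq``.

    The default fit is through the origin, matching the isotherm's
    functional form; ``r_squared`` is then computed against the
    zero-intercept model (total sum of squares about zero).  Set
    ``through_origin=False`` for an unconstrained diagnostic fit whose
    intercept is reported in ``meta``.
    """
    c, x = _as_points(points)
    if len(c) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(c)}")
    if np.allclose(c, c[0]):
        raise InvalidInputError("c_eq values must not all be identical")
    if through_origin:
        scc = float(c @ c)
        slope = float(c @ x) / scc
        resid = x - slope * c
        dof = len(c) - 1
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        se = math.sqrt(sigma2 / scc)
        ss_tot = float(x @ x)  # about zero for the no-intercept model
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        meta = {"intercept": 0.0, "r_squared_basis": "about_zero"}
    else:
        design = np.column_stack([c, np.ones_like(c)])
        coef, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        resid = x - design @ coef
        dof = len(c) - 2
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = math.sqrt(cov[0, 0])
        ss_tot = float(np.sum((x - x.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        meta = {"intercept": intercept, "r_squared_basis": "about_mean"}
    return IsothermFit(
        model="linear",
        k_y=max(slope, 0.0),
        n=1.0,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        k_y_se=se,
        n_se=0.0,
        meta=meta,
    )


def _loglog_start(c: np.ndarray, x: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Log-log linearisation: ln(x/m) = ln K + n ln C_eq."""
    lc, lx = np.log(c), np.log(x)
    n_hat, logk = np.polyfit(lc, lx, 1)
    design = np.column_stack([lc, np.ones_like(lc)])
    resid = lx - design @ np.array([n_hat, logk])
    dof = len(c) - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return float(math.exp(logk)), float(n_hat), cov


def fit_freundlich_isotherm(
    points: Sequence, method: Literal["nls", "loglog"] = "nls"
) -> IsothermFit:
    """Freundlich isotherm fit ``x/m = K_f * C_eq**n``.

    The default estimator is nonlinear least squares on the untransformed
    model, started from the log-log linearisation; ``method="loglog"``
    returns the linearised estimate itself (standard errors via the delta
    method).  ``r_squared`` is always evaluated on the untransformed scale.
    """
    c, x = _as_points(points)
    if len(c) < 4:
        raise InsufficientDataError(f"need >= 4 points, got {len(c)}")
    if np.any(c <= 0) or np.any(x <= 0):
        raise InvalidInputError("Freundlich fitting requires c_eq > 0 and x_m > 0")
    k0, n0, logcov = _loglog_start(c, x)

    def model(cc: np.ndarray, k: float, n: float) -> np.ndarray:
        return k * np.power(cc, n)

    if method == "loglog":
        k_hat, n_hat = k0, n0
        # delta method: Var(K) = K^2 * Var(ln K)
        k_se = k_hat * math.sqrt(max(logcov[1, 1], 0.0))
        n_se = math.sqrt(max(logcov[0, 0], 0.0))
        basis = "loglog-linearized"
    elif method == "nls":
        try:
            popt, pcov = optimize.curve_fit(
                model,
                c,
                x,
                p0=[k0, max(n0, 1e-3)],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            resid = x - model(c, k0, max(n0, 1e-3))
            raise FitFailureError(
                f"Freundlich fit did not converge: {exc}",
                residual_norm=float(np.linalg.norm(resid)),
            ) from exc
        k_hat, n_hat = float(popt[0]), float(popt[1])
        k_se = float(math.sqrt(max(pcov[0, 0], 0.0)))
        n_se = float(math.sqrt(max(pcov[1, 1], 0.0)))
        basis = "nls"
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    resid = x - model(c, k_hat, n_hat)
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return IsothermFit(
        model="freundlich",
        k_y=k_hat,
        n=n_hat,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        k_y_se=k_se,
        n_se=n_se,
        meta={"estimator": basis, "start": (k0, n0)},
    )


def percent_adsorption(added_mass: float, adsorbed_mass: float) -> float:
    """Percentage of the added pesticide mass that is adsorbed."""
    if added_mass <= 0:
        raise InvalidInputError("added_mass must be > 0")
    if not 0 <= adsorbed_mass <= added_mass:
        raise InvalidInputError("require 0 <= adsorbed_mass <= added_mass")
    return adsorbed_mass / added_mass * 100.0


def percent_desorption(pct_ads: float, pct_ads_24: float) -> float:
    """Desorption percentage: ``%des = %ads - %ads24``.

    A negative difference (measurement noise) is clamped to 0 with a
    logged warning.
    """
    for name, v in (("pct_ads", pct_ads), ("pct_ads_24", pct_ads_24)):
        if not 0 <= v <= 100:
            raise InvalidInputError(f"{name} must be in [0, 100], got {v}")
    des = pct_ads - pct_ads_24
    if des < 0:
        logger.warning(
            "negative %%des (%.4g) clamped to 0; %%ads24 exceeded %%ads", des
        )
        return 0.0
    return des


def hysteresis_index(k_d24: float, k_d: float) -> float:
    """Apparent desorption hysteresis index ``HI = K_d24 / K_d - 1``.

    Positive values mean the solute is released less readily than it was
    adsorbed.
    """
    if k_d <= 0:
        raise InvalidInputError("k_d must be > 0")
    if k_d24 < 0:
        raise InvalidInputError("k_d24 must be >= 0")
    return k_d24 / k_d - 1.0


def oc_normalize(k: float, oc_percent: float) -> float:
    """Organic-carbon normalised coefficient ``K / %OC * 100``."""
    if oc_percent <= 0:
        raise InvalidInputError("oc_percent must be > 0")
    return k / oc_percent * 100.0


def protonated_fraction(
    ph: float, pka: float, kind: Literal["weak-base", "weak-acid"] = "weak-base"
) -> float:
    """Ionisation state of a weak base or acid at a given pH.

    For a weak base, returns the protonated (cationic) fraction
    ``1 / (1 + 10**(ph - pka))``; for a weak acid, the complementary
    dissociated share ``1 - 1/(1 + 10**(ph - pka))``.
    """
    if not (math.isfinite(ph) and math.isfinite(pka)):
        raise InvalidInputError("ph and pka must be finite")
    base_frac = 1.0 / (1.0 + 10.0 ** (ph - pka))
    if kind == "weak-base":
        return base_frac
    if kind == "weak-acid":
        return 1.0 - base_frac
    raise InvalidInputError(f"unknown kind {kind!r}")


def retention_summary(
    pct_ads: float,
    pct_ads_24: float,
    k_d: float,
    k_d24: float,
    oc_percent: float | None = None,
    k_fa: float | None = None,
) -> RetentionSummary:
    """Assemble the derived retention indices for one soil layer."""
    return RetentionSummary(
        pct_ads=pct_ads,
        pct_ads_24=pct_ads_24,
        pct_des=percent_desorption(pct_ads, pct_ads_24),
        hi=hysteresis_index(k_d24, k_d),
        k_oc=oc_normalize(k_d, oc_percent) if oc_percent is not None else None,
        k_foc=(
            oc_normalize(k_fa, oc_percent)
            if (oc_percent is not None and k_fa is not None)
            else None
        ),
    )
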