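"""Synthetic data generators for every estimation and calibration step.

Batch sorption assays, incubation series and field campaigns are produced
as exact forward models of the package's own equations plus configurable
noise, so parameter-recovery behaviour can be studied without any
laboratory data.  Concentration noise defaults to multiplicative lognormal
(concentrations are strictly positive); identical seeds reproduce
identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from ._errors import GenerationError, InvalidInputError
from .calibration import ObservationRecord, ObservationSet
from .degradation import IncubationSeries
from .simulator import ApplicationEvent, PesticideParams, SoilLayer, simulate
from .sorption import SorptionObservation

__all__ = [
    "NoiseSpec",
    "DEFAULT_INCUBATION_DAYS",
    "gen_sorption_assay",
    "gen_incubation",
    "gen_field_campaign",
]

# standard incubation sampling design (days since spiking)
DEFAULT_INCUBATION_DAYS = (0, 1, 3, 7, 14, 31, 45, 60, 76, 102)


@dataclass(frozen=True)
class NoiseSpec:
    """Reproducible measurement noise.

    ``kind="lognormal"`` multiplies by ``exp(N(0, level))`` (``level`` is
    the approximate relative sd); ``kind="normal"`` adds ``N(0, level)``
    (``level`` is an absolute sd).  ``level=0`` is an exact forward model.
    """

    kind: Literal["lognormal", "normal"] = "lognormal"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise InvalidInputError("noise level must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.level == 0:
            return values.copy()
        if self.kind == "lognormal":
            return values * np.exp(rng.normal(0.0, self.level, size=values.shape))
        if self.kind == "normal":
            return values + rng.normal(0.0, self.level, size=values.shape)
        raise InvalidInputError(f"unknown noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _equilibrium_concentration(
    c_init: float, k_y: float, n: float, ratio: float
) -> float:
    """Solve ``c_eq + k_y * c_eq**n * ratio = c_init`` for c_eq in (0, c_init].

    ``ratio`` is soil_mass / volume (kg/L).  The left side is strictly
    increasing in c_eq, so bisection on (0, c_init] is safe whenever the
    balance has a root there.
    """
    if k_y == 0:
        return c_init

    def balance(c: float) -> float:
        return c + k_y * c**n * ratio - c_init

    lo = c_init * 1e-15
    if balance(lo) > 0 or balance(c_init) < 0:
        raise GenerationError(
            f"no equilibrium concentration in (0, {c_init}] for k_y={k_y}, n={n}"
        )
    return float(optimize.brentq(balance, lo, c_init, xtol=1e-14, rtol=1e-15))


def gen_sorption_assay(
    k_y: float,
    n: float,
    c_init_levels: Sequence[float],
    volume: float = 0.020,
    soil_mass: float = 0.010,
    noise: NoiseSpec = NoiseSpec(),
    carryover_volume: float = 0.0,
) -> list[SorptionObservation]:
    """Generate a batch-equilibrium adsorption assay from a known isotherm.

    For each initial concentration the implicit mass balance
    ``c_eq + (k_y * c_eq**n) * m/V = c_init`` is solved by bisection;
    noise is then applied to ``c_eq`` (clipped into ``(0, c_init]`` so the
    observation invariants hold).  Defaults mirror the standard design of
    10 g dry soil shaken with a 20 mL aliquot.
    """
    if k_y < 0 or n <= 0:
        raise InvalidInputError("require k_y >= 0 and n > 0")
    if volume <= 0 or soil_mass <= 0:
        raise InvalidInputError("volume and soil_mass must be > 0")
    if len(c_init_levels) < 1:
        raise InvalidInputError("need at least one initial concentration level")
    rng = noise.rng()
    ratio = soil_mass / volume
    obs = []
    for c_init in c_init_levels:
        if c_init <= 0:
            raise InvalidInputError("initial concentrations must be > 0")
        c_eq = _equilibrium_concentration(c_init, k_y, n, ratio)
        c_eq = float(noise.apply(np.array([c_eq]), rng)[0])
        c_eq = min(max(c_eq, c_init * 1e-12), c_init)
        obs.append(
            SorptionObservation(
                c_init=c_init,
                c_eq=c_eq,
                volume=volume,
                soil_mass=soil_mass,
                carryover_volume=carryover_volume,
            )
        )
    return obs


def gen_incubation(
    k: float,
    c0: float,
    times: Sequence[float] = DEFAULT_INCUBATION_DAYS,
    noise: NoiseSpec = NoiseSpec(),
    layer_id: str = "",
) -> IncubationSeries:
    """Generate a first-order incubation series ``c0 * exp(-k t)`` + noise."""
    if k < 0 or c0 <= 0:
        raise InvalidInputError("require k >= 0 and c0 > 0")
    t = np.asarray(times, dtype=float)
    conc = c0 * np.exp(-k * t)
    conc = np.clip(noise.apply(conc, noise.rng()), 0.0, None)
    return IncubationSeries(times=t, concentrations=conc, layer_id=layer_id)


def gen_field_campaign(
    profile: Sequence[SoilLayer],
    pesticide: PesticideParams,
    schedule: Sequence[ApplicationEvent],
    sampling_days: Sequence[int],
    noise: NoiseSpec = NoiseSpec(),
    loq: float = 0.0,
    flux_mode: str = "time-varying",
) -> ObservationSet:
    """Simulate a field campaign and sample noisy total concentrations.

    Runs the simulator, reads the total soil concentration of every layer
    on each sampling day, applies noise and flags values below ``loq`` as
    censored.
    """
    horizon = max(sampling_days)
    result = simulate(profile, pesticide, schedule, horizon, flux_mode)
    rng = noise.rng()
    records = []
    for day in sampling_days:
        for layer in profile:
            true_total = result.total_at(layer.layer_id, day)
            observed = float(
                np.clip(noise.apply(np.array([true_total]), rng)[0], 0.0, None)
            )
            records.append(
                ObservationRecord(
                    layer_id=layer.layer_id,
                    day=int(day),
                    total=observed,
                    below_loq=observed < loq,
                )
            )
    return ObservationSet(records, loq=loq)
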