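"""MSE objective and exhaustive grid calibration of the leaching simulator.

The objective is the mean squared difference between simulated and observed
total soil concentrations over matched (layer, day) pairs; observations
below the limit of quantification are excluded (and counted).  Calibration
is an exhaustive, deterministic grid sweep — auditable and reproducible,
matching how the candidate parameter values (penetration depths, deposited
fraction, per-layer degradation rates) are explored in practice.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InvalidInputError
from .simulator import (
    ApplicationEvent,
    PesticideParams,
    SimulationResult,
    SoilLayer,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationRecord",
    "ObservationSet",
    "CalibrationSpec",
    "CalibrationResult",
    "mean_square_error",
    "calibrate_grid",
]


@dataclass(frozen=True)
class ObservationRecord:
    """One field measurement of total soil concentration (mg/kg)."""

    layer_id: str
    day: int
    total: float
    sd: float = 0.0
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.total < 0:
            raise InvalidInputError("observed concentration must be >= 0")
        if self.day < 0:
            raise InvalidInputError("observation day must be >= 0")


@dataclass(frozen=True)
class ObservationSet:
    """A field campaign: records plus the limit of quantification (mg/kg)."""

    records: tuple[ObservationRecord, ...]
    loq: float = 0.0

    def __init__(self, records: Sequence[ObservationRecord], loq: float = 0.0):
        object.__setattr__(self, "records", tuple(records))
        object.__setattr__(self, "loq", float(loq))

    def usable(self) -> list[ObservationRecord]:
        """Records above the LOQ and not flagged as censored."""
        return [r for r in self.records if not r.below_loq and r.total >= self.loq]

    def n_censored(self) -> int:
        return len(self.records) - len(self.usable())


def _sim_total(simulated, layer_id: str, day: int) -> float | None:
    if isinstance(simulated, SimulationResult):
        key = (layer_id, day)
        return simulated.total_at(layer_id, day) if key in simulated.trajectory else None
    return simulated.get((layer_id, day))


def mean_square_error(
    simulated: SimulationResult | Mapping[tuple[str, int], float],
    observed: ObservationSet,
    layer_id: str | None = None,
) -> float:
    """Mean squared simulated-observed difference (mg^2/kg^2).

    ``simulated`` is a :class:`SimulationResult` or a mapping
    ``(layer_id, day) -> total mg/kg``.  Observations are matched to
    same-day simulator output with no interpolation; below-LOQ records are
    excluded.  ``layer_id=None`` pools all layers.

    Raises
    ------
    InvalidInputError
        If no (layer, day) pair matches.
    """
    sq = []
    n_unmatched = 0
    for rec in observed.usable():
        if layer_id is not None and rec.layer_id != layer_id:
            continue
        sim = _sim_total(simulated, rec.layer_id, rec.day)
        if sim is None:
            n_unmatched += 1
            continue
        sq.append((sim - rec.total) ** 2)
    if not sq:
        raise InvalidInputError(
            f"no matched (layer, day) pairs for layer_id={layer_id!r} "
            f"({observed.n_censored()} censored, {n_unmatched} unmatched)"
        )
    if n_unmatched:
        logger.info("%d observation(s) had no simulated counterpart", n_unmatched)
    return float(np.mean(sq))


_PESTICIDE_PARAMS = {"p_dp_soil", "p_dp_foliar", "f_soil"}


@dataclass(frozen=True)
class CalibrationSpec:
    """A calibration problem: the parameter grid plus every fixed simulator
    input.

    Grid axis names are ``p_dp_soil``, ``p_dp_foliar``, ``f_soil`` or
    ``k:<layer_id>`` (per-layer degradation rate).  Candidate values are
    evaluated exhaustively in the order given, axis by axis.
    """

    grid: dict[str, tuple[float, ...]]
    profile: tuple[SoilLayer, ...]
    pesticide: PesticideParams
    schedule: tuple[ApplicationEvent, ...]
    horizon: int
    flux_mode: str = "time-varying"

    def __init__(
        self,
        grid: Mapping[str, Sequence[float]],
        profile: Sequence[SoilLayer],
        pesticide: PesticideParams,
        schedule: Sequence[ApplicationEvent],
        horizon: int,
        flux_mode: str = "time-varying",
    ):
        layer_ids = {L.layer_id for L in profile}
        clean: dict[str, tuple[float, ...]] = {}
        for name, values in grid.items():
            values = tuple(values)
            if not values:
                raise InvalidInputError(f"grid axis {name!r} is empty")
            if name not in _PESTICIDE_PARAMS:
                if not name.startswith("k:") or name[2:] not in layer_ids:
                    raise InvalidInputError(
                        f"unknown grid parameter {name!r}; expected one of "
                        f"{sorted(_PESTICIDE_PARAMS)} or 'k:<layer_id>'"
                    )
            clean[name] = values
        object.__setattr__(self, "grid", clean)
        object.__setattr__(self, "profile", tuple(profile))
        object.__setattr__(self, "pesticide", pesticide)
        object.__setattr__(self, "schedule", tuple(schedule))
        object.__setattr__(self, "horizon", int(horizon))
        object.__setattr__(self, "flux_mode", flux_mode)

    def apply(self, params: Mapping[str, float]) -> tuple[
        tuple[SoilLayer, ...], PesticideParams
    ]:
        """Return (profile, pesticide) with the grid point substituted in."""
        pesticide = self.pesticide
        pest_updates = {k: v for k, v in params.items() if k in _PESTICIDE_PARAMS}
        if pest_updates:
            pesticide = replace(pesticide, **pest_updates)
        profile = list(self.profile)
        for name, value in params.items():
            if name.startswith("k:"):
                lid = name[2:]
                profile = [
                    replace(L, k=value) if L.layer_id == lid else L for L in profile
                ]
        return tuple(profile), pesticide


@dataclass
class CalibrationResult:
    """Argmin of the grid sweep plus the full MSE surface."""

    best_params: dict[str, float]
    best_mse: float
    table: pd.DataFrame
    result: SimulationResult | None = None


def calibrate_grid(
    spec: CalibrationSpec, observed: ObservationSet
) -> CalibrationResult:
    """Exhaustive grid search minimising the pooled MSE.

    Ties break deterministically to the first grid point in the order the
    axes and candidate values were given.  A simulator failure at a grid
    point is recorded (``mse = NaN``, ``error`` column) and skipped, not
    fatal.
    """
    names = list(spec.grid)
    rows = []
    best: tuple[float, dict[str, float], SimulationResult] | None = None
    for combo in itertools.product(*(spec.grid[n] for n in names)):
        params = dict(zip(names, combo))
        row: dict[str, object] = dict(params)
        try:
            profile, pesticide = spec.apply(params)
            sim = simulate(
                profile, pesticide, spec.schedule, spec.horizon, spec.flux_mode
            )
            mse = mean_square_error(sim, observed)
            row["mse"] = mse
            if best is None or mse < best[0]:
                best = (mse, params, sim)
        except Exception as exc:  # flagged, not fatal
            logger.warning("grid point %s failed: %s", params, exc)
            row["mse"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if best is None:
        raise InvalidInputError("every grid point failed; see the table for errors")
    return CalibrationResult(
        best_params=best[1], best_mse=best[0], table=table, result=best[2]
    )
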