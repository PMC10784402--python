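"""Scenario configuration and validated CSV readers/writers.

One tidy-CSV dialect is used throughout: UTF-8, header row, period decimal
separator, units encoded in column names.  Scenario files are YAML and are
validated exhaustively — every violation is reported, not just the first.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ._errors import InvalidInputError, ScenarioValidationError
from .calibration import ObservationRecord, ObservationSet
from .degradation import IncubationSeries
from .simulator import (
    ApplicationEvent,
    PesticideParams,
    SimulationResult,
    SoilLayer,
)
from .sorption import SorptionObservation

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "read_assay_csv",
    "read_incubation_csv",
    "read_schedule_csv",
    "read_observations_csv",
    "write_simulation_csv",
    "write_json_report",
]

_LAYER_FIELDS = ("layer_id", "top_depth", "bottom_depth", "rho_b", "f_ads", "f_des", "k")


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully validated simulation scenario."""

    profile: tuple[SoilLayer, ...]
    pesticide: PesticideParams
    schedule: tuple[ApplicationEvent, ...]
    horizon: int
    flux_mode: str = "time-varying"
    output: str | None = None


def _check_range(errors: list[str], name: str, value, lo=None, hi=None) -> bool:
    try:
        v = float(value)
    except (TypeError, ValueError):
        errors.append(f"{name}: expected a number, got {value!r}")
        return False
    if lo is not None and v < lo:
        errors.append(f"{name}: must be >= {lo}, got {v}")
        return False
    if hi is not None and v > hi:
        errors.append(f"{name}: must be <= {hi}, got {v}")
        return False
    return True


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario.

    The schedule may be inline (a list of ``{day, route, dose_mg_ha}``
    mappings) or a path to a schedule CSV, resolved relative to the
    scenario file.  Raises :class:`ScenarioValidationError` listing *all*
    violations.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScenarioValidationError(["scenario file must contain a mapping"])
    errors: list[str] = []

    pest_raw = raw.get("pesticide")
    if not isinstance(pest_raw, dict):
        errors.append("pesticide: section missing or not a mapping")
        pest_raw = {}
    _check_range(errors, "pesticide.f_soil", pest_raw.get("f_soil", 0.0), 0.0, 1.0)
    _check_range(errors, "pesticide.p_dp_soil", pest_raw.get("p_dp_soil"), 1e-12)
    _check_range(errors, "pesticide.p_dp_foliar", pest_raw.get("p_dp_foliar"), 1e-12)

    layers_raw = raw.get("profile")
    if not isinstance(layers_raw, list) or len(layers_raw) < 1:
        errors.append("profile: must be a list of at least one layer")
        layers_raw = []
    prev_arrival = None
    for i, lay in enumerate(layers_raw):
        tag = f"profile[{i}]"
        if not isinstance(lay, dict):
            errors.append(f"{tag}: must be a mapping")
            continue
        for f in _LAYER_FIELDS:
            if f not in lay:
                errors.append(f"{tag}.{f}: missing")
        _check_range(errors, f"{tag}.rho_b", lay.get("rho_b", 1.0), 1e-12)
        _check_range(errors, f"{tag}.f_ads", lay.get("f_ads", 0.0), 0.0, 1.0)
        _check_range(errors, f"{tag}.f_des", lay.get("f_des", 0.0), 0.0, 1.0)
        _check_range(errors, f"{tag}.k", lay.get("k", 0.0), 0.0)
        arrival = lay.get("tracer_arrival_day")
        if arrival is not None:
            if _check_range(errors, f"{tag}.tracer_arrival_day", arrival, 0):
                if prev_arrival is not None and float(arrival) <= prev_arrival:
                    errors.append(
                        f"{tag}.tracer_arrival_day: must strictly increase with depth "
                        f"({arrival} <= {prev_arrival})"
                    )
                prev_arrival = float(arrival)

    if _check_range(errors, "horizon", raw.get("horizon"), 1):
        horizon = int(raw["horizon"])
    else:
        horizon = 1
    flux_mode = raw.get("flux_mode", "time-varying")
    if flux_mode not in ("time-varying", "constant"):
        errors.append(f"flux_mode: must be 'time-varying' or 'constant', got {flux_mode!r}")

    schedule_raw = raw.get("schedule", [])
    schedule: list[ApplicationEvent] = []
    if isinstance(schedule_raw, str):
        sched_path = (path.parent / schedule_raw).resolve()
        if not sched_path.exists():
            errors.append(f"schedule: file not found: {schedule_raw}")
        else:
            try:
                schedule = list(read_schedule_csv(sched_path))
            except InvalidInputError as exc:
                errors.append(f"schedule: {exc}")
    elif isinstance(schedule_raw, list):
        for i, ev in enumerate(schedule_raw):
            tag = f"schedule[{i}]"
            if not isinstance(ev, dict):
                errors.append(f"{tag}: must be a mapping")
                continue
            route = ev.get("route")
            if route not in ("soil", "foliar"):
                errors.append(f"{tag}.route: must be 'soil' or 'foliar', got {route!r}")
            ok = _check_range(errors, f"{tag}.day", ev.get("day"), 0)
            ok &= _check_range(errors, f"{tag}.dose_mg_ha", ev.get("dose_mg_ha"), 0.0)
            if ok and route in ("soil", "foliar"):
                schedule.append(
                    ApplicationEvent(
                        day=int(ev["day"]), route=route, dose=float(ev["dose_mg_ha"])
                    )
                )
    else:
        errors.append("schedule: must be a list or a CSV path")

    if errors:
        raise ScenarioValidationError(errors)

    profile = tuple(
        SoilLayer(
            layer_id=str(lay["layer_id"]),
            top_depth=float(lay["top_depth"]),
            bottom_depth=float(lay["bottom_depth"]),
            rho_b=float(lay["rho_b"]),
            f_ads=float(lay["f_ads"]),
            f_des=float(lay["f_des"]),
            k=float(lay["k"]),
            tracer_arrival_day=(
                int(lay["tracer_arrival_day"])
                if lay.get("tracer_arrival_day") is not None
                else None
            ),
        )
        for lay in layers_raw
    )
    pesticide = PesticideParams(
        name=str(pest_raw.get("name", "pesticide")),
        f_soil=float(pest_raw.get("f_soil", 0.0)),
        p_dp_soil=float(pest_raw["p_dp_soil"]),
        p_dp_foliar=float(pest_raw["p_dp_foliar"]),
        pka=float(pest_raw["pka"]) if pest_raw.get("pka") is not None else None,
    )
    config = ScenarioConfig(
        profile=profile,
        pesticide=pesticide,
        schedule=tuple(schedule),
        horizon=horizon,
        flux_mode=flux_mode,
        output=raw.get("output"),
    )
    logger.info("loaded scenario: %s", config)
    return config


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")
    return df


def _row_errors(df: pd.DataFrame, checks: dict[str, tuple]) -> list[str]:
    """Per-row validity messages; row numbers refer to the data rows
    (header excluded, 1-based)."""
    errors = []
    for col, (lo, hi) in checks.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        for idx in df.index[bad]:
            errors.append(f"row {idx + 1}: invalid {col}={df.loc[idx, col]!r}")
    return errors


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    """Read a batch-assay table (one row per tube).

    Columns: ``c_init_mg_L, c_eq_mg_L, volume_L, soil_mass_kg,
    carryover_volume_L, phase (ads|des24), replicate``.  Returns the frame
    with an added ``observation`` column of :class:`SorptionObservation`
    for ``ads`` rows.
    """
    df = _read_csv(
        path,
        ["c_init_mg_L", "c_eq_mg_L", "volume_L", "soil_mass_kg", "phase"],
    )
    if "carryover_volume_L" not in df.columns:
        df["carryover_volume_L"] = 0.0
    errors = _row_errors(
        df,
        {
            "c_init_mg_L": (0.0, None),
            "c_eq_mg_L": (0.0, None),
            "volume_L": (1e-12, None),
            "soil_mass_kg": (1e-12, None),
            "carryover_volume_L": (0.0, None),
        },
    )
    bad_phase = ~df["phase"].isin(["ads", "des24"])
    errors += [f"row {i + 1}: invalid phase={df.loc[i, 'phase']!r}" for i in df.index[bad_phase]]
    if errors:
        raise InvalidInputError(f"{path}: " + "; ".join(errors))
    obs = []
    for _, row in df.iterrows():
        if row["phase"] == "ads":
            obs.append(
                SorptionObservation(
                    c_init=row["c_init_mg_L"],
                    c_eq=row["c_eq_mg_L"],
                    volume=row["volume_L"],
                    soil_mass=row["soil_mass_kg"],
                    carryover_volume=row["carryover_volume_L"],
                )
            )
        else:
            obs.append(None)
    df = df.copy()
    df["observation"] = obs
    return df


def read_incubation_csv(path: str | Path) -> dict[str, IncubationSeries]:
    """Read an incubation table (``layer_id, day, concentration_mg_kg``,
    optional ``replicate``) into one series per layer; replicates on the
    same day are averaged."""
    df = _read_csv(path, ["layer_id", "day", "concentration_mg_kg"])
    errors = _row_errors(
        df, {"day": (0.0, None), "concentration_mg_kg": (0.0, None)}
    )
    if errors:
        raise InvalidInputError(f"{path}: " + "; ".join(errors))
    out = {}
    for layer_id, grp in df.groupby("layer_id", sort=False):
        mean = grp.groupby("day")["concentration_mg_kg"].mean().sort_index()
        out[str(layer_id)] = IncubationSeries(
            times=mean.index.to_numpy(float),
            concentrations=mean.to_numpy(float),
            layer_id=str(layer_id),
        )
    return out


def read_schedule_csv(path: str | Path) -> list[ApplicationEvent]:
    """Read an application schedule (``day, route, dose_mg_ha``)."""
    df = _read_csv(path, ["day", "route", "dose_mg_ha"])
    errors = _row_errors(df, {"day": (0.0, None), "dose_mg_ha": (0.0, None)})
    bad_route = ~df["route"].isin(["soil", "foliar"])
    errors += [f"row {i + 1}: invalid route={df.loc[i, 'route']!r}" for i in df.index[bad_route]]
    if errors:
        raise InvalidInputError(f"{path}: " + "; ".join(errors))
    return [
        ApplicationEvent(day=int(r["day"]), route=r["route"], dose=float(r["dose_mg_ha"]))
        for _, r in df.iterrows()
    ]


def read_observations_csv(path: str | Path, loq: float = 0.0) -> ObservationSet:
    """Read a field-observation table (``layer_id, day, total_mg_kg``,
    optional ``sd_mg_kg``)."""
    df = _read_csv(path, ["layer_id", "day", "total_mg_kg"])
    if "sd_mg_kg" not in df.columns:
        df["sd_mg_kg"] = 0.0
    errors = _row_errors(df, {"day": (0.0, None), "total_mg_kg": (0.0, None)})
    if errors:
        raise InvalidInputError(f"{path}: " + "; ".join(errors))
    records = [
        ObservationRecord(
            layer_id=str(r["layer_id"]),
            day=int(r["day"]),
            total=float(r["total_mg_kg"]),
            sd=float(r["sd_mg_kg"]),
        )
        for _, r in df.iterrows()
    ]
    return ObservationSet(records, loq=loq)


def write_simulation_csv(result: SimulationResult, path: str | Path) -> None:
    """Write the tidy trajectory (``layer_id, day, c_solid_mg_kg,
    c_aqueous_mg_L, total_mg_kg``)."""
    result.to_frame().to_csv(path, index=False)


def write_json_report(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    try:
        return asdict(obj)
    except TypeError:
        return str(obj)
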