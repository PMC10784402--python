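"""Daily compartment model of pesticide leaching through a layered soil.

The vadose zone (0-100 cm in the reference setting) is split into stacked
layers, each described by its bulk density, an adsorption fraction, a
desorption fraction, a first-order degradation rate, and the day a
conservative tracer (bromide, retardation factor 1) reaches the layer's
bottom boundary.  Water flow is steady-state, so the tracer arrival days
are fixed inputs rather than outputs of a flow model.

Each day, in every layer:

1. the solid-phase pool decays first-order and releases a fixed fraction
   of the decayed pool to solution (desorption);
2. the aqueous pool decays at the same rate;
3. desorbed mass stays in the layer's own solution until the tracer has
   reached the layer's bottom boundary, after which it is routed as the
   daily aqueous input of the layer below (and partitioned there between
   solid and solution by that layer's adsorption fraction);
4. applications (topsoil only) are mixed instantaneously over a
   penetration depth and partitioned by the topsoil adsorption fraction.

All updates are linear in concentration, so the model is linear in dose
and fully deterministic.
"""
from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SoilLayer",
    "PesticideParams",
    "ApplicationEvent",
    "LayerState",
    "SimulationResult",
    "initial_topsoil_concentration",
    "partition_topsoil",
    "partition_subsurface",
    "step_solid",
    "step_topsoil_water",
    "step_subsurface_water",
    "route_desorbed",
    "simulate",
]

FluxMode = Literal["time-varying", "constant"]


@dataclass(frozen=True)
class SoilLayer:
    """Physical and chemical parameters of one soil layer.

    ``f_ads`` / ``f_des`` are the adsorption and desorption percentage
    fractions (0-1) measured in batch assays; ``k`` the first-order
    degradation rate (1/d); ``tracer_arrival_day`` the day a conservative
    tracer reaches this layer's *bottom* boundary (None for the deepest
    layer when drainage is not tracked).
    """

    layer_id: str
    top_depth: float
    bottom_depth: float
    rho_b: float
    f_ads: float
    f_des: float
    k: float
    tracer_arrival_day: int | None = None

    def __post_init__(self) -> None:
        if self.rho_b <= 0:
            raise InvalidInputError(f"{self.layer_id}: rho_b must be > 0")
        if not 0 <= self.f_ads <= 1:
            raise InvalidInputError(f"{self.layer_id}: f_ads must be in [0, 1]")
        if not 0 <= self.f_des <= 1:
            raise InvalidInputError(f"{self.layer_id}: f_des must be in [0, 1]")
        if self.k < 0:
            raise InvalidInputError(f"{self.layer_id}: k must be >= 0")
        if self.bottom_depth <= self.top_depth:
            raise InvalidInputError(f"{self.layer_id}: bottom_depth must exceed top_depth")


@dataclass(frozen=True)
class PesticideParams:
    """Application-side parameters of a compound.

    ``f_soil`` is the fraction of a foliar spray deposited on the topsoil;
    ``p_dp_soil`` / ``p_dp_foliar`` are the depths (m) over which a soil or
    foliar application is instantaneously mixed when computing the initial
    concentration; ``pka`` is optional and only used for speciation.
    """

    name: str
    f_soil: float
    p_dp_soil: float
    p_dp_foliar: float
    pka: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.f_soil <= 1:
            raise InvalidInputError("f_soil must be in [0, 1]")
        if self.p_dp_soil <= 0 or self.p_dp_foliar <= 0:
            raise InvalidInputError("penetration depths must be > 0")


@dataclass(frozen=True)
class ApplicationEvent:
    """A dated dose: ``day`` (simulation day), ``route`` (soil or foliar)
    and ``dose`` in mg a.i./ha."""

    day: int
    route: Literal["soil", "foliar"]
    dose: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InvalidInputError("application day must be >= 0")
        if self.dose < 0:
            raise InvalidInputError("dose must be >= 0")
        if self.route not in ("soil", "foliar"):
            raise InvalidInputError(f"route must be 'soil' or 'foliar', got {self.route!r}")


@dataclass(frozen=True)
class LayerState:
    """One layer's state on one day: solid-phase concentration (mg/kg dry
    soil), aqueous concentration (mg/L) and the desorbed flux released from
    the solid that day (mg/L solution-equivalent)."""

    day: int
    c_solid: float
    c_aqueous: float
    desorbed_flux: float = 0.0


def initial_topsoil_concentration(
    dose: float, f_soil: float, p_dp: float, rho_b: float
) -> float:
    """Initial whole-soil concentration (mg/kg) of an application.

    ``dose`` (mg/ha) times the deposited fraction, spread over the
    penetration depth: ``dose * f_soil * 1e-4 / (p_dp * rho_b * 1000)``
    (1e-4 ha/m2; 1000 L/m3).
    """
    if p_dp <= 0 or rho_b <= 0:
        raise InvalidInputError("p_dp and rho_b must be > 0")
    if dose < 0:
        raise InvalidInputError("dose must be >= 0")
    return dose * f_soil * 1e-4 / (p_dp * rho_b * 1000.0)


def partition_topsoil(c0: float, f_ads: float, rho_b: float) -> tuple[float, float]:
    """Split a whole-soil concentration (mg/kg) between phases.

    Returns ``(c_solid, c_aqueous)`` = ``(c0 * f_ads, c0 * (1 - f_ads) * rho_b)``
    in mg/kg and mg/L.
    """
    if c0 < 0:
        raise InvalidInputError("c0 must be >= 0")
    return c0 * f_ads, c0 * (1.0 - f_ads) * rho_b


def partition_subsurface(c0_sub: float, f_ads: float, rho_b: float) -> tuple[float, float]:
    """Split an incoming aqueous concentration (mg/L) between phases.

    Returns ``(c_solid, c_aqueous)`` =
    ``(c0_sub * f_ads / rho_b, c0_sub * (1 - f_ads))`` in mg/kg and mg/L.
    """
    if c0_sub < 0:
        raise InvalidInputError("c0_sub must be >= 0")
    return c0_sub * f_ads / rho_b, c0_sub * (1.0 - f_ads)


def step_solid(
    c_prev: float, k: float, dt: float = 1.0, f_des: float = 0.0, c_app: float = 0.0
) -> tuple[float, float]:
    """One solid-phase step: decay, desorb, add new input.

    ``decayed = c_prev * exp(-k dt)``; ``desorbed = decayed * f_des``;
    ``c_next = decayed - desorbed + c_app``.  Returns ``(c_next, desorbed)``
    in mg/kg.
    """
    if min(c_prev, k, dt, f_des, c_app) < 0:
        raise InvalidInputError("step_solid inputs must be >= 0")
    decayed = c_prev * math.exp(-k * dt)
    desorbed = decayed * f_des
    return decayed - desorbed + c_app, desorbed


def step_topsoil_water(c0_w: float, k: float, t_since_input: float) -> float:
    """Topsoil aqueous phase: pure first-order decay of the reference
    concentration, ``c0_w * exp(-k t)``.  After a new application the
    caller resets the reference to the decayed remnant plus the new input."""
    if min(c0_w, k, t_since_input) < 0:
        raise InvalidInputError("step_topsoil_water inputs must be >= 0")
    return c0_w * math.exp(-k * t_since_input)


def step_subsurface_water(
    c_prev_w: float, k: float, daily_input: float = 0.0, desorbed_contrib: float = 0.0
) -> float:
    """Subsurface aqueous phase, one day:

    ``c_prev_w * exp(-k) + desorbed_contrib + daily_input``

    ``desorbed_contrib`` is the in-layer desorbed mass (solid desorbed *
    rho_b) while the compound still resides in the layer, and 0 once the
    tracer has carried it to the layer below.
    """
    if min(c_prev_w, k, daily_input, desorbed_contrib) < 0:
        raise InvalidInputError("step_subsurface_water inputs must be >= 0")
    return c_prev_w * math.exp(-k) + desorbed_contrib + daily_input


def _validate_profile(profile: Sequence[SoilLayer]) -> None:
    if len(profile) < 1:
        raise InvalidInputError("profile must contain at least one layer")
    arrivals = [L.tracer_arrival_day for L in profile if L.tracer_arrival_day is not None]
    if any(b.tracer_arrival_day is not None and a.tracer_arrival_day is not None
           and b.tracer_arrival_day <= a.tracer_arrival_day
           for a, b in zip(profile, profile[1:])):
        raise InvalidInputError("tracer arrival days must strictly increase with depth")
    if any(a < 0 for a in arrivals):
        raise InvalidInputError("tracer arrival days must be >= 0")


def route_desorbed(
    profile: Sequence[SoilLayer],
    fluxes: Mapping[str, Sequence[float]],
    tracer_times: Sequence[int] | None = None,
) -> dict[str, np.ndarray]:
    """Route per-layer desorbed flux series to the layer below.

    ``fluxes[layer_id][t]`` is the desorbed flux (mg/L) of that layer on
    day ``t``.  From the tracer arrival day at a layer's bottom boundary
    onward, its flux becomes the daily aqueous input of the next layer;
    before that day the flux stays in the producing layer (and is not part
    of the returned series).  Returns ``{receiving layer_id: input series}``;
    empty for a single-layer profile.
    """
    _validate_profile(profile)
    times = (
        [L.tracer_arrival_day for L in profile]
        if tracer_times is None
        else list(tracer_times)
    )
    out: dict[str, np.ndarray] = {}
    for i in range(len(profile) - 1):
        upper, lower = profile[i], profile[i + 1]
        flux = np.asarray(fluxes[upper.layer_id], dtype=float)
        arrival = times[i]
        routed = np.zeros_like(flux)
        if arrival is not None:
            start = max(int(arrival), 0)
            routed[start:] = flux[start:]
        out[lower.layer_id] = routed
    return out


@dataclass
class SimulationResult:
    """Trajectory of a simulation: ``trajectory[(layer_id, day)]`` is a
    :class:`LayerState`; ``total`` maps the same keys to the total soil
    concentration in mg/kg (``c_solid + c_aqueous / rho_b``, mass-
    consistent with the phase partitioning)."""

    profile: tuple[SoilLayer, ...]
    horizon: int
    trajectory: dict[tuple[str, int], LayerState]
    flux_mode: FluxMode = "time-varying"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rho = {L.layer_id: L.rho_b for L in self.profile}

    def total_at(self, layer_id: str, day: int, convention: str = "mass") -> float:
        """Total soil concentration for one (layer, day).

        ``convention="mass"`` (default) converts the aqueous phase to a
        dry-soil basis before summing; ``"raw_sum"`` adds the mg/kg and
        mg/L numbers without unit conversion.
        """
        st = self.trajectory[(layer_id, day)]
        if convention == "mass":
            return st.c_solid + st.c_aqueous / self._rho[layer_id]
        if convention == "raw_sum":
            return st.c_solid + st.c_aqueous
        raise InvalidInputError(f"unknown convention {convention!r}")

    @property
    def total(self) -> dict[tuple[str, int], float]:
        return {
            key: self.total_at(key[0], key[1]) for key in self.trajectory
        }

    def desorbed_series(self, layer_id: str) -> np.ndarray:
        return np.array(
            [self.trajectory[(layer_id, d)].desorbed_flux for d in range(self.horizon + 1)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trajectory."""
        rows = [
            {
                "layer_id": lid,
                "day": day,
                "c_solid_mg_kg": st.c_solid,
                "c_aqueous_mg_L": st.c_aqueous,
                "total_mg_kg": self.total_at(lid, day),
            }
            for (lid, day), st in sorted(
                self.trajectory.items(), key=lambda kv: (kv[0][1], kv[0][0])
            )
        ]
        return pd.DataFrame(rows)


def simulate(
    profile: Sequence[SoilLayer],
    pesticide: PesticideParams,
    schedule: Sequence[ApplicationEvent],
    horizon: int,
    flux_mode: FluxMode = "time-varying",
) -> SimulationResult:
    """Run the daily leaching simulation over days 0..horizon.

    Applications are delivered to the topsoil only (soil route deposits the
    full dose; foliar route deposits ``f_soil`` of it over a shallower
    penetration depth); soil-route events on a day are processed before
    foliar ones.  ``flux_mode="constant"`` freezes each layer's routed
    daily input at its value on the first delivery day, emulating the
    assumption of time-constant desorption; the default routes the actual
    daily desorbed flux.  Events dated beyond the horizon are ignored with
    a warning.
    """
    profile = tuple(profile)
    _validate_profile(profile)
    if horizon < 1:
        raise InvalidInputError("horizon must be >= 1")
    if flux_mode not in ("time-varying", "constant"):
        raise InvalidInputError(f"unknown flux_mode {flux_mode!r}")

    events_by_day: dict[int, list[ApplicationEvent]] = defaultdict(list)
    for ev in schedule:
        if ev.day > horizon:
            warnings.warn(
                f"application on day {ev.day} is beyond horizon {horizon}; ignored",
                stacklevel=2,
            )
            continue
        events_by_day[ev.day].append(ev)
    route_rank = {"soil": 0, "foliar": 1}

    nz = len(profile)
    decay = [math.exp(-L.k) for L in profile]
    c_s = [0.0] * nz
    c_w = [0.0] * nz
    frozen_input: list[float | None] = [None] * nz
    trajectory: dict[tuple[str, int], LayerState] = {}

    for day in range(horizon + 1):
        des_flux = [0.0] * nz
        if day > 0:
            routed_in = [0.0] * nz
            for i, layer in enumerate(profile):
                decayed = c_s[i] * decay[i]
                desorbed = decayed * layer.f_des
                c_s[i] = decayed - desorbed
                c_w[i] *= decay[i]
                flux = desorbed * layer.rho_b
                des_flux[i] = flux
                arrival = layer.tracer_arrival_day
                if arrival is None or day < arrival:
                    # compound still resides in this layer: desorbed mass
                    # feeds the layer's own solution
                    c_w[i] += flux
                elif i + 1 < nz:
                    routed_in[i + 1] = flux
                # else: flux crosses the profile's bottom boundary
            for i in range(1, nz):
                if flux_mode == "constant":
                    upstream = profile[i - 1].tracer_arrival_day
                    if upstream is not None and day >= upstream:
                        if frozen_input[i] is None:
                            frozen_input[i] = routed_in[i]
                        routed_in[i] = frozen_input[i]
                if routed_in[i] > 0:
                    ds, dw = partition_subsurface(
                        routed_in[i], profile[i].f_ads, profile[i].rho_b
                    )
                    c_s[i] += ds
                    c_w[i] += dw
        for ev in sorted(events_by_day.get(day, []), key=lambda e: route_rank[e.route]):
            top = profile[0]
            if ev.route == "soil":
                c0 = initial_topsoil_concentration(ev.dose, 1.0, pesticide.p_dp_soil, top.rho_b)
            else:
                c0 = initial_topsoil_concentration(
                    ev.dose, pesticide.f_soil, pesticide.p_dp_foliar, top.rho_b
                )
            ds, dw = partition_topsoil(c0, top.f_ads, top.rho_b)
            c_s[0] += ds
            c_w[0] += dw
        for i, layer in enumerate(profile):
            trajectory[(layer.layer_id, day)] = LayerState(
                day=day, c_solid=c_s[i], c_aqueous=c_w[i], desorbed_flux=des_flux[i]
            )

    return SimulationResult(
        profile=profile,
        horizon=horizon,
        trajectory=trajectory,
        flux_mode=flux_mode,
        meta={
            "pesticide": pesticide.name,
            "n_events": sum(len(v) for v in events_by_day.values()),
            "total_convention": "mass (c_solid + c_aqueous / rho_b)",
        },
    )
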