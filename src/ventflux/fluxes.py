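"""Chamber-incubation flux computation.

Whole settlement tiles are incubated in sealed 3.7 L chambers; oxygen is
logged every minute, and water samples bracketing each run give total
alkalinity and nutrient (NH4+, NO3-, PO43-) concentrations.  This module
turns one light + dark chamber pair (plus their empty-chamber controls) into
per-tile rates:

* net photosynthesis (NP) and dark respiration (R) from the O2 slope,
* gross photosynthesis GP = NP - R,
* net calcification from the alkalinity anomaly at 2:1 stoichiometry,
* nutrient uptake from start/end concentration differences,

all control-corrected and optionally standardised per gram dry weight or per
unit area.  Sign conventions: O2 consumption and net CaCO3 dissolution are
negative; nutrient removal from the water is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .carbonate import ConstantsSet

__all__ = [
    "IncubationRecord",
    "FluxResult",
    "o2_rate",
    "control_correct",
    "gross_photosynthesis",
    "calcification_from_alkalinity",
    "nutrient_uptake",
    "o2_saturation_concentration",
    "saturation_flags",
    "standardize",
    "SEAWATER_DENSITY",
    "CHAMBER_VOLUME_L",
    "DETECTION_LIMITS",
]

SEAWATER_DENSITY = 1.025  # kg L-1, fixed per the incubation protocol
CHAMBER_VOLUME_L = 3.7
TILE_AREA_CM2 = 225.0  # 15 x 15 cm, one side

#: Flow-analyser detection limits, mmol m-3.
DETECTION_LIMITS = {"nh4": 0.05, "no3": 0.01, "po4": 0.01}

MAX_LIGHT_MINUTES = 75.0
MAX_DARK_MINUTES = 60.0


class FluxError(ValueError):
    pass


@dataclass
class IncubationRecord:
    """One chamber run.

    ``o2_series`` is the per-minute O2 concentration in umol/L;
    ``o2_minutes`` the matching elapsed minutes (defaults to 0,1,2,...).
    ``mode`` is one of light/dark/control_light/control_dark; controls are
    empty chambers measuring background water metabolism.  ``at_start`` /
    ``at_end`` may hold replicate measurements (averaged before
    differencing); nutrient dicts map {"nh4","no3","po4"} to mmol m-3.
    """

    chamber_id: str
    mode: str
    o2_series: np.ndarray
    tile_id: str | None = None
    o2_minutes: np.ndarray | None = None
    volume: float = CHAMBER_VOLUME_L
    duration_h: float | None = None
    at_start: np.ndarray | float | None = None
    at_end: np.ndarray | float | None = None
    nutrient_start: dict | None = None
    nutrient_end: dict | None = None
    par_series: np.ndarray | None = None
    temperature: float | None = None
    salinity: float | None = None

    def __post_init__(self):
        valid = {"light", "dark", "control_light", "control_dark"}
        if self.mode not in valid:
            raise FluxError(f"mode {self.mode!r} not in {sorted(valid)}")
        self.o2_series = np.asarray(self.o2_series, dtype=float)
        if self.o2_minutes is None:
            self.o2_minutes = np.arange(len(self.o2_series), dtype=float)
        else:
            self.o2_minutes = np.asarray(self.o2_minutes, dtype=float)
        if len(self.o2_minutes) != len(self.o2_series):
            raise FluxError("o2_minutes and o2_series lengths differ")
        if self.volume <= 0:
            raise FluxError("chamber volume must be > 0")
        minutes = self.o2_minutes[-1] - self.o2_minutes[0] if len(self.o2_minutes) else 0.0
        limit = MAX_LIGHT_MINUTES if "light" in self.mode else MAX_DARK_MINUTES
        if minutes > limit:
            warnings.warn(
                f"{self.mode} incubation of {minutes:.0f} min exceeds the "
                f"{limit:.0f} min protocol limit",
                stacklevel=2,
            )

    @property
    def is_control(self) -> bool:
        return self.mode.startswith("control")

    @property
    def duration_hours(self) -> float:
        if self.duration_h is not None:
            return self.duration_h
        return (self.o2_minutes[-1] - self.o2_minutes[0]) / 60.0


@dataclass
class FluxResult:
    """Control-corrected per-tile rates, umol h-1 per tile."""

    tile_id: str
    np_rate: float  # net photosynthesis, umol O2 h-1
    r_rate: float  # dark respiration (negative = O2 consumption)
    gp_rate: float  # gross photosynthesis = np - r
    calcification: float | None = None  # umol CaCO3 h-1; negative = dissolution
    uptake_nh4: float | None = None
    uptake_no3: float | None = None
    uptake_po4: float | None = None
    qc_flags: list = field(default_factory=list)

    def __post_init__(self):
        if not np.isclose(self.gp_rate, self.np_rate - self.r_rate):
            raise FluxError("gp must equal np - r")


def o2_rate(record: IncubationRecord, method: str = "regression") -> float:
    """Chamber O2 rate in umol O2 h-1 from the logged concentration series.

    ``regression`` (default) takes the OLS slope of concentration vs time
    over the whole window; ``endpoints`` uses only the first and last points
    (mirrors how the start/end-sample analytes must be handled).
    """
    y = record.o2_series
    t = record.o2_minutes
    if len(y) < 10:
        raise FluxError(f"need >= 10 O2 points, got {len(y)}")
    if np.any(np.diff(t) <= 0):
        raise FluxError("o2 timestamps must be strictly increasing")
    if method == "regression":
        slope = np.polyfit(t, y, 1)[0]  # umol L-1 min-1
    elif method == "endpoints":
        slope = (y[-1] - y[0]) / (t[-1] - t[0])
    else:
        raise FluxError(f"unknown o2 rate method {method!r}")
    return slope * 60.0 * record.volume


def control_correct(rate: float, control_rate: float, mode: str = None,
                    control_mode: str = None) -> float:
    """Subtract the empty-chamber background rate from a tile rate."""
    if mode is not None and control_mode is not None:
        if mode.replace("control_", "") != control_mode.replace("control_", ""):
            raise FluxError(
                f"mode mismatch: cannot correct {mode!r} with {control_mode!r}"
            )
    return rate - control_rate


def gross_photosynthesis(np_rate: float, r_rate: float) -> float:
    """GP = NP - R; respiration is negative when O2 is consumed in the dark."""
    if r_rate > 0:
        warnings.warn(
            "net O2 production in the dark (r > 0); flagged, not forbidden",
            stacklevel=2,
        )
    return np_rate - r_rate


def calcification_from_alkalinity(
    at_start: float | np.ndarray,
    at_end: float | np.ndarray,
    duration_h: float,
    volume_l: float = CHAMBER_VOLUME_L,
    density: float = SEAWATER_DENSITY,
) -> float:
    """Net calcification from the alkalinity anomaly, umol CaCO3 h-1.

    Each mole of CaCO3 precipitated lowers A_T by two moles, so
    G = -(dA_T)/2 * rho * V / dt.  Replicate A_T measurements are averaged
    before differencing.  Positive = net precipitation; negative = net
    dissolution.
    """
    if duration_h <= 0:
        raise FluxError("duration must be > 0")
    a0 = float(np.mean(at_start))
    a1 = float(np.mean(at_end))
    return -(a1 - a0) / 2.0 * density * volume_l / duration_h


def nutrient_uptake(
    start: float,
    end: float,
    control_start: float,
    control_end: float,
    duration_h: float,
    volume_l: float = CHAMBER_VOLUME_L,
    nutrient: str | None = None,
    flags: list | None = None,
) -> float:
    """Control-corrected nutrient uptake, umol h-1 per tile (positive = removal).

    mmol m-3 is numerically umol L-1, so uptake =
    [(start-end) - (control_start-control_end)] * V / dt.  Concentrations at
    or below the analyser detection limit are floored at the limit and
    flagged ``detection_limit``.
    """
    if duration_h <= 0:
        raise FluxError("duration must be > 0")
    values = {"start": start, "end": end,
              "control_start": control_start, "control_end": control_end}
    limit = DETECTION_LIMITS.get(nutrient) if nutrient else None
    for name, v in values.items():
        if v < 0:
            raise FluxError(f"negative concentration for {name} without a flag")
        if limit is not None and v < limit:
            values[name] = limit
            if flags is not None:
                flags.append(f"detection_limit:{nutrient}:{name}")
    delta = (values["start"] - values["end"]) - (
        values["control_start"] - values["control_end"]
    )
    return delta * volume_l / duration_h


def o2_saturation_concentration(temperature: float, salinity: float) -> float:
    """Equilibrium O2 concentration (100% saturation), umol/L.

    Garcia & Gordon (1992) combined fit to the Benson & Krause data
    (umol/kg), converted to umol/L with the protocol density.
    Check value: T=10 C, S=35 -> 274.6 umol/kg.
    """
    ts = np.log((298.15 - temperature) / (273.15 + temperature))
    a = [5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369]
    b = [-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3]
    c0 = -2.75915e-7
    ln_c = (
        a[0] + a[1] * ts + a[2] * ts**2 + a[3] * ts**3 + a[4] * ts**4 + a[5] * ts**5
        + salinity * (b[0] + b[1] * ts + b[2] * ts**2 + b[3] * ts**3)
        + c0 * salinity**2
    )
    return float(np.exp(ln_c)) * SEAWATER_DENSITY


def saturation_flags(record: IncubationRecord, constants: ConstantsSet | None = None) -> list:
    """Flag O2 points violating the protocol saturation bounds.

    Light incubations must stay below 150% saturation (photosynthesis
    inhibition / pH drift); dark incubations above 80% (fauna hypoxia).
    """
    if record.temperature is None or record.salinity is None:
        raise FluxError("temperature and salinity required for saturation flags")
    c100 = o2_saturation_concentration(record.temperature, record.salinity)
    sat = record.o2_series / c100 * 100.0
    flags = []
    if "light" in record.mode and np.any(sat > 150.0):
        flags.append("oversaturated")
    if "dark" in record.mode and np.any(sat < 80.0):
        flags.append("hypoxic_risk")
    return flags


def standardize(flux: float, basis: float) -> float:
    """Express a per-tile rate per gram dry weight or per cm2 (flux / basis)."""
    if basis <= 0:
        raise FluxError("standardization basis must be > 0")
    return flux / basis


def compute_tile_fluxes(
    light: IncubationRecord,
    dark: IncubationRecord,
    control_light: IncubationRecord,
    control_dark: IncubationRecord,
    method: str = "regression",
) -> FluxResult:
    """Full chain for one tile: slopes, control correction, GP, anomaly, uptake."""
    if light.tile_id != dark.tile_id:
        raise FluxError("light and dark records belong to different tiles")
    np_rate = control_correct(
        o2_rate(light, method), o2_rate(control_light, method),
        light.mode, control_light.mode,
    )
    r_rate = control_correct(
        o2_rate(dark, method), o2_rate(control_dark, method),
        dark.mode, control_dark.mode,
    )
    flags = []
    for rec in (light, dark):
        if rec.temperature is not None and rec.salinity is not None:
            flags.extend(saturation_flags(rec))

    calc = None
    if light.at_start is not None and light.at_end is not None:
        calc = calcification_from_alkalinity(
            light.at_start, light.at_end, light.duration_hours, light.volume
        )
        if control_light.at_start is not None and control_light.at_end is not None:
            calc = control_correct(
                calc,
                calcification_from_alkalinity(
                    control_light.at_start, control_light.at_end,
                    control_light.duration_hours, control_light.volume,
                ),
            )

    uptakes = {}
    if light.nutrient_start and light.nutrient_end:
        for nut in ("nh4", "no3", "po4"):
            if nut in light.nutrient_start:
                uptakes[nut] = nutrient_uptake(
                    light.nutrient_start[nut],
                    light.nutrient_end[nut],
                    (control_light.nutrient_start or {}).get(nut, 0.0),
                    (control_light.nutrient_end or {}).get(nut, 0.0),
                    light.duration_hours,
                    light.volume,
                    nutrient=nut,
                    flags=flags,
                )

    return FluxResult(
        tile_id=light.tile_id,
        np_rate=np_rate,
        r_rate=r_rate,
        gp_rate=gross_photosynthesis(np_rate, r_rate),
        calcification=calc,
        uptake_nh4=uptakes.get("nh4"),
        uptake_no3=uptakes.get("no3"),
        uptake_po4=uptakes.get("po4"),
        qc_flags=flags,
    )
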