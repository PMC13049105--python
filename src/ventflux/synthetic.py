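"""Synthetic inputs with the statistical structure of the vent transplant study.

Generates every table the pipeline consumes — pH sensor logs, chamber
incubation records, tile cover surveys, species registry and tidy model
inputs — so each stage, and the hierarchical model's parameter recovery, is
testable without field data.

The scenario defaults encode the study conditions: three pH zones (ambient
mean pH 8.02; low 7.70 with a left-skewed venting mixture; extreme low 6.43
with a heavy left tail), three community types x six tiles per zone, time
points 0/7/30/120 days, a 61-taxon species pool (25 algae + 1 turf group +
35 invertebrates), per-zone species-loss means, and per-zone directional
trends in calcification, photosynthesis and nutrient uptake.  pH mixtures
are two-component (quiet background + venting pulses) with weights solved so
mean and quartiles hit the zone targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import SpeciesRecord, TileObservation
from .fluxes import IncubationRecord, CHAMBER_VOLUME_L, SEAWATER_DENSITY

__all__ = [
    "ZonePH",
    "Scenario",
    "default_species_registry",
    "generate_ph_series",
    "generate_incubation",
    "generate_community_trajectories",
    "generate_pi_observations",
    "generate_function_study",
]

ZONES = ("ambient", "low", "extreme_low")
COMMUNITIES = ("calcifying", "mixed", "fleshy")
TIME_POINTS = (0, 7, 30, 120)  # days

#: master seed used for documentation runs (first sensor deployment date)
DEFAULT_MASTER_SEED = 20230508


@dataclass(frozen=True)
class ZonePH:
    """Two-component pH mixture for one zone.

    With probability ``venting_weight`` a sample comes from the venting
    component, otherwise from the quiet background; parameters are solved so
    the mixture mean and 25th/75th percentiles land on the zone's observed
    targets.
    """

    mean_target: float
    q25_target: float
    q75_target: float
    background_mean: float
    background_sd: float
    venting_mean: float
    venting_sd: float
    venting_weight: float
    n_sensor_samples: int  # per-zone sample count over both deployments


#: Zone generators calibrated to the observed per-zone mean and quartiles.
ZONE_PH_DEFAULTS = {
    "ambient": ZonePH(8.02, 7.99, 8.05, 8.02, 0.0445, 8.02, 0.0445, 0.0, 6342),
    "low": ZonePH(7.70, 7.72, 8.00, 7.94, 0.125, 6.85, 0.25, 0.22, 5587),
    "extreme_low": ZonePH(6.43, 6.43, 6.68, 6.602, 0.1447, 5.455, 0.40, 0.15, 5546),
}

#: mean species lost by the final time point, per (community, zone)
SPECIES_LOSS_MEANS = {
    ("fleshy", "ambient"): 7.0, ("fleshy", "low"): 7.0, ("fleshy", "extreme_low"): 18.0,
    ("mixed", "ambient"): 4.0, ("mixed", "low"): 6.5, ("mixed", "extreme_low"): 17.0,
    ("calcifying", "ambient"): 4.0, ("calcifying", "low"): 7.0,
    ("calcifying", "extreme_low"): 14.0,
}

#: per-zone endpoint multipliers for surviving covers (relative to T0)
SURVIVOR_COVER_FACTOR = {"ambient": 1.0, "low": 0.65, "extreme_low": 0.1}

#: planted per-tile function trends: (rate at T0, rate at day 120), umol h-1.
#: All zones share the T0 baseline because every tile recolonised in the
#: ambient zone before being transplanted at T0; divergence develops after.
FUNCTION_TRENDS = {
    "calcification": {
        "ambient": (20.0, 30.0), "low": (20.0, 15.0), "extreme_low": (20.0, -15.0)
    },
    "photosynthesis": {
        "ambient": (50.0, 60.0), "low": (50.0, 100.0), "extreme_low": (50.0, 200.0)
    },
    "uptake_nh4": {
        "ambient": (0.40, 0.45), "low": (0.40, 1.20), "extreme_low": (0.40, 4.00)
    },
}


@dataclass
class Scenario:
    """Generator configuration reproducing the study's design."""

    zones: tuple = ZONES
    communities: tuple = COMMUNITIES
    tiles_per_cell: int = 6
    time_points: tuple = TIME_POINTS
    zone_ph: dict = field(default_factory=lambda: dict(ZONE_PH_DEFAULTS))
    species_loss_means: dict = field(default_factory=lambda: dict(SPECIES_LOSS_MEANS))
    function_trends: dict = field(default_factory=lambda: dict(FUNCTION_TRENDS))
    initial_richness_mean: float = 21.0
    initial_richness_sd: float = 2.0
    o2_noise: float = 0.5  # umol L-1 per-minute sensor noise
    at_noise: float = 2.0  # umol kg-1 bottle replicate noise
    nutrient_noise: float = 0.01  # mmol m-3
    tile_rate_cv: float = 0.15  # between-tile spread of planted rates
    cover_jitter: float = 0.4  # survey noise on grid counts (squares)
    temperature_mean: float = 22.4
    temperature_sd: float = 2.6
    seed: int = DEFAULT_MASTER_SEED

    @property
    def total_sensor_samples(self) -> int:
        return sum(z.n_sensor_samples for z in self.zone_ph.values())


# ---------------------------------------------------------------------------
# species registry
# ---------------------------------------------------------------------------

def default_species_registry(seed: int | None = None) -> dict:
    """61-taxon registry: 25 algae + 1 turf group + 35 invertebrates.

    Functional roles follow the field pattern: calcifying algae (articulated
    corallines and allies), fleshy algae across the three algal phyla, a
    turf group, calcifying filter-feeders (bryozoans, serpulids, molluscs,
    barnacle) and soft-bodied filter-feeders (sponges, tunicates).
    Dry-weight densities (g DW per 25 cm2 patch) are log-normal in
    [~0.05, 2]: calcifiers heavy, turf light.
    """
    rng = np.random.default_rng(DEFAULT_MASTER_SEED if seed is None else seed)
    registry = {}

    def add(sp, group, roles, lo, hi):
        dw = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        registry[sp] = SpeciesRecord(
            species_id=sp, taxon_group=group, roles=frozenset(roles),
            dry_weight_density=dw,
        )

    # 8 calcifying algae
    for i, group in enumerate(
        ["Rhodophyta"] * 5 + ["Chlorophyta"] * 2 + ["Phaeophyceae"]
    ):
        add(f"alga_calc_{i:02d}", group, {"calcifier", "primary_producer"}, 0.4, 2.0)
    # 17 fleshy algae
    for i, group in enumerate(
        ["Chlorophyta"] * 5 + ["Phaeophyceae"] * 6 + ["Rhodophyta"] * 6
    ):
        add(f"alga_fleshy_{i:02d}", group, {"primary_producer"}, 0.08, 0.6)
    # 1 turf group
    add("turf", "Turf", {"primary_producer"}, 0.05, 0.08)
    # 10 calcifying filter-feeders
    for i, group in enumerate(
        ["Bryozoa"] * 4 + ["Mollusca"] * 3 + ["Polychaeta"] * 2 + ["Crustacea"]
    ):
        add(f"invert_calc_{i:02d}", group, {"calcifier", "filter_feeder"}, 0.3, 1.5)
    # 25 soft-bodied filter-feeders
    for i, group in enumerate(
        ["Porifera"] * 10 + ["Tunicata"] * 8 + ["Cnidaria"] * 4 + ["Annelida"] * 3
    ):
        add(f"invert_soft_{i:02d}", group, {"filter_feeder"}, 0.05, 0.8)
    return registry


# ---------------------------------------------------------------------------
# pH sensor series
# ---------------------------------------------------------------------------

def generate_ph_series(
    scenario: Scenario,
    zone: str,
    n: int | None = None,
    cadence_min: int = 15,
    duration_days: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Timestamped 15-min pH/temperature log for one zone.

    Either ``n`` samples or a ``duration_days`` window (>= 100 points).
    The pH mixture hits the zone's configured mean and quartiles to ~±0.03
    at n >= 5000.
    """
    if zone not in scenario.zone_ph:
        raise ValueError(f"unknown zone {zone!r}")
    cfg = scenario.zone_ph[zone]
    if n is None:
        if duration_days is None:
            n = cfg.n_sensor_samples
        else:
            n = int(duration_days * 24 * 60 / cadence_min)
            if n < 100:
                raise ValueError("duration too short: need >= 100 points")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    venting = rng.random(n) < cfg.venting_weight
    ph = np.where(
        venting,
        rng.normal(cfg.venting_mean, cfg.venting_sd, n),
        rng.normal(cfg.background_mean, cfg.background_sd, n),
    )
    ph = np.clip(ph, 3.0, 9.5)
    temp = np.clip(
        rng.normal(scenario.temperature_mean, scenario.temperature_sd, n), 12.0, 32.0
    )
    t0 = pd.Timestamp("2023-05-08T00:00:00+01:00")
    ts = t0 + pd.to_timedelta(np.arange(n) * cadence_min, unit="m")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "zone": zone,
            "ph_total": ph,
            "temperature_c": temp,
            "depth_m": 1.0,
        }
    )


# ---------------------------------------------------------------------------
# incubations
# ---------------------------------------------------------------------------

def generate_incubation(
    true_np: float = 0.0,
    true_calcification: float = 0.0,
    true_uptake: dict | None = None,
    mode: str = "light",
    tile_id: str | None = "tile_0",
    duration_min: int = 75,
    o2_start: float = 230.0,
    at_start: float = 2662.0,
    nutrient_start: dict | None = None,
    o2_noise: float = 0.0,
    at_noise: float = 0.0,
    nutrient_noise: float = 0.0,
    volume: float = CHAMBER_VOLUME_L,
    temperature: float = 22.4,
    salinity: float = 38.0,
    seed: int | None = None,
) -> IncubationRecord:
    """One chamber run with planted rates.

    O2 follows a linear trend at slope true_np / (60 V) plus Gaussian noise;
    the end A_T / nutrient bottles are consistent with the planted
    calcification (2:1 alkalinity stoichiometry) and uptake rates.  With all
    noises at zero the flux chain recovers the planted rates exactly.
    """
    rng = np.random.default_rng(seed)
    minutes = np.arange(duration_min + 1, dtype=float)
    slope = true_np / 60.0 / volume  # umol L-1 min-1
    o2 = o2_start + slope * minutes
    if np.any(o2 <= 0):
        raise ValueError("planted rates drive O2 below zero")
    if o2_noise > 0:
        o2 = o2 + rng.normal(0.0, o2_noise, len(o2))
    dur_h = duration_min / 60.0

    d_at = -2.0 * true_calcification * dur_h / (SEAWATER_DENSITY * volume)
    a0 = at_start + (rng.normal(0, at_noise) if at_noise > 0 else 0.0)
    a1 = at_start + d_at + (rng.normal(0, at_noise) if at_noise > 0 else 0.0)

    nut0 = dict(nutrient_start or {"nh4": 2.0, "no3": 1.0, "po4": 0.2})
    nut1 = {}
    for k, v in nut0.items():
        uptake = (true_uptake or {}).get(k, 0.0)
        end = v - uptake * dur_h / volume
        if nutrient_noise > 0:
            nut0[k] = v + rng.normal(0, nutrient_noise)
            end += rng.normal(0, nutrient_noise)
        if end < 0:
            raise ValueError(f"planted uptake empties the chamber of {k}")
        nut1[k] = end

    return IncubationRecord(
        chamber_id=f"{tile_id or 'control'}_{mode}",
        tile_id=tile_id,
        mode=mode,
        o2_series=o2,
        o2_minutes=minutes,
        volume=volume,
        duration_h=dur_h,
        at_start=a0,
        at_end=a1,
        nutrient_start=nut0,
        nutrient_end=nut1,
        temperature=temperature,
        salinity=salinity,
    )


# ---------------------------------------------------------------------------
# community cover trajectories
# ---------------------------------------------------------------------------

def _t0_counts(rng, registry, community, richness):
    """Initial grid counts: the community's dominant algal guild gets the
    high covers, the rest fill in at low cover."""
    calc_algae = [s for s, r in registry.items()
                  if r.is_alga and "calcifier" in r.roles]
    fleshy_algae = [s for s, r in registry.items()
                    if r.is_alga and "calcifier" not in r.roles]
    inverts = [s for s, r in registry.items() if not r.is_alga]
    n_dom = max(4, richness // 3)
    if community == "calcifying":
        dominant, other = calc_algae, fleshy_algae
        chosen_dom = list(rng.choice(dominant, min(n_dom, len(dominant)),
                                     replace=False))
    elif community == "fleshy":
        dominant, other = fleshy_algae, calc_algae
        chosen_dom = list(rng.choice(dominant, min(n_dom, len(dominant)),
                                     replace=False))
    else:
        # balanced dominance keeps the calcifier share near 0.5
        k = n_dom // 2
        chosen_dom = list(rng.choice(calc_algae, k, replace=False)) + list(
            rng.choice(fleshy_algae, n_dom - k, replace=False)
        )
        other = [s for s in calc_algae + fleshy_algae if s not in chosen_dom]
    rest_pool = [s for s in other + inverts if s not in chosen_dom]
    n_rest = max(0, richness - n_dom)
    chosen_rest = list(rng.choice(rest_pool, min(n_rest, len(rest_pool)), replace=False))

    counts = {}
    for sp in chosen_dom:
        counts[sp] = int(rng.integers(8, 20))
    for sp in chosen_rest:
        counts[sp] = int(rng.integers(1, 6))
    return counts


def generate_community_trajectories(
    scenario: Scenario, seed: int | None = None, registry: dict | None = None
) -> list[TileObservation]:
    """TileObservations for every (zone, community, tile, side, time point).

    Species losses are realised by per-species extinction draws whose
    probability equals the configured per-(community, zone) loss mean over
    the tile's initial richness, so realised mean losses match the targets
    to within sampling error; survivors' covers shrink (or grow for
    vent-tolerant taxa) exponentially toward the zone's endpoint factor.
    Calcifiers are forced extinct under extreme low pH from day 100.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    registry = registry if registry is not None else default_species_registry()
    t_final = max(scenario.time_points)
    obs = []
    for zone in scenario.zones:
        for community in scenario.communities:
            p_loss_target = scenario.species_loss_means[(community, zone)]
            for tile_i in range(scenario.tiles_per_cell):
                tile_id = f"{zone}_{community}_{tile_i}"
                richness = int(np.clip(
                    round(rng.normal(scenario.initial_richness_mean,
                                     scenario.initial_richness_sd)), 10, 30,
                ))
                counts0 = _t0_counts(rng, registry, community, richness)
                # split species across the two tile faces
                sides = {"front": {}, "back": {}}
                for sp, n in counts0.items():
                    rec = registry[sp]
                    side = "front" if rec.is_alga or rng.random() < 0.3 else "back"
                    sides[side][sp] = n

                forced_species = {
                    sp for sp in counts0
                    if zone == "extreme_low" and "calcifier" in registry[sp].roles
                }
                n_free = max(len(counts0) - len(forced_species), 1)
                p_ext = min(0.95, max(
                    0.0, (p_loss_target - len(forced_species)) / n_free
                ))
                extinct_time = {}
                for sp in counts0:
                    forced = sp in forced_species
                    if forced or rng.random() < p_ext:
                        later = [t for t in scenario.time_points if t > 0]
                        t_ext = float(rng.choice(later))
                        if forced:
                            t_ext = min(t_ext, 100.0)
                        extinct_time[sp] = t_ext

                endpoint = SURVIVOR_COVER_FACTOR[zone]
                for t in scenario.time_points:
                    for side, counts in sides.items():
                        sq = {}
                        for sp, n0 in counts.items():
                            if sp in extinct_time and t >= extinct_time[sp]:
                                continue
                            frac = t / t_final if t_final > 0 else 0.0
                            factor = endpoint ** frac
                            rec = registry[sp]
                            if zone != "ambient" and rec.taxon_group == "Turf":
                                factor = (1.8 if zone == "low" else 1.2) ** frac
                            jitter = (
                                rng.normal(0, scenario.cover_jitter)
                                if scenario.cover_jitter > 0 else 0.0
                            )
                            n = int(np.clip(round(n0 * factor + jitter), 1, 25))
                            sq[sp] = n
                        obs.append(TileObservation(
                            tile_id=tile_id, side=side,
                            time_point=f"T{scenario.time_points.index(t)}",
                            squares_occupied=sq,
                        ))
    return obs


# ---------------------------------------------------------------------------
# PI-curve observations
# ---------------------------------------------------------------------------

def generate_pi_observations(
    n_tiles: int = 9,
    seed: int | None = None,
    alpha_mean: float = 20.0,
    gamma_range: tuple = (-0.012, -0.005),
    target_r2: tuple = (0.55, 0.70),
    par_max: float = 600.0,
) -> pd.DataFrame:
    """Diel PI measurements: 1-h incubations every 2 h, 06:00-22:00, 3 days.

    Each tile carries its own true curve (beta = 1 so y(0) = 0); noise is
    calibrated from the tile's own signal variance so the fitted R^2 lands
    in the study's band.  Returns columns tile_id, day, hour, par, np.
    """
    rng = np.random.default_rng(seed)
    hours = np.arange(6.0, 22.0 + 1e-9, 2.0)
    rows = []
    for i in range(n_tiles):
        alpha = alpha_mean * np.exp(rng.normal(0.0, 0.25))
        gamma = rng.uniform(*gamma_range)
        par_profile = par_max * np.sin(np.pi * (hours - 6.0) / 16.0) ** 2
        signal = []
        pts = []
        for day in range(3):
            par = np.clip(par_profile * np.exp(rng.normal(0, 0.15, len(hours))),
                          0.0, None)
            y = alpha * (1.0 - np.exp(gamma * par))
            signal.extend(y)
            pts.extend(zip([day] * len(hours), hours, par, y))
        signal = np.asarray(signal)
        r2 = rng.uniform(*target_r2)
        noise_sd = float(np.std(signal)) * np.sqrt(1.0 / r2 - 1.0)
        for day, hour, par, y in pts:
            rows.append(dict(
                tile_id=f"tile_{i}", day=day, hour=hour, par=float(par),
                np=float(y + rng.normal(0.0, noise_sd)),
                true_alpha=alpha, true_gamma=gamma,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end function study
# ---------------------------------------------------------------------------

def generate_function_study(
    scenario: Scenario, seed: int | None = None
) -> dict:
    """Chamber records for every tile x time point, with planted trends.

    The planted per-tile rates interpolate linearly between each zone's T0
    and day-120 endpoint (calcification declining into dissolution under
    extreme low pH; photosynthesis and NH4+ uptake rising as pH falls);
    tiles get a fixed multiplicative offset (CV ``tile_rate_cv``).  Returns
    {"records": [(light, dark, control_light, control_dark), ...],
    "truth": DataFrame of planted per-tile rates}.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    tr = scenario.function_trends
    t_final = max(scenario.time_points)
    records, truth = [], []
    for zone in scenario.zones:
        for community in scenario.communities:
            for tile_i in range(scenario.tiles_per_cell):
                tile_id = f"{zone}_{community}_{tile_i}"
                tile_factor = float(np.exp(rng.normal(0.0, scenario.tile_rate_cv)))
                for t in scenario.time_points:
                    frac = t / t_final

                    def planted(fn):
                        lo, hi = tr[fn][zone]
                        return (lo + (hi - lo) * frac) * tile_factor

                    np_rate = planted("photosynthesis")
                    calc = planted("calcification")
                    upt = planted("uptake_nh4")
                    resp = -0.25 * np_rate  # dark respiration scales with GP
                    sub = rng.integers(0, 2**31)
                    light = generate_incubation(
                        true_np=np_rate, true_calcification=calc,
                        true_uptake={"nh4": upt}, mode="light", tile_id=tile_id,
                        o2_noise=scenario.o2_noise, at_noise=scenario.at_noise,
                        nutrient_noise=scenario.nutrient_noise,
                        nutrient_start={"nh4": 6.0, "no3": 1.0, "po4": 0.2},
                        seed=int(sub),
                    )
                    dark = generate_incubation(
                        true_np=resp, mode="dark", tile_id=tile_id,
                        duration_min=60, o2_noise=scenario.o2_noise,
                        seed=int(sub) + 1,
                    )
                    ctrl_l = generate_incubation(
                        mode="control_light", tile_id=None,
                        o2_noise=scenario.o2_noise, at_noise=scenario.at_noise,
                        nutrient_noise=scenario.nutrient_noise,
                        nutrient_start={"nh4": 6.0, "no3": 1.0, "po4": 0.2},
                        seed=int(sub) + 2,
                    )
                    ctrl_d = generate_incubation(
                        mode="control_dark", tile_id=None, duration_min=60,
                        o2_noise=scenario.o2_noise, seed=int(sub) + 3,
                    )
                    records.append((light, dark, ctrl_l, ctrl_d))
                    truth.append(dict(
                        tile_id=tile_id, zone=zone, community=community,
                        time_days=t, np_rate=np_rate, r_rate=resp,
                        calcification=calc, uptake_nh4=upt,
                    ))
    return {"records": records, "truth": pd.DataFrame(truth)}
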