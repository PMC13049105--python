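"""Staged pipeline binding the analysis modules, with manifest and resume.

Stage order: simulate -> carb -> fluxes -> pi-fit -> community -> model.
Each stage writes its outputs (with provenance headers) into the configured
output directory; a JSON manifest records the resolved configuration, its
hash, the seeds used, and the files each stage produced.  With
``resume=True`` stages whose outputs already exist are skipped, so deleting
an intermediate file regenerates only the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import SeawaterState, solve_from_at_ph, DEFAULT_SALINITY
from .community import (
    bray_curtis, classify_community, cover_from_grid, biomass_estimate,
    permanova, DOMINANCE_THRESHOLD,
)
from .fluxes import compute_tile_fluxes, standardize, CHAMBER_VOLUME_L, SEAWATER_DENSITY
from .hierarchical import CommunityResponseModel
from .io import write_table
from .picurves import PICurve
from .synthetic import (
    Scenario, default_species_registry, generate_ph_series,
    generate_community_trajectories, generate_pi_observations,
    generate_function_study,
)
from .community import standardize_to_t0

log = logging.getLogger("ventflux")

STAGES = ("simulate", "carb", "fluxes", "pi_fit", "community", "model")


@dataclass
class PipelineConfig:
    """Resolved run configuration; written alongside every output."""

    out_dir: str = "ventflux_out"
    seed: int = 0
    constant_choice: str = "lueker"
    salinity_default: float = DEFAULT_SALINITY
    chamber_volume_l: float = CHAMBER_VOLUME_L
    seawater_density: float = SEAWATER_DENSITY
    detection_limit_nh4: float = 0.05
    detection_limit_no3: float = 0.01
    detection_limit_po4: float = 0.01
    dominance_threshold: float = DOMINANCE_THRESHOLD
    permutations: int = 999
    model_chains: int = 2
    model_iterations: int = 800
    model_warmup: int = 200
    resume: bool = False

    def __post_init__(self):
        for name in ("chamber_volume_l", "seawater_density",
                     "detection_limit_nh4", "detection_limit_no3",
                     "detection_limit_po4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("out_dir", "resume")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, scenario: Scenario | None = None) -> dict:
    """Run all stages on a (synthetic) scenario; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = scenario if scenario is not None else Scenario(seed=config.seed)
    prov = {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "version": __version__, "stages": {}}

    def done(stage: str, *files) -> bool:
        return config.resume and all((out / f).exists() for f in files)

    # -- simulate ----------------------------------------------------------
    ph_file = "ph_sensor.csv"
    if not done("simulate", ph_file):
        try:
            frames = [
                generate_ph_series(scenario, z, seed=config.seed + i)
                for i, z in enumerate(scenario.zones)
            ]
            write_table(pd.concat(frames, ignore_index=True), out / ph_file, prov)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e
    manifest["stages"]["simulate"] = [ph_file]
    log.info("simulate: wrote %s", ph_file)

    # -- carb --------------------------------------------------------------
    carb_file = "carbonate.csv"
    if not done("carb", carb_file):
        try:
            df = pd.read_csv(out / ph_file, comment="#")
            results = []
            for _, row in df.iterrows():
                s = row.get("salinity", np.nan)
                state = SeawaterState(
                    temperature=row["temperature_c"],
                    salinity=config.salinity_default if pd.isna(s) else s,
                    alkalinity_total=row.get("alkalinity_total", 2662.0),
                    ph_total=row["ph_total"],
                    salinity_defaulted=pd.isna(s),
                )
                r = solve_from_at_ph(state)
                results.append((r.ct, r.pco2, r.omega_calcite, r.omega_aragonite))
            df[["ct", "pco2", "omega_calcite", "omega_aragonite"]] = results
            df["salinity_defaulted"] = df.get("salinity", pd.Series(
                np.nan, index=df.index)).isna()
            write_table(df, out / carb_file, prov)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("carb", str(e)) from e
    manifest["stages"]["carb"] = [carb_file]
    log.info("carb: wrote %s", carb_file)

    # -- fluxes ------------------------------------------------------------
    flux_file = "fluxes.csv"
    study = None
    if not done("fluxes", flux_file):
        try:
            study = generate_function_study(scenario, seed=config.seed)
            rows = []
            truth = study["truth"]
            for (light, dark, cl, cd), (_, meta) in zip(
                study["records"], truth.iterrows()
            ):
                fr = compute_tile_fluxes(light, dark, cl, cd)
                rows.append(dict(
                    tile_id=fr.tile_id, zone=meta["zone"],
                    community=meta["community"], time_days=meta["time_days"],
                    np_rate=fr.np_rate, r_rate=fr.r_rate, gp_rate=fr.gp_rate,
                    calcification=fr.calcification,
                    uptake_nh4=fr.uptake_nh4,
                    qc_flags=";".join(fr.qc_flags),
                ))
            write_table(pd.DataFrame(rows), out / flux_file, prov)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("fluxes", str(e)) from e
    manifest["stages"]["fluxes"] = [flux_file]
    log.info("fluxes: wrote %s", flux_file)

    # -- pi_fit ------------------------------------------------------------
    pi_file = "pi_fits.csv"
    if not done("pi_fit", pi_file):
        try:
            obs = generate_pi_observations(n_tiles=9, seed=config.seed)
            fits = []
            for tile, grp in obs.groupby("tile_id"):
                f = PICurve(grp["par"].values, grp["np"].values).fit()
                fits.append(dict(tile_id=tile, alpha=f.alpha, beta=f.beta,
                                 gamma=f.gamma, r_squared=f.r_squared))
            write_table(pd.DataFrame(fits), out / pi_file, prov)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("pi_fit", str(e)) from e
    manifest["stages"]["pi_fit"] = [pi_file]
    log.info("pi_fit: wrote %s", pi_file)

    # -- community ---------------------------------------------------------
    comm_file = "community.csv"
    perm_file = "permanova.json"
    if not done("community", comm_file, perm_file):
        try:
            registry = default_species_registry(seed=config.seed)
            observations = generate_community_trajectories(
                scenario, seed=config.seed, registry=registry
            )
            by_tile_t0: dict[str, dict] = {}
            rows = []
            for o in observations:
                covers = cover_from_grid(o)
                if o.time_point == "T0":
                    by_tile_t0.setdefault(o.tile_id, {})[o.side] = covers
            species = sorted(registry)
            mat, labels = [], []
            for tile, sides in sorted(by_tile_t0.items()):
                biomass = biomass_estimate(sides, registry)
                label, flags = classify_community(
                    sides.get("front", {}), registry, config.dominance_threshold
                )
                rows.append(dict(tile_id=tile, biomass_t0_g=biomass,
                                 label=label, flags=";".join(flags)))
                front = sides.get("front", {})
                mat.append([front.get(sp, 0.0) for sp in species])
                labels.append(tile.split("_")[1])
            d, _ = bray_curtis(np.asarray(mat))
            pr = permanova(d, labels, n_permutations=config.permutations,
                           seed=config.seed)
            write_table(pd.DataFrame(rows), out / comm_file, prov)
            (out / perm_file).write_text(json.dumps(dict(
                pseudo_f=pr.pseudo_f, r_squared=pr.r_squared,
                p_value=pr.p_value, n_permutations=pr.n_permutations,
                seed=config.seed,
            ), indent=2))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("community", str(e)) from e
    manifest["stages"]["community"] = [comm_file, perm_file]
    log.info("community: wrote %s, %s", comm_file, perm_file)

    # -- model -------------------------------------------------------------
    model_file = "model_summary.csv"
    if not done("model", model_file):
        try:
            flux = pd.read_csv(out / flux_file, comment="#")
            tidy = []
            for tile, grp in flux.groupby("tile_id"):
                grp = grp.sort_values("time_days")
                t0 = grp.iloc[0]
                std = standardize_to_t0(
                    grp["uptake_nh4"].values, t0["uptake_nh4"]
                )
                for t, v in zip(grp["time_days"], std):
                    tidy.append(dict(
                        tile_id=tile, community=grp.iloc[0]["community"],
                        ph_zone=grp.iloc[0]["zone"], time_days=t, response=v,
                        response_type="uptake_nh4",
                    ))
            model = CommunityResponseModel(pd.DataFrame(tidy), family="gaussian")
            res = model.fit(chains=config.model_chains,
                            iterations=config.model_iterations,
                            warmup=config.model_warmup, seed=config.seed)
            write_table(res.summary().reset_index(), out / model_file, prov)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("model", str(e)) from e
    manifest["stages"]["model"] = [model_file]
    log.info("model: wrote %s", model_file)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
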