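"""End-to-end orchestration of the survey-to-risk workflow.

Stages (each independently invocable, all file-driven):

simulate
    Generate synthetic soil, core, water and questionnaire tables plus
    zone polygons into the output directory.
interpolate
    IDW map of surface tAs clipped to the site, written as an ESRI ASCII
    grid, with the NOM-147 (22 mg/kg) exceedance summary.
stats
    Zone summaries, Tukey outer-fence outlier screen, IA-vs-NIA
    comparison, water threshold ratios and irrigation mass loading.
risk
    Monte Carlo dermal risk characterization from the soil and
    questionnaire tables.
all
    Everything above, merged into one JSON report.

Reports are deterministic for a fixed config and seed (no timestamps);
numbers are stored unrounded with 2-significant-figure display strings
where relevant.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import shapely
import yaml

from . import idw as idw_mod
from . import io as pio
from . import stats as pstats
from . import synthetic as syn
from .risk import DermalRiskModel, round_sig

__all__ = ["PipelineConfig", "run", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "pitchrisk_out",
    "paths": {  # resolved relative to out_dir unless absolute
        "soil": "soil.csv",
        "cores": "cores.csv",
        "water": "water.csv",
        "survey": "survey.csv",
        "zones": "zones.geojson",
        "raster": "tas_idw.asc",
        "report": "report.json",
    },
    "idw": {"power": 2.0, "neighborhood": "all", "k": 12, "radius": 100.0,
            "cell_size": 5.0},
    "quartile_convention": "tukey",
    "mc": {"n_iter": 10000},
    "risk": {"zones": ["IA"], "joint": False},
    "thresholds": {
        "soil_mg_kg": 22.0,        # NOM-147 residential/agricultural soil As
        "water_mg_l": 0.4,         # Mexican surface-water As threshold
        "water_who_mg_l": 0.01,    # WHO drinking-water guideline
        "risk_strict": 1e-6,
        "risk_upper": 1e-4,
    },
    "irrigation": {
        "concentration_mg_per_l": 6.65,
        "flow_l_per_s": 7.63,
        "duration_s": 1800.0,
        "events_per_week": 2.0,
        "weeks_per_year": 52.0,
        "years": 13.0,
    },
}


def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


class PipelineConfig:
    """Structured configuration; YAML-backed, with defaults for every key."""

    def __init__(self, overrides: dict | None = None) -> None:
        self.data = _deep_update(DEFAULT_CONFIG, overrides or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.data["out_dir"])

    def path(self, key: str) -> Path:
        p = Path(self.data["paths"][key])
        return p if p.is_absolute() else self.out_dir / p

    def idw_config(self) -> idw_mod.IDWConfig:
        return idw_mod.IDWConfig(**self.data["idw"])

    def irrigation_spec(self) -> pstats.IrrigationSpec:
        return pstats.IrrigationSpec(**self.data["irrigation"])


def _stage_simulate(config: PipelineConfig) -> dict:
    seed = config.seed
    site = syn.default_site(seed=seed)
    pop = syn.SoilPopulationSpec()
    soil = syn.generate_soil_samples(site, pop)
    cores = syn.generate_depth_cores(site, pop)
    water = syn.generate_water_samples(seed=seed)
    survey = syn.generate_survey(syn.SurveySpec(), seed=seed)
    pio.write_soil_table(soil, config.path("soil"))
    pio.write_soil_table(cores, config.path("cores"))
    pio.write_water_table(water, config.path("water"))
    pio.write_survey_table(survey, config.path("survey"))
    pio.write_zones(dict(site.zones), config.path("zones"))
    return {
        "n_soil_rows": int(len(soil)),
        "n_primary": int((~soil["is_duplicate"]).sum()),
        "n_core_rows": int(len(cores)),
        "n_survey": int(len(survey)),
        "artifacts": {k: str(config.path(k))
                      for k in ("soil", "cores", "water", "survey", "zones")},
    }


def _stage_interpolate(config: PipelineConfig) -> dict:
    soil = pio.reconcile_duplicates(pio.read_soil_table(config.path("soil")))
    zones = pio.read_zones(config.path("zones"))
    boundary = shapely.union_all(list(zones.values()))
    grid = idw_mod.idw_interpolate(
        soil[["x", "y"]].to_numpy(), soil["tAs"].to_numpy(),
        config.idw_config(), boundary)
    pio.write_raster(grid, config.path("raster"))
    threshold = config.data["thresholds"]["soil_mg_kg"]
    return {
        "raster": str(config.path("raster")),
        "exceedance": idw_mod.exceedance_summary(grid, threshold),
    }


def _stage_stats(config: PipelineConfig) -> dict:
    convention = config.data["quartile_convention"]
    soil = pio.reconcile_duplicates(pio.read_soil_table(config.path("soil")))
    summaries = {
        label: pstats.zone_summary(soil, zone, convention).to_dict()
        for label, zone in (("all", None), ("IA", "IA"), ("NIA", "NIA"))
    }
    screen = pstats.screen_extreme_outliers(soil, convention)
    retained = screen.retained
    comparison = pstats.compare_zones(
        retained.loc[retained["zone"] == "IA", "tAs"],
        retained.loc[retained["zone"] == "NIA", "tAs"])

    mean_updates = {}
    if screen.n_flagged:
        whole = pstats.zone_summary(soil, None, convention)
        removed = float(soil.loc[soil["sample_id"] == screen.flagged_ids[0], "tAs"].iloc[0])
        mean_updates["all_after_removal"] = pstats.mean_after_removal(
            whole.n, whole.mean, removed)
        zone_of = soil.loc[soil["sample_id"] == screen.flagged_ids[0], "zone"].iloc[0]
        zs = pstats.zone_summary(soil, zone_of, convention)
        mean_updates[f"{zone_of}_after_removal"] = pstats.mean_after_removal(
            zs.n, zs.mean, removed)

    water = pio.read_water_table(config.path("water"))
    water_mean = float(water["As"].mean())
    thresholds = config.data["thresholds"]
    spec = config.irrigation_spec()
    annual = pstats.annual_arsenic_load(spec)
    return {
        "zone_summaries": summaries,
        "outlier_screen": {
            "fence": screen.fence, "q3": screen.q3, "iqr": screen.iqr,
            "flagged": list(screen.flagged_ids),
        },
        "mean_updates": mean_updates,
        "zone_comparison": comparison.to_dict(),
        "water": {
            "mean_As_mg_l": water_mean,
            "fold_over_national": pstats.fold_exceedance(
                water_mean, thresholds["water_mg_l"]),
            "fold_over_who": pstats.fold_exceedance(
                water_mean, thresholds["water_who_mg_l"]),
        },
        "soil_fold_over_threshold": pstats.fold_exceedance(
            summaries["IA"]["mean"], thresholds["soil_mg_kg"]),
        "irrigation_load": {
            "spec": dataclasses.asdict(spec),
            "annual_kg": annual,
            "cumulative_kg": pstats.cumulative_load(spec),
        },
    }


def _stage_risk(config: PipelineConfig) -> dict:
    soil = pio.reconcile_duplicates(pio.read_soil_table(config.path("soil")))
    responses = pio.read_survey_table(config.path("survey"))
    exposure = pio.survey_exposure_frame(responses)
    model = DermalRiskModel.from_tables(
        soil, exposure,
        zones=tuple(config.data["risk"]["zones"]),
        joint=bool(config.data["risk"]["joint"]))
    results = model.fit(n_iter=int(config.data["mc"]["n_iter"]), seed=config.seed)
    out = results.to_dict()
    out["summary_text"] = results.summary()
    return out


_STAGES = {
    "simulate": _stage_simulate,
    "interpolate": _stage_interpolate,
    "stats": _stage_stats,
    "risk": _stage_risk,
}


def run(subcommand: str, config: PipelineConfig) -> dict:
    """Run one stage (or ``all``) and write/merge the JSON report.

    Returns the report dict; raises ValueError on unknown subcommands and
    propagates validation errors from the stages.
    """
    if subcommand != "all" and subcommand not in _STAGES:
        raise ValueError(
            f"unknown subcommand {subcommand!r}; choose from "
            f"{', '.join([*_STAGES, 'all'])}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    names = list(_STAGES) if subcommand == "all" else [subcommand]
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_echo": config.data,
        "stages": {},
    }
    for name in names:
        report["stages"][name] = _STAGES[name](config)
    if "risk" in report["stages"]:
        upper = report["stages"]["risk"]["deterministic_upper"]
        report["headline"] = {
            "deterministic_upper_risk": upper,
            "deterministic_upper_risk_display": f"{round_sig(upper):.1e}",
        }
    with open(config.path("report"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
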