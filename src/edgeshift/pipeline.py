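"""End-to-end orchestration: simulate -> prep -> edges -> niche -> model.

A single validated :class:`RunConfig` drives every stage; all randomness
derives deterministically from one master seed via named sub-seed streams,
so re-running a configuration reproduces every output bit-identically and
inserting a stage never perturbs the others.  Outputs are tab-separated
tables with a sidecar JSON of column descriptions plus a machine-readable
run report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from edgeshift import synthetic
from edgeshift._seeds import subseed
from edgeshift.edge_shift import estimate_shifts_table, summarize_shifts
from edgeshift.grid import GridSpec
from edgeshift.niche_metrics import assemble_model_table, niche_metrics_table
from edgeshift.occurrence_prep import (
    ZonePartition,
    balance_effort,
    filter_southern_species,
    grid_presences,
)
from edgeshift.shift_model import (
    best_subsets,
    diagnostics,
    drop1,
    per_size_best,
    predict_profile,
    select_final,
)


class ConfigError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


_GRID_KEYS = {"x_min", "y_min", "x_max", "y_max", "cell_size"}

#: Variant presets mirroring the study's alternative models:
#: (a) tau 0.75, (b) CV breadths, (c) GDD5/PREC variables.
PRESETS: dict[str, dict] = {
    "main": {},
    "alt_a": {"tau_main": 0.75},
    "alt_b": {"breadth_kind": "CV"},
    "alt_c": {"thermal_var": "GDD5", "moisture_var": "PREC"},
}

DEFAULT_CANDIDATES = (
    "Tmean",
    "Tbreadth",
    "Mmean",
    "Mbreadth",
    "wintering_mode",
    "n_generations_class",
    "body_size",
    "range_size",
)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    n_species: int = 200
    grid: dict = field(
        default_factory=lambda: dict(
            x_min=200_000.0, y_min=6_600_000.0,
            x_max=400_000.0, y_max=7_700_000.0, cell_size=10_000.0,
        )
    )
    continent_grid: dict = field(
        default_factory=lambda: dict(
            x_min=0.0, y_min=0.0, x_max=2.5e6, y_max=3.0e6, cell_size=50_000.0
        )
    )
    periods: dict = field(
        default_factory=lambda: {"T1": (1992, 1996), "T2": (2013, 2017)}
    )
    effort: dict = field(
        default_factory=lambda: {
            "T1": {"rate": 0.1, "north_multiplier": 1.0},
            "T2": {"rate": 0.3, "north_multiplier": 1.0},
        }
    )
    occupancy_prob: float = 0.5
    effect_model: dict = field(
        default_factory=lambda: dict(synthetic.DEFAULT_EFFECT_MODEL)
    )
    shift_noise_sd: float = 20.0
    n_zones: int = 5
    n_replicates: int = 5
    center_threshold: float = 7_000_000.0
    center_method: str = "mean"
    taus: tuple = (0.9, 0.75)
    tau_main: float = 0.9
    ci_method: str = "bootstrap"
    B: int = 1000
    min_support: int = 5
    thermal_var: str = "MAT"
    moisture_var: str = "SWC"
    breadth_kind: str = "SD"
    candidates: tuple = DEFAULT_CANDIDATES
    delta_aic: float = 2.0
    simulate: bool = True
    occurrences_path: str | None = None
    atlas_path: str | None = None
    climate_path: str | None = None
    traits_path: str | None = None
    stages: tuple = ("simulate", "prep", "edges", "niche", "model")

    def grid_spec(self) -> GridSpec:
        return GridSpec(**self.grid)

    def continent_spec(self) -> GridSpec:
        return GridSpec(**self.continent_grid)


def validate_config(raw) -> RunConfig:
    """Parse and cross-check a config mapping or YAML document.

    Unknown keys are rejected; numeric fields are range-checked; defaults
    are applied for omitted keys (5 replicates, delta-AIC 2, B = 1000...).
    A ``preset`` key applies one of the variant presets before the explicit
    keys.
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(str(raw)) if isinstance(raw, str) else yaml.safe_load(
            Path(raw).read_text()
        )
        if isinstance(raw, str):
            raise ConfigError("config document did not parse to a mapping")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    raw = dict(raw)
    preset = raw.pop("preset", "main")
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {list(PRESETS)}")
    merged = {**PRESETS[preset], **raw}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(merged) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**merged)

    cfg.taus = tuple(float(t) for t in cfg.taus)
    cfg.candidates = tuple(cfg.candidates)
    cfg.stages = tuple(cfg.stages)
    cfg.periods = {k: tuple(v) for k, v in cfg.periods.items()}
    for name, tau in [("tau_main", cfg.tau_main)] + [
        (f"taus[{i}]", t) for i, t in enumerate(cfg.taus)
    ]:
        if not 0.0 < float(tau) < 1.0:
            raise ConfigError(f"{name} must be in (0, 1), got {tau}")
    if cfg.B <= 0:
        raise ConfigError(f"B must be positive, got {cfg.B}")
    if cfg.n_replicates < 1:
        raise ConfigError(f"n_replicates must be >= 1, got {cfg.n_replicates}")
    if cfg.n_zones < 1:
        raise ConfigError(f"n_zones must be >= 1, got {cfg.n_zones}")
    if cfg.breadth_kind not in ("SD", "CV"):
        raise ConfigError(f"breadth_kind must be 'SD' or 'CV', got {cfg.breadth_kind!r}")
    if cfg.thermal_var not in ("MAT", "GDD5"):
        raise ConfigError(f"thermal_var must be MAT or GDD5, got {cfg.thermal_var!r}")
    if cfg.moisture_var not in ("SWC", "PREC"):
        raise ConfigError(f"moisture_var must be SWC or PREC, got {cfg.moisture_var!r}")
    if cfg.ci_method not in ("bootstrap", "none"):
        raise ConfigError(f"ci_method must be bootstrap or none, got {cfg.ci_method!r}")
    if cfg.center_method not in ("mean", "median"):
        raise ConfigError(f"center_method must be mean or median")
    if set(cfg.grid) != _GRID_KEYS or set(cfg.continent_grid) != _GRID_KEYS:
        raise ConfigError(f"grid specs need exactly the keys {sorted(_GRID_KEYS)}")
    if len(cfg.periods) != 2:
        raise ConfigError("exactly two period windows are required")
    cfg.grid_spec()
    cfg.continent_spec()
    if not cfg.simulate:
        needed = {
            "prep": ["occurrences_path"],
            "niche": ["atlas_path", "climate_path"],
            "model": ["traits_path"],
        }
        for stage, paths in needed.items():
            if stage in cfg.stages:
                for p in paths:
                    if getattr(cfg, p) is None:
                        raise ConfigError(
                            f"stage {stage!r} without simulation requires {p}"
                        )
    return cfg


_SIDECARS = {
    "occurrences.tsv": {
        "species_id": "species identifier",
        "easting_m": "record easting (m)",
        "northing_m": "record northing (m)",
        "year": "observation year",
    },
    "climate_grid.tsv": {
        "cell_id": "row-major continent cell id",
        "easting_m": "cell centroid easting (m)",
        "northing_m": "cell centroid northing (m)",
        "MAT": "mean annual temperature (degC)",
        "GDD5": "growing degree days above 5 degC",
        "PREC": "annual precipitation (mm)",
        "SWC": "soil water content (fraction)",
    },
    "edges.tsv": {
        "species_id": "species identifier",
        "tau": "quantile defining the edge",
        "edge_T1_m": "edge northing in T1 (m)",
        "edge_T2_m": "edge northing in T2 (m)",
        "shift_km": "edge shift (km, + = northward)",
        "ci_low_km": "lower 95% CI bound (km)",
        "ci_high_km": "upper 95% CI bound (km)",
        "class": "northward / southward / none",
        "n_T1": "T1 presences", "n_T2": "T2 presences",
        "n_replicates": "replicates averaged",
    },
}


def _write_tsv(df: pd.DataFrame, path: Path, name: str) -> None:
    df.to_csv(path / name, sep="\t", index=False)
    if name in _SIDECARS:
        (path / (name + ".json")).write_text(
            json.dumps(_SIDECARS[name], indent=1)
        )


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run all configured stages; return the machine-readable run report."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: str(v) for k, v in asdict(cfg).items()}, "stages": {}}
    spec = cfg.grid_spec()

    # --- simulate -------------------------------------------------------
    if cfg.simulate and "simulate" in cfg.stages:
        truth = synthetic.simulate_species_pool(
            cfg.n_species,
            effect_model=dict(cfg.effect_model),
            shift_noise_sd=cfg.shift_noise_sd,
            seed=subseed(cfg.seed, "species-pool"),
        )
        climate = synthetic.simulate_climate_grid(
            cfg.continent_spec(),
            synthetic.CONTINENT_GRADIENTS,
            seed=subseed(cfg.seed, "climate-grid"),
        )
        atlas = synthetic.simulate_european_atlas(
            truth, climate, seed=subseed(cfg.seed, "atlas")
        )
        effort = {
            k: synthetic.EffortSpec(**v) for k, v in cfg.effort.items()
        }
        occurrences = synthetic.simulate_occurrences(
            truth, spec, cfg.periods, effort, cfg.occupancy_prob,
            seed=subseed(cfg.seed, "occurrences"),
        )
        traits = synthetic.traits_table(truth)
        _write_tsv(truth, out, "truth.tsv")
        _write_tsv(climate, out, "climate_grid.tsv")
        _write_tsv(atlas, out, "euro_atlas.tsv")
        _write_tsv(occurrences, out, "occurrences.tsv")
        _write_tsv(traits, out, "traits.tsv")
        report["stages"]["simulate"] = {
            "n_species": int(len(truth)),
            "n_occurrence_records": int(len(occurrences)),
            "skipped_species": occurrences.attrs.get("skipped_species", []),
        }
    else:
        occurrences = pd.read_csv(cfg.occurrences_path, sep="\t")
        atlas = pd.read_csv(cfg.atlas_path, sep="\t")
        climate = pd.read_csv(cfg.climate_path, sep="\t")
        traits = pd.read_csv(cfg.traits_path, sep="\t")
        truth = None

    # --- prep -----------------------------------------------------------
    prep_report: dict = {}
    presences = grid_presences(occurrences, spec, cfg.periods, report=prep_report)
    retained = filter_southern_species(
        presences, cfg.center_threshold, cfg.center_method, report=prep_report
    )
    presences = presences[presences["species_id"].isin(retained)]
    zones = ZonePartition.equal_width(spec.y_min, spec.y_max, cfg.n_zones)
    replicates = balance_effort(
        presences, zones, cfg.n_replicates, seed=subseed(cfg.seed, "balance")
    )
    _write_tsv(presences, out, "presences.tsv")
    for rep in replicates:
        _write_tsv(rep.presences, out, f"replicate_{rep.index}.tsv")
    prep_report["zone_counts"] = replicates[0].zone_counts.to_dict("records")
    prep_report["replicate_seeds"] = [r.seed for r in replicates]
    report["stages"]["prep"] = prep_report

    # --- edges ----------------------------------------------------------
    edges_by_tau: dict[float, pd.DataFrame] = {}
    edge_report: dict = {}
    for tau in cfg.taus:
        edges_by_tau[tau] = estimate_shifts_table(
            replicates, tau=tau, ci=cfg.ci_method, B=cfg.B,
            seed=subseed(cfg.seed, f"edges-tau-{tau}"),
            min_support=cfg.min_support, report=edge_report,
        )
    edges_all = pd.concat(edges_by_tau.values(), ignore_index=True)
    _write_tsv(edges_all, out, "edges.tsv")
    edges_main = edges_by_tau[cfg.tau_main]
    summary = summarize_shifts(edges_main)
    _write_tsv(summary, out, "group_summary.tsv")
    report["stages"]["edges"] = {
        **edge_report,
        "n_species_estimated": int(edges_main["species_id"].nunique()),
        "mean_shift_km": float(edges_main["shift_km"].mean()),
    }

    # --- niche ----------------------------------------------------------
    niches = niche_metrics_table(atlas, climate)
    _write_tsv(niches, out, "niche_metrics.tsv")
    table_report: dict = {}
    model_table = assemble_model_table(
        edges_main, niches, traits,
        thermal_var=cfg.thermal_var, moisture_var=cfg.moisture_var,
        breadth_kind=cfg.breadth_kind, report=table_report,
    )
    _write_tsv(model_table, out, "model_table.tsv")
    report["stages"]["niche"] = {
        **table_report, "n_model_rows": int(len(model_table))
    }

    # --- model ----------------------------------------------------------
    sel_report: dict = {}
    if "model" in cfg.stages:
        cands = best_subsets(model_table, cfg.candidates)
        cand_df = pd.DataFrame(
            {
                "subset": [" + ".join(c.predictors) or "(intercept)" for c in cands],
                "size": [c.size for c in cands],
                "r2": [c.r2 for c in cands],
                "adj_r2": [c.model.adj_r2 if c.model else np.nan for c in cands],
                "pred_r2": [c.model.pred_r2 if c.model else np.nan for c in cands],
                "aic": [c.aic for c in cands],
                "best_in_size": [c.best_in_size for c in cands],
            }
        )
        _write_tsv(cand_df, out, "candidates.tsv")
        sel = select_final(per_size_best(cands), delta=cfg.delta_aic)
        final = sel.chosen.model
        sel_report = {
            "chosen_predictors": list(sel.chosen.predictors),
            "size": sel.size,
            "aic": sel.aic,
            "r2": final.r2,
            "adj_r2": final.adj_r2,
            "pred_r2": final.pred_r2,
            "coefficients": final.params.to_dict(),
        }
        (out / "selection.json").write_text(json.dumps(sel_report, indent=1))
        _write_tsv(drop1(final), out, "drop1.tsv")
        diag = diagnostics(final)
        diag_json = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in diag.items()
        }
        (out / "diagnostics.json").write_text(json.dumps(diag_json, indent=1))
        profiles = []
        for p in final.predictors:
            if p in final.design.cont_stats:
                prof = predict_profile(final, p)
                prof.insert(0, "focus", p)
                prof = prof.rename(columns={p: "focus_value"})
                profiles.append(prof)
        if profiles:
            _write_tsv(pd.concat(profiles, ignore_index=True), out, "profiles.tsv")
        report["stages"]["model"] = sel_report

    if truth is not None and not edges_main.empty:
        merged = edges_main.merge(
            truth[["species_id", "true_shift_km"]], on="species_id"
        )
        if len(merged) > 2:
            report["recovery"] = {
                "pearson_r_est_vs_true": float(
                    np.corrcoef(merged["shift_km"], merged["true_shift_km"])[0, 1]
                ),
                "mean_true_shift_km": float(merged["true_shift_km"].mean()),
                "mean_estimated_shift_km": float(merged["shift_km"].mean()),
            }
    report["seed"] = cfg.seed
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
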