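"""Configuration and end-to-end pipeline runner.

The pipeline chains the analysis stages over a designed-experiment table and
a compound library: quadratic fit -> ANOVA -> desirability optimization ->
(optional) MLP surrogate -> model comparison -> optimum validation ->
mass annotation.  Configuration is a TOML file with a fixed schema; unknown
keys are rejected so typos fail loudly rather than silently using defaults.

Numeric report values are serialized at full precision in the JSON report;
the CSV exports are for display and round to conventional table precision.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann, datasets, design as design_mod, mass, metrics
from .desirability import DesirabilityGoal, goals_from_observed, optimize_desirability
from .errors import PipelineIOError
from .rsm import QuadraticSurface

log = logging.getLogger("extractopt")

_SCHEMA = {
    "pipeline": {"seed", "output_dir"},
    "inputs": {"design_csv", "library_csv"},
    "rsm": {"responses"},
    "optimize": {"grid_step", "goals"},
    "ann": {"enabled", "hidden", "trainer", "seeds", "max_epochs", "patience", "cascade"},
    "annotate": {"tolerance_ppm"},
    "validate": {"actual"},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "extractopt_out"
    design_csv: str | None = None
    library_csv: str | None = None
    responses: tuple = ("TPC", "TFC")
    grid_step: float = 0.01
    goals: list = field(default_factory=list)  # DesirabilityGoal overrides
    ann_enabled: bool = True
    ann_hidden: int = 5
    ann_trainer: str = "levenberg_marquardt"
    ann_seeds: int = 10
    ann_max_epochs: int = 100
    ann_patience: int = 6
    ann_cascade: bool = False
    tolerance_ppm: float = 5.0
    validate_actual: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise PipelineIOError("config", f"cannot read config: {exc}") from exc
        for section, keys in raw.items():
            if section not in _SCHEMA:
                raise PipelineIOError("config", f"unknown config section {section!r}")
            for key in keys:
                if key not in _SCHEMA[section]:
                    raise PipelineIOError(
                        "config", f"unknown key {key!r} in section {section!r}"
                    )
        cfg = cls()
        pl = raw.get("pipeline", {})
        cfg.seed = int(pl.get("seed", cfg.seed))
        cfg.output_dir = pl.get("output_dir", cfg.output_dir)
        inp = raw.get("inputs", {})
        cfg.design_csv = inp.get("design_csv") or None
        cfg.library_csv = inp.get("library_csv") or None
        cfg.responses = tuple(raw.get("rsm", {}).get("responses", cfg.responses))
        opt = raw.get("optimize", {})
        cfg.grid_step = float(opt.get("grid_step", cfg.grid_step))
        for g in opt.get("goals", []):
            cfg.goals.append(
                DesirabilityGoal(
                    response=g["response"],
                    kind=g.get("kind", "maximize"),
                    low=float(g["low"]),
                    high=float(g["high"]),
                    target=g.get("target"),
                    weight=float(g.get("weight", 1.0)),
                    shape=float(g.get("shape", 1.0)),
                )
            )
        a = raw.get("ann", {})
        cfg.ann_enabled = bool(a.get("enabled", cfg.ann_enabled))
        cfg.ann_hidden = int(a.get("hidden", cfg.ann_hidden))
        cfg.ann_trainer = a.get("trainer", cfg.ann_trainer)
        cfg.ann_seeds = int(a.get("seeds", cfg.ann_seeds))
        cfg.ann_max_epochs = int(a.get("max_epochs", cfg.ann_max_epochs))
        cfg.ann_patience = int(a.get("patience", cfg.ann_patience))
        cfg.ann_cascade = bool(a.get("cascade", cfg.ann_cascade))
        cfg.tolerance_ppm = float(raw.get("annotate", {}).get("tolerance_ppm", cfg.tolerance_ppm))
        cfg.validate_actual = dict(raw.get("validate", {}).get("actual", {}))
        return cfg


def _load_design(cfg: PipelineConfig):
    if cfg.design_csv is None:
        return datasets.load_dateseed_design()
    try:
        df = pd.read_csv(cfg.design_csv)
    except Exception as exc:
        raise PipelineIOError("design", f"cannot read {cfg.design_csv}: {exc}") from exc
    needed = ["ec_pct", "time_min", "temp_c"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PipelineIOError("design", f"design CSV missing columns: {missing}")
    coded = design_mod.code_point(df[needed].to_numpy(), design_mod.DATESEED_FACTORS)
    table = design_mod.DesignTable(
        factors=design_mod.DATESEED_FACTORS,
        coded=np.round(coded).astype(int) if np.allclose(coded, np.round(coded)) else coded,
        run_ids=list(df["run"]) if "run" in df.columns else [],
    )
    responses = {}
    for name in cfg.responses:
        col = f"{name.lower()}_exp"
        if col not in df.columns:
            raise PipelineIOError("design", f"design CSV missing response column {col!r}")
        responses[name] = df[col].to_numpy(dtype=float)
    return table, responses


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under cfg.output_dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}

    design, responses = _load_design(cfg)
    log.info("design: %d runs, %d centers", len(design), design.center_replicates)
    design.to_csv(out / "design.csv")

    # fit + anova per response
    models: dict[str, QuadraticSurface] = {}
    anova_frames = []
    report["rsm"] = {}
    for name in cfg.responses:
        model = QuadraticSurface(response=name).fit(design.coded, responses[name])
        models[name] = model
        panel = model.anova()
        frame = panel.to_frame()
        frame.insert(0, "response", name)
        anova_frames.append(frame)
        report["rsm"][name] = {
            "coefficients": model.coefficients(),
            **panel.summary_stats(),
            "model_f": panel.model_f,
            "model_p": panel.model_p,
            "lack_of_fit_f": panel.lack_of_fit_f,
            "lack_of_fit_p": panel.lack_of_fit_p,
        }
        (out / f"model_{name}.json").write_text(model.to_json())
    pd.concat(anova_frames).to_csv(out / "anova.csv", index=False)

    # desirability optimization
    goals = list(cfg.goals) or goals_from_observed(responses)
    opt = optimize_desirability(models, goals, design.factors, grid_step=cfg.grid_step)
    report["optimum"] = json.loads(opt.to_json())
    (out / "optimum.json").write_text(opt.to_json())

    # surrogate + comparison
    comparison_rows = []
    for name in cfg.responses:
        obs = responses[name]
        rsm_pred = models[name].predict(design.coded)
        comparison_rows.append(metrics.compare(obs, rsm_pred, f"RSM {name}").to_dict())
        if cfg.ann_enabled:
            net = ann.best_of_seeds(
                design.coded,
                obs,
                seeds=range(cfg.seed, cfg.seed + cfg.ann_seeds),
                hidden_units=cfg.ann_hidden,
                trainer=cfg.ann_trainer,
                max_epochs=cfg.ann_max_epochs,
                patience=cfg.ann_patience,
                cascade=cfg.ann_cascade,
            )
            comparison_rows.append(
                metrics.compare(obs, net.predict(design.coded), f"ANN {name}").to_dict()
            )
            (out / f"ann_{name}.json").write_text(net.to_json())
    report["comparison"] = comparison_rows
    pd.DataFrame(comparison_rows).to_csv(out / "comparison.csv", index=False)

    # optimum validation against confirmatory values, when provided
    report["validation"] = {}
    for name, actual in cfg.validate_actual.items():
        if name in report["optimum"]["predicted"]:
            v = metrics.validate_optimum(actual, report["optimum"]["predicted"][name])
            report["validation"][name] = v.to_dict()

    # mass annotation: self-annotate the library's observed masses
    library = (
        mass.read_library_csv(cfg.library_csv)
        if cfg.library_csv
        else datasets.load_compound_library()
    )
    peaks = [rec.observed_mz for rec in library]
    matches, unmatched = mass.annotate(peaks, library, tolerance_ppm=cfg.tolerance_ppm)
    mass.annotation_frame(matches, unmatched).to_csv(out / "annotation.csv", index=False)
    report["annotation"] = {
        "library_size": len(library),
        "tolerance_ppm": cfg.tolerance_ppm,
        "matched_peaks": len(matches),
        "unmatched_peaks": len(unmatched),
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
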