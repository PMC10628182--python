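"""Pipeline orchestration: simulate -> analyze -> fit -> compare -> report.

A single validated config drives every stage; all randomness derives from one
global seed through named substreams, every output file carries the config
hash, and stages exchange data only through the documented file formats
(trial TSV, tidy TSV tables, JSON summaries).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import behavior, ddm, mixture, simulate, trials, tuning
from .fokker_planck import DriftField
from .wheel import ACCURACY_WINDOWS, ColorWheelSpec

log = logging.getLogger("driftring")


class GeneratorBlock(BaseModel):
    n_trials: int = 20000
    trial_type_weights: Optional[list[float]] = None
    serial_bias_gain: float = 0.0
    n_sessions: int = 8
    drift: str = "six_attractor"  # or "none"
    drift_amplitude: float = 1.0
    beta_encode: dict[int, float] = Field(default_factory=lambda: {1: 1.2, 2: 1.2})
    sigma_encode: dict[int, float] = Field(default_factory=lambda: {1: 0.25, 2: 0.35})
    beta_memory: dict[int, float] = Field(default_factory=lambda: {1: 0.6, 2: 0.8})
    sigma_memory: dict[int, float] = Field(default_factory=lambda: {1: 0.35, 2: 0.5})
    p_swap: float = 0.1
    p_guess: dict[int, float] = Field(default_factory=lambda: {1: 0.05, 2: 0.1})


class DDMBlock(BaseModel):
    grid_size: int = 128
    k_folds: int = 4
    n_restarts: int = 2
    maxiter: int = 120
    subsample: Optional[int] = 3000
    variants: list[str] = Field(default_factory=lambda: list(ddm.VARIANTS))


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML on disk)."""

    input_path: Optional[str] = None
    generator: Optional[GeneratorBlock] = None
    n_colors: int = 64
    seed: int = 0
    output_dir: str = "driftring_out"
    run_behavior: bool = True
    run_mixture: bool = True
    run_colorfit: bool = True
    run_ddm: bool = False
    ddm: DDMBlock = Field(default_factory=DDMBlock)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path or generator must be set")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(**yaml.safe_load(fh))


def _substream(seed: int, name: str) -> np.random.SeedSequence:
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.SeedSequence([seed, digest])


def _model_from_block(g: GeneratorBlock) -> simulate.GenerativeModelSpec:
    if g.drift == "six_attractor":
        drift = simulate.six_attractor_drift(g.drift_amplitude)
    elif g.drift == "none":
        drift = DriftField(np.zeros(12))
    else:
        raise ValueError(f"unknown drift preset {g.drift!r}")
    return simulate.GenerativeModelSpec(
        drift=drift,
        beta_encode=dict(g.beta_encode), sigma_encode=dict(g.sigma_encode),
        beta_memory=dict(g.beta_memory), sigma_memory=dict(g.sigma_memory),
        p_swap=g.p_swap, p_guess=dict(g.p_guess),
    )


def simulate_stage(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    g = config.generator
    model = _model_from_block(g)
    seeds = _substream(config.seed, "generator").generate_state(g.n_sessions)
    per = g.n_trials // g.n_sessions
    tables = []
    for i, s in enumerate(seeds):
        cfg = simulate.SessionConfig(
            n_trials=per + (g.n_trials % g.n_sessions if i == g.n_sessions - 1 else 0),
            trial_type_weights=None if g.trial_type_weights is None else np.asarray(g.trial_type_weights),
            n_colors=config.n_colors,
            seed=int(s % (2**31)),
            serial_bias_gain=g.serial_bias_gain,
            session_id=f"s{i + 1:03d}",
        )
        tables.append(simulate.generate_dataset(cfg, model))
    table = pd.concat(tables, ignore_index=True)
    trials.write_trials(table, out_dir / "trials.tsv")
    return table


def behavior_stage(table: pd.DataFrame, wheel: ColorWheelSpec, out_dir: Path) -> dict:
    perf = behavior.performance_by_condition(table, wheel)
    tidy = []
    for lvl, mat in perf["matrices"].items():
        m = mat.reset_index(names="load_condition").melt(
            id_vars="load_condition", var_name="delay_class", value_name="proportion"
        )
        m["accuracy_level"] = lvl
        tidy.append(m)
    pd.concat(tidy).to_csv(out_dir / "performance.tsv", sep="\t", index=False)
    freq = behavior.normalized_response_frequency(table, wheel)
    freq.to_csv(out_dir / "response_frequency.tsv", sep="\t", index=False)
    diag = behavior.bias_precision_along_diagonal(table, wheel)
    diag.to_csv(out_dir / "bias_precision.tsv", sep="\t", index=False)
    summary = {
        "n_trials": int(len(table)),
        "diagonal_full_range": perf["diagonal"]["full"],
        "bias_diagonal": diag["bias"].tolist(),
        "precision_diagonal": diag["precision"].tolist(),
    }
    try:
        sd = behavior.serial_dependence_curve(table, wheel)
        sd.as_frame().to_csv(out_dir / "serial_bias_curve.tsv", sep="\t", index=False)
        summary["serial_peak_deg"] = sd.peak_location_deg
        summary["serial_peak_rad"] = sd.peak_magnitude_rad
    except ValueError:
        pass
    return summary


def mixture_stage(table: pd.DataFrame, wheel: ColorWheelSpec, out_dir: Path, seed: int) -> dict:
    rows = {}
    cond = behavior._condition_labels(table)
    for name, delay in behavior.DIAGONAL:
        sel = ((cond == name) & (table["delay_class"] == delay)).to_numpy()
        if sel.sum() < 10:
            continue
        sub = table.loc[sel]
        err = trials.response_errors(sub, wheel)
        nt = trials.nontarget_errors(sub, wheel)
        fit = mixture.fit_mixture(err, nt, random_state=seed)
        rows[f"{name}_{delay}"] = fit.to_dict()
    with open(out_dir / "mixture_fits.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    pd.DataFrame(rows).T.rename_axis("condition").reset_index().to_csv(
        out_dir / "mixture_fits.tsv", sep="\t", index=False
    )
    return rows


def colorfit_stage(table: pd.DataFrame, wheel: ColorWheelSpec, out_dir: Path) -> pd.DataFrame:
    coefs = tuning.color_tuning_table(table, wheel)
    coefs.to_csv(out_dir / "color_tuning.tsv", sep="\t", index=False)
    return coefs


def ddm_stage(table: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    d = config.ddm
    fit_kwargs = dict(
        grid_size=d.grid_size, subsample=d.subsample,
        n_restarts=d.n_restarts, maxiter=d.maxiter,
    )
    full = ddm.DriftDiffusionModel(variant="full", random_state=config.seed, **fit_kwargs).fit(table)
    att = full.attractors()
    grid = full.params_.drift.grid
    beta = max(full.params_.beta_memory.values()) or max(full.params_.beta_encode.values())
    pd.DataFrame({"angle_rad": grid, "drift": beta * full.params_.drift.on_grid()}).to_csv(
        out_dir / "drift_curve.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"attractor_angle_rad": att.attractor_angles,
         "nearest_color": 1 + np.round(att.attractor_angles / (2 * np.pi / config.n_colors)).astype(int) % config.n_colors}
    ).to_csv(out_dir / "attractors.tsv", sep="\t", index=False)
    comparison = ddm.cross_validate(
        table, variants=tuple(d.variants), k_folds=d.k_folds,
        seed=config.seed, **fit_kwargs,
    )
    comparison.fold_nll.rename_axis("fold").reset_index().to_csv(
        out_dir / "model_comparison.tsv", sep="\t", index=False
    )
    report = {
        "fit": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in full.result_.items()},
        "nll": full.nll_,
        "n_attractors": att.count,
        "attractor_angles_rad": att.attractor_angles.tolist(),
        "best_variant": comparison.best_variant(),
        "mean_nll": comparison.mean_nll.to_dict(),
    }
    with open(out_dir / "ddm_fit.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wheel = ColorWheelSpec(config.n_colors)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    t_start = time.time()
    try:
        if config.generator is not None:
            table = simulate_stage(config, out_dir)
            manifest["stages"]["simulate"] = {"n_trials": int(len(table))}
        else:
            table = trials.read_trials(config.input_path, wheel)
            manifest["stages"]["load"] = {"n_trials": int(len(table))}
        if config.run_behavior:
            manifest["stages"]["behavior"] = behavior_stage(table, wheel, out_dir)
        if config.run_mixture:
            manifest["stages"]["mixture"] = {"conditions": list(mixture_stage(table, wheel, out_dir, config.seed))}
        if config.run_colorfit:
            coefs = colorfit_stage(table, wheel, out_dir)
            manifest["stages"]["colorfit"] = {"mean_adj_r2": float(coefs["adj_r2"].mean())}
        if config.run_ddm:
            manifest["stages"]["ddm"] = ddm_stage(table, config, out_dir)
    except Exception as exc:  # partial outputs retained with a failure manifest
        manifest["failure"] = {"stage": "see stages", "error": str(exc)}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


FIXTURE_PRESETS = {
    "six_attractor": GeneratorBlock(n_trials=4000, n_sessions=4),
    "pure_diffusion": GeneratorBlock(n_trials=4000, n_sessions=4, drift="none", p_swap=0.05),
    "swap_heavy": GeneratorBlock(
        n_trials=4000, n_sessions=4, p_swap=0.3,
        trial_type_weights=[0, 0, 0, 0, 0, 0, 1, 1, 1],
    ),
}


def make_fixtures(seed: int, out_dir) -> dict:
    """Generate the small bundled test datasets with documented parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, block in FIXTURE_PRESETS.items():
        cfg = PipelineConfig(generator=block, seed=seed, output_dir=str(out_dir / name),
                             run_behavior=False, run_mixture=False, run_colorfit=False)
        sub = Path(cfg.output_dir)
        sub.mkdir(parents=True, exist_ok=True)
        simulate_stage(cfg, sub)
        manifest[name] = block.model_dump()
    with open(out_dir / "fixtures.json", "w") as fh:
        json.dump({"seed": seed, "presets": manifest}, fh, indent=2)
    return manifest
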