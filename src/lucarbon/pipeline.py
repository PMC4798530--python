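"""End-to-end orchestration: config in, report files out.

A run is driven by one YAML config. Inputs are either CSV paths (grid,
biomass samples, admin stats) or a synthetic preset; the pipeline validates
the grid, builds parameters, runs the baseline engine (plus any requested
scenarios), writes the report tables and a manifest capturing the config
hash, seed and input digests. Outputs are written atomically
(write-then-rename) so a failed run never leaves partial files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, reporting, scenarios, synth
from .bookkeeping import InitConfig, run_grid, validate_grid
from .dynamics import curve_table
from .params import build_params

__all__ = ["load_config", "run_pipeline"]

log = logging.getLogger("lucarbon")


def load_config(config_path: str | os.PathLike) -> dict:
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"config {config_path} must be a mapping")
    return config


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    _atomic_write(path, lambda tmp: frame.to_csv(tmp, index=False))


def _write_json(path: Path, obj) -> None:
    _atomic_write(
        path, lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=2) + "\n")
    )


def _load_inputs(config: Mapping, seed: int):
    """Return (grid, biomass table, admin stats, input digests)."""
    digests: dict[str, str] = {}
    if "inputs" in config:
        inputs = config["inputs"]
        grid = pd.read_csv(inputs["grid"])
        biomass = pd.read_csv(inputs["biomass"])
        admin = pd.read_csv(inputs["admin"])
        for key in ("grid", "biomass", "admin"):
            digests[key] = _sha256_file(Path(inputs[key]))
        return grid, biomass, admin, digests
    synth_cfg = dict(config.get("synth", {}))
    preset = synth_cfg.pop("preset", "national_like")
    if preset != "national_like":
        raise ValueError(f"unknown synthetic preset {preset!r}")
    n_pixels = int(synth_cfg.pop("n_pixels", 800))
    landscape = synth.gen_national_like(n_pixels=n_pixels, seed=seed)
    grid, biomass, admin = synth.gen_landscape(landscape)
    digests["synthetic_seed"] = str(seed)
    return grid, biomass, admin, digests


def run_pipeline(
    config_path: str | os.PathLike, output_dir: str | os.PathLike
) -> dict:
    """Execute a full run and return the manifest (also written to disk)."""
    config_path = Path(config_path)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_text = config_path.read_text()
    config = load_config(config_path)
    seed = int(config.get("seed", 0))

    log.info("stage=inputs loading data")
    grid, biomass, admin, digests = _load_inputs(config, seed)
    try:
        validate_grid(grid)
    except ValueError as exc:
        raise ValueError(f"stage=validate grid validation failed: {exc}") from exc

    log.info("stage=params building carbon parameters")
    base_config = dict(config.get("params", {}))
    spec_name = config.get("scenario", {}).get("name", "baseline")
    try:
        spec = scenarios.SCENARIOS[spec_name]
    except KeyError:
        raise ValueError(
            f"stage=params unknown scenario {spec_name!r}; "
            f"valid: {sorted(scenarios.SCENARIOS)}"
        ) from None
    init_cfg = InitConfig(**config.get("init", {}))

    log.info("stage=bookkeeping running scenario %s", spec.name)
    result = scenarios.run_scenario(grid, biomass, spec, base_config, init_cfg)
    params = build_params(scenarios.apply_scenario(base_config, spec), biomass)
    pixels = result.grid_result.pixels

    log.info("stage=reporting writing tables")
    outputs: dict[str, str] = {}

    def emit_csv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        _write_csv(path, frame)
        outputs[name] = _sha256_file(path)

    emit_csv("pixels.csv", pixels)
    emit_csv("national.csv", result.national)
    emit_csv("departments.csv", reporting.aggregate(pixels, "department"))
    emit_csv("municipalities.csv", reporting.aggregate(pixels, "municipality"))
    summary = reporting.summary_table(pixels, admin)
    emit_csv("summary.csv", summary)
    classes, freqs = reporting.classify_pixels(pixels["flux_tco2_km2_yr"])
    emit_csv(
        "classification.csv",
        pixels[["pixel_id", "period", "flux_tco2_km2_yr"]].assign(
            pixel_class=classes
        ),
    )
    emit_csv("curves.csv", curve_table(params.forest_types.values()))

    if config.get("scenarios") == "all":
        log.info("stage=scenarios running full sensitivity set")
        table = scenarios.run_all(grid, biomass, admin, base_config, init=init_cfg)
        emit_csv("scenarios.csv", table)

    summary_json = {
        "scenario": spec.name,
        "periods": {
            row["period"]: {
                "total_tco2": row["total_tco2"],
                "avg_annual_tco2": row["avg_annual_tco2"],
                "per_capita_tco2": row["per_capita_tco2"],
                "per_gdp_kg_bs": row["per_gdp_kg_bs"],
            }
            for row in summary.to_dict("records")
        },
        "pixel_class_frequencies": freqs,
    }
    path = outdir / "summary.json"
    _write_json(path, summary_json)
    outputs["summary.json"] = _sha256_file(path)

    manifest = {
        "config_hash": _sha256_text(config_text),
        "seed": seed,
        "input_digests": digests,
        "version": __version__,
        "outputs": outputs,
    }
    _write_json(outdir / "manifest.json", manifest)
    log.info("stage=done wrote %d outputs to %s", len(outputs), outdir)
    return manifest
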