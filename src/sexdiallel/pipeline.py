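"""Pipeline orchestration: simulate/load -> validate -> fit -> geometry -> ssdr.

Every run is reproducible from its config and seed alone; all numeric
tables are written in full double precision and the provenance block
records the config hash, seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import DiallelDataset, read_diallel_table, validate_dataset
from .reml import ModelSpec, RemlOptions, build_design, fit_reml
from .geometry import GeometryReport, geometry_report
from .simulate import SimulationConfig, generate_diallel
from .ssdr import SsdrResult, ssdr_statistics

log = logging.getLogger("sexdiallel")

ALL_STAGES = ("validate", "fit", "geometry", "ssdr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


@dataclass
class PipelineConfig:
    """Exactly one input source: a phenotype table or a simulation."""

    data_path: str | None = None
    simulation: SimulationConfig | None = None
    seed: int | None = None
    offset: float = 1.0
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str | None = None

    def __post_init__(self):
        if (self.data_path is None) == (self.simulation is None):
            raise ValueError("exactly one of data_path / simulation required")
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.simulation is not None and self.seed is not None:
            self.simulation = self.simulation.with_seed(self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        raw.update(overrides)
        return cls(simulation=sim, **raw)

    def digest(self) -> str:
        payload = {k: (v.__dict__ if isinstance(v, SimulationConfig) else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything a run produced, regenerable from config + seed."""

    config: PipelineConfig
    validation: object = None
    fit_full: object = None
    fit_male: object = None
    fit_female: object = None
    geometry: GeometryReport | None = None
    ssdr_baseline: SsdrResult | None = None
    ssdr_no_additive: SsdrResult | None = None
    dataset: DiallelDataset | None = None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.dataset is not None:
            self.dataset.to_csv(out / "data.csv")
        if self.validation is not None:
            v = self.validation
            pd.DataFrame({
                "metric": ["n_records", "missing_outcross", "missing_selfs",
                           "malformed_rows"],
                "value": [v.n_records, v.n_missing_outcross,
                          v.n_missing_selfs, len(v.malformed_rows)],
            }).to_csv(out / "validation.csv", index=False)
        for name, fit in (("full", self.fit_full), ("male", self.fit_male),
                          ("female", self.fit_female)):
            if fit is not None:
                fit.varcomp_table().to_csv(out / f"varcomp_{name}.csv",
                                           index=False)
                fit.fixed_tests.to_csv(out / f"fixed_{name}.csv", index=False)
        if self.geometry is not None:
            self.geometry.to_csv(out / "geometry.csv")
        for res in (self.ssdr_baseline, self.ssdr_no_additive):
            if res is not None:
                res.summary_frame().to_csv(out / f"ssdr_{res.variant}.csv",
                                           index=False)
                res.strain_frame().to_csv(
                    out / f"ssdr_{res.variant}_strains.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _load_input(config: PipelineConfig) -> DiallelDataset:
    if config.data_path is not None:
        return read_diallel_table(config.data_path)
    ds, _truth = generate_diallel(config.simulation)
    return ds


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the enabled stages in order; any failure aborts with a
    stage-tagged error."""
    bundle = ReportBundle(config=config)
    bundle.provenance = {
        "config_hash": config.digest(),
        "seed": config.seed if config.seed is not None
        else (config.simulation.seed if config.simulation else None),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    try:
        ds = _load_input(config)
    except Exception as err:  # noqa: BLE001 - stage context wanted
        raise PipelineError("input", err) from err
    bundle.dataset = ds

    opts = RemlOptions()
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "validate":
                bundle.validation = validate_dataset(ds)
            elif stage == "fit":
                bundle.fit_full = fit_reml(build_design(
                    ds, ModelSpec.full_sexed(offset=config.offset)), opts)
                log.info("full fit: loglik=%.4f converged=%s",
                         bundle.fit_full.loglik, bundle.fit_full.converged)
            elif stage == "geometry":
                if bundle.fit_full is None:
                    bundle.fit_full = fit_reml(build_design(
                        ds, ModelSpec.full_sexed(offset=config.offset)), opts)
                bundle.fit_male = fit_reml(build_design(
                    ds, ModelSpec.sex_specific("M", offset=config.offset)),
                    opts)
                bundle.fit_female = fit_reml(build_design(
                    ds, ModelSpec.sex_specific("F", offset=config.offset)),
                    opts)
                for f in (bundle.fit_male, bundle.fit_female):
                    log.info("%s fit: loglik=%.4f converged=%s",
                             f.model_id, f.loglik, f.converged)
                bundle.geometry = geometry_report(
                    bundle.fit_full, bundle.fit_male, bundle.fit_female)
            elif stage == "ssdr":
                bundle.ssdr_baseline = ssdr_statistics(
                    ds, remove_sc_additive=False, offset=config.offset)
                bundle.ssdr_no_additive = ssdr_statistics(
                    ds, remove_sc_additive=True, offset=config.offset)
        except Exception as err:  # noqa: BLE001
            raise PipelineError(stage, err) from err
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
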