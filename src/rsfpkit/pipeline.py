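"""Reproducible pipeline: simulate -> extract -> fit -> populations -> report.

A :class:`PipelineConfig` (validated with pydantic, loadable from YAML or
JSON) describes which stages run and with what parameters; every run writes
its resolved config, a manifest with config/input hashes and per-stage
status, and the stage artifacts (tidy trace CSVs, fit JSONs, amplitude and
fatigue CSVs) into one output directory.  Deterministic stages reproduce
byte-identical artifacts when re-run with the same config hash and inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as rio
from .experiment import SwitchingExperiment, SwitchingProtocol
from .extraction import extract_traces, segment_objects
from .kinetics import TwoStateKinetics, global_fit
from .populations import (
    PopulationDynamicsParams,
    fatigue_metrics,
    fit_population_dynamics,
    observed_stabilization,
)
from .spectroscopy import percent_change
from .synthetic import ColonyLayout, GroundTruth, NoiseModel, render_colony_stack, simulate_traces

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "compare_constructs"]


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cycles: int = 500
    on_periods: int = 25
    off_periods: int = 25
    period_duration: float = 0.1
    frame_exposure: Optional[float] = None
    trailing_on_periods: int = 0

    def build(self) -> SwitchingProtocol:
        return SwitchingProtocol(**self.model_dump())


class KineticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_A: float = 6.0
    k_B: float = 1.0
    f_A: float = 0.0
    f_B: float = 0.15
    c: float = 0.02
    k_on: Optional[float] = None

    def build(self) -> TwoStateKinetics:
        return TwoStateKinetics(**self.model_dump())


class PopDynConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_AB: float = 0.006
    k_dA: float = 0.004
    k_dB: float = 0.004
    a0: float = 1.0
    b0: float = 0.05
    k_BA: float = 0.0

    def build(self) -> PopulationDynamicsParams:
        return PopulationDynamicsParams(**self.model_dump())


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shot_scale: float = 1000.0
    read_sigma: float = 0.01
    background: float = 0.05

    def build(self) -> NoiseModel:
        return NoiseModel(**self.model_dump())


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    popdyn: PopDynConfig = Field(default_factory=PopDynConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    n_objects: int = 1


class ExtractConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    input_tiff: str
    protocol: ProtocolConfig
    method: str = "otsu"
    threshold: Optional[float] = None
    min_area: int = 5
    subtract_background: bool = True


class PipelineConfig(BaseModel):
    """Top-level run description; exactly one trace source must be enabled."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    simulate: Optional[SimulateConfig] = None
    extract: Optional[ExtractConfig] = None
    fit_switching: bool = True
    fit_populations: bool = True
    fatigue: bool = True

    @model_validator(mode="after")
    def _check_sources(self) -> "PipelineConfig":
        if self.simulate is not None and self.extract is not None:
            raise ValueError("enable either 'simulate' or 'extract', not both")
        if self.simulate is None and self.extract is None and (
            self.fit_switching or self.fit_populations or self.fatigue
        ):
            raise ValueError("fitting stages need a trace source: enable 'simulate' or 'extract'")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class RunManifest(BaseModel):
    started: str
    finished: str = ""
    config_hash: str
    input_hashes: dict = Field(default_factory=dict)
    stages: list = Field(default_factory=list)
    artifacts: dict = Field(default_factory=dict)

    def record(self, stage: str, status: str, detail: str = "", seconds: float = 0.0) -> None:
        self.stages.append(
            {"stage": stage, "status": status, "detail": detail, "seconds": round(seconds, 3)}
        )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the enabled stages in order, writing all artifacts to ``outdir``.

    Pre-run validation (schema, input existence) raises before any stage
    runs.  A stage failure is recorded in the manifest together with the
    completed stages' artifacts; dependent stages are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.extract is not None and not Path(config.extract.input_tiff).exists():
        raise FileNotFoundError(
            f"extraction input TIFF not found: {config.extract.input_tiff}"
        )

    manifest = RunManifest(
        started=time.strftime("%Y-%m-%dT%H:%M:%S"), config_hash=config.config_hash()
    )
    rio.write_json(config.model_dump(mode="json"), outdir / "config.json")
    manifest.artifacts["config"] = "config.json"

    experiment: SwitchingExperiment | None = None
    amplitudes = None

    def run_stage(name, fn):
        nonlocal experiment, amplitudes
        t0 = time.perf_counter()
        try:
            fn()
            manifest.record(name, "ok", seconds=time.perf_counter() - t0)
            return True
        except Exception as err:  # noqa: BLE001 — failures are part of the manifest
            manifest.record(
                name,
                "failed",
                detail=f"{err}\n{traceback.format_exc(limit=3)}",
                seconds=time.perf_counter() - t0,
            )
            return False

    ok = True
    if config.simulate is not None:

        def _simulate():
            nonlocal experiment
            sim = config.simulate
            truth = GroundTruth(
                kinetics=sim.kinetics.build(),
                popdyn=sim.popdyn.build(),
                noise=sim.noise.build(),
                seed=config.seed,
            )
            experiment = simulate_traces(sim.protocol.build(), truth, n_objects=sim.n_objects)
            rio.write_traces_csv(experiment, outdir / "traces.csv")
            manifest.artifacts["traces"] = "traces.csv"

        ok = run_stage("simulate", _simulate)

    if config.extract is not None:

        def _extract():
            nonlocal experiment
            ext = config.extract
            tiff = Path(ext.input_tiff)
            manifest.input_hashes[str(tiff)] = _hash_file(tiff)
            stack = rio.read_stack_tiff(tiff)
            proto = ext.protocol.build()
            reference = stack[proto.normalization_frame_index]
            objects = segment_objects(
                reference, method=ext.method, threshold=ext.threshold, min_area=ext.min_area
            )
            experiment = extract_traces(
                stack, objects, proto, subtract_background=ext.subtract_background
            )
            rio.write_traces_csv(experiment, outdir / "traces.csv")
            manifest.artifacts["traces"] = "traces.csv"

        ok = run_stage("extract", _extract)

    if config.fit_switching and ok:

        def _fit():
            nonlocal amplitudes
            kin, amps, result = global_fit(experiment)
            amplitudes = amps
            rio.write_json(
                {"kinetics": kin.to_dict(), "fit": result.to_dict()}, outdir / "kinetics.json"
            )
            amps.to_frame().to_csv(outdir / "amplitudes.csv", index=False)
            manifest.artifacts["kinetics"] = "kinetics.json"
            manifest.artifacts["amplitudes"] = "amplitudes.csv"

        ok = run_stage("fit_switching", _fit)

    if config.fit_populations and ok and amplitudes is not None:

        def _popdyn():
            params, result = fit_population_dynamics(amplitudes.a, amplitudes.b)
            rio.write_json(
                {"popdyn": params.to_dict(), "fit": result.to_dict()}, outdir / "popdyn.json"
            )
            manifest.artifacts["popdyn"] = "popdyn.json"

        ok = run_stage("fit_populations", _popdyn)

    if config.fatigue and ok and experiment is not None:

        def _fatigue():
            report = fatigue_metrics(experiment)
            report.to_frame().to_csv(outdir / "fatigue.csv", index=False)
            rio.write_json({"cycles_to_half": report.cycles_to_half}, outdir / "fatigue.json")
            manifest.artifacts["fatigue"] = "fatigue.csv"

        run_stage("fatigue", _fatigue)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    rio.write_json(manifest.model_dump(), outdir / "manifest.json")
    return manifest


def load_bundle(bundle_dir: str | Path) -> dict:
    """Load the artifacts of one pipeline run into a dict."""
    bundle_dir = Path(bundle_dir)
    out: dict = {"dir": str(bundle_dir)}
    kin = bundle_dir / "kinetics.json"
    if kin.exists():
        out["kinetics"] = rio.read_json(kin)["kinetics"]
    pop = bundle_dir / "popdyn.json"
    if pop.exists():
        out["popdyn"] = rio.read_json(pop)["popdyn"]
    fat = bundle_dir / "fatigue.json"
    if fat.exists():
        out["fatigue"] = rio.read_json(fat)
    return out


def compare_constructs(bundles: dict[str, dict], reference: str) -> pd.DataFrame:
    """Compare per-construct pipeline bundles against a reference construct.

    Reports off-switching rate ratios, percent changes of fatigue endurance
    (cycles to half on-level) and the observed fold-stabilization of the
    fast species (k_dA ratio).  Constructs missing a metric get NaN there.
    """
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles to compare")
    if reference not in bundles:
        raise ValueError(f"reference {reference!r} not among the bundles")
    ref = bundles[reference]
    rows = []
    for name, bundle in bundles.items():
        row: dict = {"construct": name}
        if "kinetics" in bundle and "kinetics" in ref:
            row["k_A"] = bundle["kinetics"]["k_A"]
            row["k_B"] = bundle["kinetics"]["k_B"]
            row["k_A_ratio_vs_ref"] = bundle["kinetics"]["k_A"] / ref["kinetics"]["k_A"]
        if "popdyn" in bundle and "popdyn" in ref:
            pd_b = PopulationDynamicsParams(**bundle["popdyn"])
            pd_r = PopulationDynamicsParams(**ref["popdyn"])
            row["k_dA"] = pd_b.k_dA
            row["fold_stabilization_vs_ref"] = observed_stabilization(pd_r, pd_b)[
                "fold_stabilization"
            ]
        if "fatigue" in bundle and "fatigue" in ref:
            c_b = bundle["fatigue"]["cycles_to_half"]
            c_r = ref["fatigue"]["cycles_to_half"]
            row["cycles_to_half"] = c_b
            if np.isfinite(c_b) and np.isfinite(c_r) and c_r > 0:
                row["cycles_to_half_change_pct"] = percent_change(c_r, c_b)
        rows.append(row)
    return pd.DataFrame(rows).set_index("construct")
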