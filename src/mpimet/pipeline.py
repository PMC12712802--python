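"""Staged pipeline: phantom -> simulate -> reconstruct -> calibrate ->
quantify -> cohort -> classify, with per-stage provenance.

Every artifact is stamped (manifest.json) with the configuration hash and
seed that produced it, and stages fail fast, naming the missing upstream
artifact, when run out of order. Reruns with the same configuration and
seeds reproduce CSV/JSON outputs byte-identically (volumes are written as
uncompressed .nii for the same reason: gzip embeds timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import volio
from .cohort import CohortSpec, generate_cohort, spec_4t1
from .diagnostics import classify_cohort
from .forward import ScannerConfig, TracerModel, config_hash, simulate_scan
from .phantoms import make_calibration_ladder, make_shine_through_phantom
from .quantify import LinearCalibration, roi_signal
from .recon import build_operator, reconstruct_map

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_demo_config"]

STAGE_ORDER = ("phantom", "simulate", "reconstruct", "calibrate",
               "quantify", "cohort", "classify")


class PipelineError(RuntimeError):
    """Raised when a stage cannot run; carries the offending stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Which stages to run, with what scanner, seeds and output directory."""

    output_dir: str = "mpimet_out"
    stages: tuple[str, ...] = STAGE_ORDER
    seed: int = 0
    scanner: ScannerConfig = field(default_factory=ScannerConfig)
    tracer: TracerModel = field(default_factory=TracerModel)
    cohort_spec: CohortSpec = field(default_factory=spec_4t1)
    calibration_masses_mg: tuple[float, ...] = (
        0.0, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)
    n_iter: int = 250
    n_bootstrap: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kw = dict(doc)
        if "scanner" in kw:
            kw["scanner"] = ScannerConfig.from_dict(kw["scanner"])
        if "tracer" in kw:
            kw["tracer"] = TracerModel(**kw["tracer"])
        if "cohort_spec" in kw:
            spec = dict(kw["cohort_spec"])
            rho = spec.pop("target_rho", {})
            spec["target_rho"] = {
                tuple(k.split(" vs ")) if isinstance(k, str) and " vs " in k else k: v
                for k, v in rho.items()}
            kw["cohort_spec"] = CohortSpec(**spec)
        for key in ("stages", "calibration_masses_mg"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def default_demo_config(output_dir: str, seed: int = 0) -> PipelineConfig:
    """A small end-to-end demonstration configuration (32 mm, 65 px grid)."""
    scanner = ScannerConfig(fov=(32.5, 32.5), grid=(65, 65), angles=(0.0, 90.0))
    cohort = spec_4t1(seed=seed)
    return PipelineConfig(
        output_dir=output_dir, seed=seed, scanner=scanner,
        cohort_spec=cohort,
        calibration_masses_mg=(0.0, 0.001, 0.005, 0.01, 0.05, 0.1),
        n_iter=60, n_bootstrap=300,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing artifact {path.name} "
                                   f"(produced by the '{producer}' stage)")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns {artifact name: path}."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError("config", f"unknown stages {sorted(unknown)}")
    chash = config_hash(config.scanner, config.tracer)
    artifacts: dict[str, Path] = {}
    manifest = {"config_hash": chash, "seed": config.seed, "stages": {}}

    scanner, tracer = config.scanner, config.tracer
    operator = None

    def get_operator():
        nonlocal operator
        if operator is None:
            operator = build_operator(tracer, scanner)
        return operator

    for stage in stages:
        logger.info("stage %s (config %s, seed %d)", stage, chash, config.seed)
        if stage == "phantom":
            phantom = make_shine_through_phantom(config=scanner)
            p = out / "phantom.nii"
            volio.write_volume(phantom, p)
            artifacts["phantom"] = p
        elif stage == "simulate":
            src = _require(out / "phantom.nii", stage, "phantom")
            phantom = volio.read_volume(src)
            sig = simulate_scan(phantom, tracer, scanner, seed=config.seed)
            p = out / "signal.npz"
            volio.write_signal(sig, p, sidecar=True)
            artifacts["signal"] = p
        elif stage == "reconstruct":
            src = _require(out / "signal.npz", stage, "simulate")
            sig = volio.read_signal(src)
            res = reconstruct_map(sig, get_operator(), n_iter=config.n_iter)
            p = out / "recon.nii"
            from .phantoms import VoxelPhantom
            volio.write_volume(VoxelPhantom(res.image,
                                            spacing=(scanner.spacing[1], scanner.spacing[0])), p)
            np.savetxt(out / "objective_trace.csv", res.objective_trace,
                       delimiter=",", header="objective", comments="")
            artifacts["recon"] = p
        elif stage == "calibrate":
            masses_mg = config.calibration_masses_mg
            op = get_operator()
            signals = []
            for m in masses_mg:
                ladder = make_calibration_ladder([m], config=scanner)[0]
                sig = simulate_scan(ladder, tracer, scanner, seed=config.seed)
                res = reconstruct_map(sig, op, n_iter=config.n_iter)
                signals.append(roi_signal(res.image).total_signal)
            cal = LinearCalibration(
                np.asarray(masses_mg) * 1e3, signals, config_hash=chash).fit()
            p = out / "calibration.json"
            cal.to_json(p)
            artifacts["calibration"] = p
        elif stage == "quantify":
            src = _require(out / "recon.nii", stage, "reconstruct")
            calp = _require(out / "calibration.json", stage, "calibrate")
            from .quantify import CalibrationResult, signal_to_iron
            image = volio.read_volume(src).concentration
            cal = CalibrationResult.from_json(calp)
            meas = roi_signal(image)
            iron = signal_to_iron(meas.total_signal, cal, image_config_hash=chash)
            p = out / "quantification.json"
            _write_json(p, {
                "total_signal": meas.total_signal,
                "mean_signal": meas.mean_signal,
                "n_pixels": meas.n_pixels,
                "iron_mass_ug": iron,
                "config_hash": chash,
            })
            artifacts["quantification"] = p
        elif stage == "cohort":
            table = generate_cohort(config.cohort_spec)
            p = out / "cohort.csv"
            table.to_csv(p, index=False)
            artifacts["cohort"] = p
        elif stage == "classify":
            src = _require(out / "cohort.csv", stage, "cohort")
            import pandas as pd
            table = pd.read_csv(src)
            cal = None
            calp = out / "calibration.json"
            if calp.exists():
                from .quantify import CalibrationResult
                cal = CalibrationResult.from_json(calp)
                if cal.slope <= 0:
                    cal = None
            report = classify_cohort(table, cal, n_iterations=config.n_bootstrap,
                                     seed=config.seed)
            p = out / "classification.json"
            _write_json(p, report.to_dict())
            (out / "classification.txt").write_text(report.summary() + "\n")
            artifacts["classification"] = p
        manifest["stages"][stage] = {
            "artifacts": sorted(str(artifacts[k].name) for k in artifacts),
            "seed": config.seed,
        }
    _write_json(out / "manifest.json", manifest)
    return artifacts
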