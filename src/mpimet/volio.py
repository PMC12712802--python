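"""Volume, signal and configuration IO.

Volumes travel as NIfTI (.nii/.nii.gz, via nibabel) or NRRD (via SimpleITK)
with voxel spacing preserved; round trips are lossless. 2D phantoms are
stored as single-slice 3D volumes and squeezed back to 2D on read.
Harmonic signals are saved as a single .npz carrying the arrays plus the
scanner/tracer configuration as an embedded JSON string (a human-readable
.json sidecar can be written alongside). Scanner/tracer configurations and
cohort specs read from YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .cohort import CohortSpec
from .forward import HarmonicSignal, ScannerConfig, TracerModel
from .phantoms import VoxelPhantom

__all__ = [
    "read_volume",
    "write_volume",
    "read_signal",
    "write_signal",
    "load_scanner_yaml",
    "dump_scanner_yaml",
    "load_cohort_spec_yaml",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_volume(volume, path) -> None:
    """Write a VoxelPhantom (or bare array + spacing 1 mm) to NIfTI/NRRD."""
    path = Path(path)
    if isinstance(volume, VoxelPhantom):
        data, spacing = volume.concentration, volume.spacing
    else:
        data = np.asarray(volume, dtype=float)
        spacing = (1.0,) * data.ndim
    if data.ndim == 2:
        data3 = data[np.newaxis, ...]          # single-slice 3D
        spacing3 = (1.0,) + tuple(spacing)
    else:
        data3, spacing3 = data, tuple(spacing)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        # nibabel is (i, j, k) fastest-first; keep array order and record
        # spacing in the affine so zooms survive the round trip
        affine = np.diag(list(spacing3[::-1]) + [1.0])
        img = nib.Nifti1Image(np.asarray(data3.T, dtype=np.float64), affine)
        nib.save(img, str(path))
    elif sfx in _NRRD_SUFFIXES:
        img = sitk.GetImageFromArray(data3)
        img.SetSpacing(tuple(float(s) for s in spacing3[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume extension '{sfx}' "
                         "(use .nii, .nii.gz or .nrrd)")


def read_volume(path) -> VoxelPhantom:
    """Read a volume; single-slice 3D collapses back to 2D."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=float).T
            spacing = tuple(float(z) for z in img.header.get_zooms()[::-1])
        except Exception as exc:  # corrupt header
            raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    elif sfx in _NRRD_SUFFIXES:
        try:
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).astype(float)
            spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
        except Exception as exc:
            raise ValueError(f"could not read NRRD volume {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported volume extension '{sfx}' "
                         "(use .nii, .nii.gz or .nrrd)")
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
        spacing = spacing[1:]
    return VoxelPhantom(np.ascontiguousarray(data), spacing=spacing)


# --------------------------------------------------------------------------
# harmonic signals
# --------------------------------------------------------------------------

def write_signal(signal: HarmonicSignal, path, sidecar: bool = False) -> None:
    """Save a HarmonicSignal as .npz with embedded JSON metadata."""
    path = Path(path)
    meta = {
        "config": signal.config.to_dict(),
        "tracer": dataclasses.asdict(signal.tracer),
        "noise_sd": signal.noise_sd,
        "seed": signal.seed,
    }
    np.savez(
        path,
        data=signal.data,
        sample_positions=signal.sample_positions,
        meta=np.array(json.dumps(meta, sort_keys=True)),
    )
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_signal(path) -> HarmonicSignal:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        config = ScannerConfig.from_dict(meta["config"])
        tracer = TracerModel(**meta["tracer"])
        return HarmonicSignal(
            data=z["data"],
            angles=config.angles,
            harmonics=config.harmonics,
            sample_positions=z["sample_positions"],
            config=config,
            tracer=tracer,
            noise_sd=meta["noise_sd"],
            seed=meta["seed"],
        )


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------

def load_scanner_yaml(path) -> tuple[ScannerConfig, TracerModel]:
    """Read a YAML file with optional 'scanner' and 'tracer' sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    config = ScannerConfig.from_dict(doc.get("scanner", {}))
    tracer = TracerModel(**doc.get("tracer", {}))
    return config, tracer


def dump_scanner_yaml(config: ScannerConfig, tracer: TracerModel, path) -> None:
    doc = {"scanner": config.to_dict(), "tracer": dataclasses.asdict(tracer)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_cohort_spec_yaml(path) -> CohortSpec:
    """Read a CohortSpec from YAML; target_rho keys may be 'a vs b' strings."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    rho = doc.pop("target_rho", {})
    parsed = {}
    for key, val in rho.items():
        if isinstance(key, str) and " vs " in key:
            a, b = key.split(" vs ", 1)
            parsed[(a.strip(), b.strip())] = float(val)
        else:
            parsed[key] = float(val)
    doc["target_rho"] = parsed
    return CohortSpec(**doc)
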