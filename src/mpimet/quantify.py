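"""Tracer quantification: calibration, ROI statistics, SNR, iron arithmetic.

MPI signal is linear in iron mass, so a ladder of known masses scanned under
fixed acquisition settings defines a straight line signal = slope*mass +
intercept; any summed-ROI signal measured under the *same* settings then
converts to micrograms of iron. Calibrations carry a configuration hash and
refuse to quantify images acquired under a different configuration, because
the arbitrary signal units change with drive amplitude.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ROIMeasurement",
    "CalibrationResult",
    "LinearCalibration",
    "roi_signal",
    "fit_calibration",
    "signal_to_iron",
    "snr",
    "dose_fraction",
    "pellet_iron",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


# --------------------------------------------------------------------------
# ROI statistics
# --------------------------------------------------------------------------

@dataclass
class ROIMeasurement:
    """Summed/mean/sd pixel statistics over a region of interest."""

    total_signal: float
    mean_signal: float
    sd_signal: float
    n_pixels: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("ROI must contain at least one pixel")


def roi_signal(image: np.ndarray, mask: np.ndarray | None = None,
               label: str = "") -> ROIMeasurement:
    """Summed scalar pixel values (and mean/sd) inside a mask.

    ``mask=None`` selects the whole grid — the full-area segmentation used
    for 2D organ scans (a 241 x 241 scan yields 58,081 pixels). The sd is
    the sample standard deviation (ddof=1; 0 for a single pixel).
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        values = image.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
        if not mask.any():
            raise ValueError("empty ROI mask")
        values = image[mask]
    n = values.size
    return ROIMeasurement(
        total_signal=float(values.sum()),
        mean_signal=float(values.mean()),
        sd_signal=float(values.std(ddof=1)) if n > 1 else 0.0,
        n_pixels=int(n),
        label=label,
    )


def snr(organ: ROIMeasurement, control: ROIMeasurement) -> float:
    """Signal-to-noise ratio (S_NP - S_PBS) / SD_PBS.

    ``organ`` is the tracer-injected organ's ROI, ``control`` the matched
    vehicle-injected organ. Undefined (raises) when the control sd is 0.
    """
    if control.sd_signal <= 0:
        raise ValueError("SNR undefined: control ROI has zero standard deviation")
    return (organ.mean_signal - control.mean_signal) / control.sd_signal


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Fitted signal-vs-iron line: signal [a.u.] = slope * mass [ug] + intercept."""

    slope: float
    intercept: float
    r_squared: float
    mass_range: tuple[float, float]
    config_hash: str | None = None
    n_points: int = 0

    def predict_signal(self, mass_ug) -> np.ndarray:
        return self.slope * np.asarray(mass_ug, dtype=float) + self.intercept

    def iron_mass(self, signal) -> float:
        """Invert the line; negative estimates are clipped to 0 with a warning."""
        return signal_to_iron(signal, self)

    def summary(self) -> str:
        lines = [
            "Linear signal-vs-iron calibration",
            f"  slope:      {self.slope:.6g} a.u./ugFe",
            f"  intercept:  {self.intercept:.6g} a.u.",
            f"  r^2:        {self.r_squared:.6f}",
            f"  mass range: {self.mass_range[0]:g} - {self.mass_range[1]:g} ugFe"
            f" ({self.n_points} points)",
        ]
        if self.config_hash:
            lines.append(f"  config:     {self.config_hash}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["mass_range"] = list(d["mass_range"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        d["mass_range"] = tuple(d["mass_range"])
        return cls(**d)


class LinearCalibration:
    """Model object for the signal-vs-mass calibration fit (OLS).

    Mirrors the usual model/results split: construct from the ladder data,
    call :meth:`fit` to obtain a :class:`CalibrationResult`.
    """

    def __init__(self, masses_ug, signals, config_hash: str | None = None):
        self.masses = np.asarray(masses_ug, dtype=float)
        self.signals = np.asarray(signals, dtype=float)
        if self.masses.shape != self.signals.shape or self.masses.ndim != 1:
            raise ValueError("masses and signals must be equal-length 1D sequences")
        if self.masses.size < 3:
            raise ValueError("calibration needs at least 3 points")
        if np.allclose(self.masses, self.masses[0]):
            raise ValueError("degenerate design: all masses are equal")
        self.config_hash = config_hash

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mass_col: str = "mass_ug",
                       signal_col: str = "signal", **kw) -> "LinearCalibration":
        return cls(df[mass_col].to_numpy(), df[signal_col].to_numpy(), **kw)

    def fit(self, force_zero_intercept: bool = False) -> CalibrationResult:
        m, s = self.masses, self.signals
        if force_zero_intercept:
            slope = float(m @ s) / float(m @ m)
            intercept = 0.0
            pred = slope * m
            ss_res = float(((s - pred) ** 2).sum())
            ss_tot = float(((s - s.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        elif np.allclose(s, s[0]):
            # constant signal (e.g. all-zero ladder): flat line, r^2 trivially 1
            slope, intercept, r2 = 0.0, float(s[0]), 1.0
        else:
            res = stats.linregress(m, s)
            slope, intercept = float(res.slope), float(res.intercept)
            r2 = float(res.rvalue**2)
        return CalibrationResult(
            slope=slope, intercept=intercept, r_squared=r2,
            mass_range=(float(m.min()), float(m.max())),
            config_hash=self.config_hash, n_points=int(m.size),
        )


def fit_calibration(masses_ug, signals, force_zero_intercept: bool = False,
                    config_hash: str | None = None) -> CalibrationResult:
    """OLS fit of signal = slope * mass + intercept (see LinearCalibration)."""
    return LinearCalibration(masses_ug, signals, config_hash).fit(force_zero_intercept)


def signal_to_iron(signal: float, cal: CalibrationResult,
                   image_config_hash: str | None = None) -> float:
    """Convert a summed MPI signal to iron mass in ugFe.

    (signal - intercept) / slope; negative estimates clip to 0 with a
    warning. If both the calibration and the image carry configuration
    hashes they must match — signal units are only comparable under the
    acquisition settings the calibration was measured with.
    """
    if cal.slope <= 0:
        raise ValueError("calibration slope must be > 0 to invert")
    if (image_config_hash is not None and cal.config_hash is not None
            and image_config_hash != cal.config_hash):
        raise ValueError(
            f"image acquired under config {image_config_hash} but calibration "
            f"belongs to config {cal.config_hash}"
        )
    mass = (float(signal) - cal.intercept) / cal.slope
    if mass < 0:
        warnings.warn(f"negative iron estimate {mass:.3g} ug clipped to 0",
                      stacklevel=2)
        return 0.0
    return mass


# --------------------------------------------------------------------------
# dose and per-cell arithmetic
# --------------------------------------------------------------------------

def dose_fraction(loaded_mass_mg: float, clinical_dose_mg: float = 510.0) -> float:
    """Loaded tracer as percent of a clinical iron dose, to 2 significant figures.

    E.g. 2.55 mg of a 510 mg dose -> 0.5%; 0.3 mg -> 0.059%.
    """
    if clinical_dose_mg <= 0:
        raise ValueError("clinical dose must be > 0")
    if loaded_mass_mg < 0:
        raise ValueError("loaded mass must be >= 0")
    return round_sig(100.0 * loaded_mass_mg / clinical_dose_mg, 2)


def pellet_iron(n_cells: float, per_cell_pg: float) -> float:
    """Total iron in a labelled cell pellet, ugFe to 3 significant figures.

    E.g. 14e6 cells at 0.96 pgFe/cell -> 13.4 ug; at 2.184 pg/cell -> 30.6 ug.
    """
    if n_cells < 0 or per_cell_pg < 0:
        raise ValueError("inputs must be nonnegative")
    return round_sig(n_cells * per_cell_pg * 1e-6, 3)
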