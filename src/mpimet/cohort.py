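"""Synthetic mouse cohorts with the study's statistical structure.

Each cohort row is one animal: tracer-injected metastatic mice whose lung
MPI signal scales with metastatic burden, tracer-injected mice without lung
metastasis whose lung signal is pure background, and un-injected (or
vehicle) controls. Burden covariates (tumor weight, lung nodule area,
F4/80+ macrophage count) are tied together through a shared lognormal
"severity" latent via a Gaussian copula, so rank (Spearman) correlations
between each covariate and the lung signal can be dialled to a target: for
a bivariate normal latent, rho_spearman = (6/pi) asin(r/2), inverted as
r = 2 sin(pi rho / 6).

Only rank correlations are targeted — the study reports no marginal
distributions — so the lognormal marginals here are a realism choice, not a
fit. The generated table is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math
import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "generate_cohort", "spec_4t1", "spec_huher2"]

COHORT_COLUMNS = [
    "animal_id", "cohort", "treatment", "metastasis", "lung_signal",
    "tumor_weight", "nodule_area", "macrophage_count",
]


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Counts: n_tracer_tumored metastatic tracer animals, n_tracer_nonmet
    tracer animals without lung metastasis (background lungs), n_control
    vehicle controls. Signals in arbitrary units (a.u.); nodule_area in mm2;
    tumor_weight in g. ``target_rho`` maps covariate names
    ("tumor_weight", "macrophage_count") to the desired Spearman correlation
    with lung_signal; the nodule_area-signal correlation is governed directly
    by signal_per_unit_burden versus noise_sd (it reaches 1 as noise -> 0).
    """

    name: str = "4T1"
    n_tracer_tumored: int = 10
    n_tracer_nonmet: int = 4
    n_control: int = 0
    background_mean: float = 15000.0
    background_sd: float = 3000.0
    signal_per_unit_burden: float = 4000.0  # a.u. per mm2 of nodule area
    noise_sd: float = 2000.0
    target_rho: dict = field(default_factory=dict)
    seed: int = 0
    # marginal shape parameters (median / lognormal sigma), realism only
    nodule_area_median: float = 5.0
    nodule_area_sigma: float = 0.8
    tumor_weight_median: float = 0.4
    tumor_weight_sigma: float = 0.5
    macrophage_median: float = 2000.0
    macrophage_sigma: float = 0.9
    macrophage_baseline: float = 150.0

    def __post_init__(self) -> None:
        for name in ("n_tracer_tumored", "n_tracer_nonmet", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("background_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for pair, rho in self.target_rho.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target rho for {pair} must lie in [-1, 1]")


def _copula_loading(rho_spearman: float) -> float:
    """Latent Gaussian correlation reproducing a Spearman target."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; deterministic given ``spec.seed``.

    Metastatic animals: severity z ~ N(0,1) drives nodule_area (lognormal),
    and lung_signal = background_mean + signal_per_unit_burden * nodule_area
    + N(0, noise_sd). Covariates with a target_rho entry share the latent
    through their copula loading. Non-metastatic and control animals draw
    lung_signal from the background distribution only and have zero nodule
    area. Signals are clipped at 0 (no negative summed images).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    n_met = spec.n_tracer_tumored
    z = rng.standard_normal(n_met)
    area = spec.nodule_area_median * np.exp(spec.nodule_area_sigma * z)
    signal = (spec.background_mean + spec.signal_per_unit_burden * area
              + spec.noise_sd * rng.standard_normal(n_met))

    def covariate(name, median, sigma, size, latent):
        rho = spec.target_rho.get((name, "lung_signal"), spec.target_rho.get(name))
        if rho is None:
            zc = rng.standard_normal(size)
        else:
            r = _copula_loading(rho)
            zc = r * latent + math.sqrt(1.0 - r * r) * rng.standard_normal(size)
        return median * np.exp(sigma * zc)

    weight = covariate("tumor_weight", spec.tumor_weight_median,
                       spec.tumor_weight_sigma, n_met, z)
    macro = covariate("macrophage_count", spec.macrophage_median,
                      spec.macrophage_sigma, n_met, z)
    for i in range(n_met):
        rows.append(dict(
            animal_id=f"{spec.name}-M{i + 1:02d}", cohort=spec.name,
            treatment="tracer", metastasis=True,
            lung_signal=max(0.0, float(signal[i])),
            tumor_weight=float(weight[i]),
            nodule_area=float(area[i]),
            macrophage_count=int(round(macro[i])),
        ))

    # tracer-injected animals without lung metastasis: background lungs,
    # tumored (they carry a primary tumor) but zero nodule area
    n_non = spec.n_tracer_nonmet
    bg = spec.background_mean + spec.background_sd * rng.standard_normal(n_non)
    w_non = spec.tumor_weight_median * np.exp(
        spec.tumor_weight_sigma * rng.standard_normal(n_non))
    m_non = spec.macrophage_baseline * np.exp(0.3 * rng.standard_normal(n_non))
    for i in range(n_non):
        rows.append(dict(
            animal_id=f"{spec.name}-N{i + 1:02d}", cohort=spec.name,
            treatment="tracer", metastasis=False,
            lung_signal=max(0.0, float(bg[i])),
            tumor_weight=float(w_non[i]),
            nodule_area=0.0,
            macrophage_count=int(round(m_non[i])),
        ))

    n_ctl = spec.n_control
    bg = spec.background_mean + spec.background_sd * rng.standard_normal(n_ctl)
    m_ctl = spec.macrophage_baseline * np.exp(0.3 * rng.standard_normal(n_ctl))
    for i in range(n_ctl):
        rows.append(dict(
            animal_id=f"{spec.name}-C{i + 1:02d}", cohort=spec.name,
            treatment="control", metastasis=False,
            lung_signal=max(0.0, float(bg[i])),
            tumor_weight=0.0,
            nodule_area=0.0,
            macrophage_count=int(round(m_ctl[i])),
        ))

    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def spec_4t1(seed: int = 0, **overrides) -> CohortSpec:
    """Syngeneic orthotopic cohort layout: 10 tracer metastatic + 4 tracer
    non-metastatic animals, rank-correlation targets from the reported
    tumor-weight (0.873) and macrophage (0.934) associations."""
    kw = dict(
        name="4T1", n_tracer_tumored=10, n_tracer_nonmet=4, n_control=0,
        target_rho={("tumor_weight", "lung_signal"): 0.873,
                    ("macrophage_count", "lung_signal"): 0.934},
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def spec_huher2(seed: int = 0, **overrides) -> CohortSpec:
    """Transgenic cohort layout: 11 tracer tumored animals (7 metastatic,
    4 without lung involvement) + 5 controls; weaker covariate coupling
    (0.892 weight, 0.515 macrophage) and more class overlap."""
    kw = dict(
        name="huHER2", n_tracer_tumored=7, n_tracer_nonmet=4, n_control=5,
        background_mean=20000.0, background_sd=8000.0,
        signal_per_unit_burden=9000.0, noise_sd=6000.0,
        nodule_area_median=3.0,
        target_rho={("tumor_weight", "lung_signal"): 0.892,
                    ("macrophage_count", "lung_signal"): 0.515},
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)
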