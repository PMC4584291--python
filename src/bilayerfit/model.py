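"""Parametric bilayer electron-density models with closed-form form factors.

The transverse structure of a fluid bilayer is modeled as mirrored Gaussian
component groups (PC and PE headgroups, carbonyl-glycerol, terminal methyl,
optionally a peptide) superposed on an error-function hydrocarbon slab, with
bulk water filling the volume the slab does not occupy:

    ρ(z) = ρ_W·(1 − s(z)) + ρ_HC·s(z) + Σ_g  A_g/(σ_g√(2π)) ·
           [exp(−(z−c_g)²/2σ_g²) + exp(−(z+c_g)²/2σ_g²)]

where s(z) is an indicator of the slab |z| < D_C smoothed by an interfacial
error function of width w.  Every term has an analytic Fourier transform, so
the model doubles as the exact oracle for the numerical density→form-factor
pipeline and as the ground truth behind the synthetic trajectory generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .density import DensityProfile
from .formfactor import (
    DELTA_BREAKPOINT,
    DELTA_HIGH,
    DELTA_LOW,
    FormFactor,
    assign_delta,
    find_lobes,
    lobe_maximum,
)

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)

#: Bulk water electron density at ~37 °C, e/Å³.
WATER_DENSITY = 0.333

#: Hydrocarbon volume per lipid, Å³, anchoring D_C = V_C / A_L for the
#: DOPC:DOPE (1:1) condition family (A_L = 66 Å² ↔ 2D_C = 29.5 Å).
HYDROCARBON_VOLUME = 973.5

#: Excess electrons of one Tat(47-57) peptide over the water it displaces:
#: ~838 electrons total, partial specific volume 0.73 cm³/g → ~1890 Å³
#: displacing ~630 water electrons.
PEPTIDE_EXCESS_ELECTRONS = 208.0


@dataclass(frozen=True)
class ComponentGaussian:
    """A mirrored Gaussian component group.

    ``areal_excess`` is the integrated excess electron density per unit area
    of one mirror copy (e/Å²); the component contributes identical Gaussians
    centered at ±``center``, making its density an even function of z.
    Negative ``areal_excess`` describes electron-poor groups such as the
    terminal-methyl trough.
    """

    label: str
    center: float
    width: float
    areal_excess: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.center < 0:
            raise ValueError("center must be non-negative (mirroring is implicit)")

    def density(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        amp = self.areal_excess / (self.width * _SQRT2PI)
        return amp * (
            np.exp(-((z - self.center) ** 2) / (2.0 * self.width**2))
            + np.exp(-((z + self.center) ** 2) / (2.0 * self.width**2))
        )

    def formfactor(self, qz: np.ndarray) -> np.ndarray:
        qz = np.asarray(qz, dtype=float)
        return (
            2.0
            * self.areal_excess
            * np.exp(-0.5 * self.width**2 * qz**2)
            * np.cos(qz * self.center)
        )


@dataclass(frozen=True)
class BilayerModel:
    """Gaussian components + hydrocarbon slab + complementary water fill."""

    gaussians: tuple[ComponentGaussian, ...] = ()
    hc_plateau: float = 0.30
    hc_halfwidth: float = 14.75
    hc_smoothing: float = 2.5
    water_density: float = WATER_DENSITY
    box_halfheight: float = 40.0

    def __post_init__(self):
        object.__setattr__(self, "gaussians", tuple(self.gaussians))
        if self.hc_plateau < 0:
            raise ValueError("hc_plateau must be non-negative")
        if self.hc_halfwidth <= 0:
            raise ValueError("hc_halfwidth must be positive")
        if self.hc_smoothing < 0:
            raise ValueError("hc_smoothing must be non-negative")
        if self.box_halfheight <= 0:
            raise ValueError("box_halfheight must be positive")

    # -- density -----------------------------------------------------------

    def slab_shape(self, z: np.ndarray) -> np.ndarray:
        """Smoothed indicator of the hydrocarbon slab, 1 in the core → 0 outside."""
        z = np.asarray(z, dtype=float)
        d, w = self.hc_halfwidth, self.hc_smoothing
        if w == 0.0:
            inside = (np.abs(z) < d).astype(float)
            return np.where(np.abs(z) == d, 0.5, inside)
        return 0.5 * (erf((d - z) / (_SQRT2 * w)) + erf((d + z) / (_SQRT2 * w)))

    def component_density(self, z: np.ndarray) -> dict[str, np.ndarray]:
        """Per-component densities on ``z``, including the water fill."""
        z = np.asarray(z, dtype=float)
        s = self.slab_shape(z)
        out: dict[str, np.ndarray] = {}
        for g in self.gaussians:
            d = g.density(z)
            out[g.label] = out[g.label] + d if g.label in out else d
        out["CH2"] = out.get("CH2", 0.0) + self.hc_plateau * s
        out["water"] = self.water_density * (1.0 - s)
        return out

    def total_density(self, z: np.ndarray) -> np.ndarray:
        comps = self.component_density(z)
        return np.sum(list(comps.values()), axis=0)

    # -- form factor -------------------------------------------------------

    def formfactor_values(self, qz: np.ndarray) -> np.ndarray:
        """Signed F(qz): analytic transform of ρ(z) − ρ_W."""
        qz = np.asarray(qz, dtype=float)
        d, w = self.hc_halfwidth, self.hc_smoothing
        # 2·(ρ_HC − ρ_W)·sin(qz·D_C)/qz, Gaussian-smoothed; sinc handles qz = 0.
        slab = (
            2.0
            * (self.hc_plateau - self.water_density)
            * d
            * np.sinc(qz * d / np.pi)
            * np.exp(-0.5 * w**2 * qz**2)
        )
        f = slab.astype(float)
        for g in self.gaussians:
            f = f + g.formfactor(qz)
        return f

    def areal_electron_excess(self) -> float:
        """F(0): integrated electron excess over water per unit area, e/Å²."""
        return float(self.formfactor_values(np.array([0.0]))[0])


def model_density(model: BilayerModel, grid: np.ndarray) -> dict[str, DensityProfile]:
    """Evaluate per-component and total density profiles on a uniform grid.

    The grid must span the simulation box [−Lz/2, +Lz/2]; the returned dict
    contains one profile per component plus ``"water"`` and ``"total"``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with at least two points")
    dz = grid[1] - grid[0]
    h = model.box_halfheight
    if grid[0] > -h + dz or grid[-1] < h - dz:
        raise ValueError("grid does not cover the box [-box_halfheight, +box_halfheight]")
    comps = model.component_density(grid)
    out = {
        lbl: DensityProfile(grid, vals, weighting="electron", component=lbl)
        for lbl, vals in comps.items()
    }
    out["total"] = DensityProfile(
        grid, model.total_density(grid), weighting="electron", component="total"
    )
    return out


def model_formfactor(model: BilayerModel, qz: np.ndarray) -> FormFactor:
    """Closed-form |F(qz)| of the model, absolute e/Å² units."""
    qz = np.asarray(qz, dtype=float)
    if np.any(qz < 0):
        raise ValueError("qz must be non-negative")
    return FormFactor(qz, np.abs(model.formfactor_values(qz)), scale_status="absolute")


def synthesize_experiment(
    model: BilayerModel,
    qz: np.ndarray,
    noise_seed: int = 0,
    arbitrary_scale: float = 1.0,
    noise_level: float = 1.0,
    breakpoint: float = DELTA_BREAKPOINT,
    delta_low: float = DELTA_LOW,
    delta_high: float = DELTA_HIGH,
    minimum_threshold_fraction: float = 0.2,
) -> FormFactor:
    """Generate a noisy, arbitrarily scaled "experimental" form factor.

    Gaussian noise with standard deviation Δ(qz) (the experimental error
    model) is applied in lobe-2-normalized units — i.e. with absolute
    magnitude Δ(qz)·max(lobe-2 |F|) — clipped at zero, then everything is
    multiplied by ``arbitrary_scale``.  The recorded Δ is expressed in the
    same output units so downstream χ² fitting is scale-consistent.
    ``noise_level`` multiplies the noise standard deviation (0 → noiseless).
    """
    if arbitrary_scale <= 0:
        raise ValueError("arbitrary_scale must be positive")
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    ff = model_formfactor(model, qz)
    lobes = find_lobes(ff, minimum_threshold_fraction)
    l2max = lobe_maximum(ff, lobes, 2)
    delta_norm = assign_delta(ff.qz, breakpoint, delta_low, delta_high)
    rng = np.random.default_rng(noise_seed)
    eps = rng.normal(0.0, 1.0, size=ff.qz.size) * delta_norm * noise_level
    amp = arbitrary_scale * np.maximum(0.0, ff.amplitude + eps * l2max)
    delta = arbitrary_scale * l2max * delta_norm
    return FormFactor(ff.qz, amp, delta=delta, scale_status="arbitrary")


def condition_model(
    area_per_lipid: float,
    peptide_depth: float | None = None,
    n_peptides: int = 2,
    n_lipids: int = 128,
    hydrocarbon_volume: float = HYDROCARBON_VOLUME,
    peptide_excess_electrons: float = PEPTIDE_EXCESS_ELECTRONS,
    water_density: float = WATER_DENSITY,
    box_halfheight: float = 40.0,
) -> BilayerModel:
    """Build the DOPC:DOPE (1:1) model for one (z, A_L) simulation condition.

    The hydrocarbon half-thickness follows volume conservation,
    D_C = V_C / A_L, so compressing the bilayer laterally thickens it and
    vice versa.  Headgroup Gaussians sit at fixed offsets above the
    hydrocarbon boundary, with the PC peak 2 Å further from the bilayer
    center than PE.  An optional peptide component is a mirrored Gaussian at
    ±``peptide_depth`` whose areal excess scales with the number of peptides
    per leaflet.
    """
    if area_per_lipid <= 0:
        raise ValueError("area_per_lipid must be positive")
    d_c = hydrocarbon_volume / area_per_lipid
    gaussians = [
        ComponentGaussian("PC-head", d_c + 4.9, 3.0, 0.35),
        ComponentGaussian("PE-head", d_c + 2.9, 3.0, 0.35),
        ComponentGaussian("CG", d_c + 1.0, 2.5, 0.15),
        ComponentGaussian("CH3", 0.0, 2.5, -0.15),
    ]
    if peptide_depth is not None:
        if n_peptides <= 0 or n_peptides % 2 != 0:
            raise ValueError("n_peptides must be a positive even number")
        area = (n_lipids / 2) * area_per_lipid
        areal = (n_peptides / 2) * peptide_excess_electrons / area
        gaussians.append(ComponentGaussian("peptide", abs(peptide_depth), 3.5, areal))
    return BilayerModel(
        gaussians=tuple(gaussians),
        hc_plateau=0.30,
        hc_halfwidth=d_c,
        hc_smoothing=2.5,
        water_density=water_density,
        box_halfheight=box_halfheight,
    )
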