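"""Form factors |F(qz)| and scattering-lobe structure.

The bilayer form factor is the cosine transform of the water-subtracted,
symmetrized electron density profile,

    F(qz) = ∫ (ρ(z) − ρ_W) cos(qz·z) dz ,

expressed in e/Å².  Diffuse-scattering experiments determine |F| only up to
an unknown overall scale, so experimental curves are normalized such that the
maximum of the second scattering lobe equals one, and per-point uncertainties
Δ are assigned in those normalized units (0.05 below qz = 0.6 Å⁻¹, 0.1 above).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .density import DensityProfile

SCALE_STATUSES = ("absolute", "arbitrary", "lobe2_normalized")

#: Default qz breakpoint (Å⁻¹) and Δ values of the experimental error model.
DELTA_BREAKPOINT = 0.6
DELTA_LOW = 0.05
DELTA_HIGH = 0.1


@dataclass(frozen=True)
class FormFactor:
    """|F| sampled on an ascending qz grid.

    ``delta`` holds optional per-point experimental uncertainties (same units
    as ``amplitude``).  ``scale_status`` records whether the amplitudes are in
    absolute e/Å² units, on an arbitrary experimental scale, or normalized to
    a lobe-2 maximum of one.
    """

    qz: np.ndarray
    amplitude: np.ndarray
    delta: np.ndarray | None = None
    scale_status: str = "absolute"

    def __post_init__(self):
        q = np.asarray(self.qz, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if q.ndim != 1 or q.shape != a.shape:
            raise ValueError("qz and amplitude must be 1-D arrays of equal length")
        if np.any(np.diff(q) <= 0):
            raise ValueError("qz must be strictly ascending")
        if np.any(a < 0):
            raise ValueError("amplitude must be non-negative")
        d = self.delta
        if d is not None:
            d = np.asarray(d, dtype=float)
            if d.shape != q.shape:
                raise ValueError("delta must match qz in length")
            if np.any(d <= 0):
                raise ValueError("delta must be positive")
        if self.scale_status not in SCALE_STATUSES:
            raise ValueError(f"scale_status must be one of {SCALE_STATUSES}")
        object.__setattr__(self, "qz", q)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "delta", d)

    def __len__(self) -> int:
        return self.qz.size


@dataclass(frozen=True)
class LobeStructure:
    """Numbered scattering lobes and the minima separating them.

    ``minima_qz`` are the inter-lobe minima (M1, M2, ...) in ascending qz;
    ``lobe_intervals`` are the (lo, hi) qz intervals of lobes L1, L2, ...,
    including the leading interval below M1 (lobe 1, possibly truncated by
    the low-qz data cutoff) and the trailing interval above the last minimum.
    """

    minima_qz: tuple[float, ...]
    lobe_intervals: tuple[tuple[float, float], ...]


def default_qz_grid(qz_max: float = 0.8, step: float = 0.005) -> np.ndarray:
    """Fixed simulation-side qz grid covering lobes L1-L4 (0 to 0.8 Å⁻¹)."""
    n = int(round(qz_max / step))
    return np.linspace(0.0, qz_max, n + 1)


def experimental_qz_grid(
    qz_min: float = 0.1, qz_max: float = 0.8, step: float = 0.005
) -> np.ndarray:
    """Experimental-style qz grid.

    Diffuse data are cut off below the beamstop, so the grid starts above the
    model form factor's low-q zero; the leading truncated interval is then
    numbered lobe 1, matching the experimental convention.
    """
    n = int(round((qz_max - qz_min) / step))
    return np.linspace(qz_min, qz_max, n + 1)


def fourier_transform(
    profile: DensityProfile, water_density: float, qz: np.ndarray
) -> FormFactor:
    """Cosine-transform a symmetrized density profile into |F(qz)|.

    Trapezoid quadrature of (ρ(z) − ρ_W)·cos(qz·z) over the profile's grid,
    which must be symmetric about z = 0.  Returns amplitudes in e/Å² with
    scale status ``"absolute"``.
    """
    if not profile.is_symmetric_grid():
        raise ValueError("profile grid is not symmetric about z = 0")
    qz = np.asarray(qz, dtype=float)
    z = profile.bin_centers
    contrast = profile.values - water_density
    integrand = contrast[None, :] * np.cos(np.outer(qz, z))
    f = np.trapezoid(integrand, z, axis=1)
    return FormFactor(qz, np.abs(f), scale_status="absolute")


def find_lobes(ff: FormFactor, minimum_threshold_fraction: float = 0.2) -> LobeStructure:
    """Locate inter-lobe minima and number the lobes between them.

    Minima are interior local minima whose amplitude falls below
    ``minimum_threshold_fraction`` of the global maximum (diffuse data never
    reach exact zeros).  At least two qualifying minima are required.
    """
    a = ff.amplitude
    threshold = minimum_threshold_fraction * np.max(a)
    idx, _ = find_peaks(-a)
    idx = idx[a[idx] < threshold]
    if idx.size < 2:
        raise ValueError(
            f"found {idx.size} qualifying minima below "
            f"{minimum_threshold_fraction:g} of the maximum; need at least 2"
        )
    minima = tuple(float(q) for q in ff.qz[idx])
    bounds = (float(ff.qz[0]),) + minima + (float(ff.qz[-1]),)
    intervals = tuple((bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
    return LobeStructure(minima_qz=minima, lobe_intervals=intervals)


def lobe_maximum(ff: FormFactor, lobes: LobeStructure, lobe_number: int) -> float:
    """Maximum |F| within lobe ``lobe_number`` (1-based)."""
    lo, hi = lobes.lobe_intervals[lobe_number - 1]
    mask = (ff.qz >= lo) & (ff.qz <= hi)
    return float(np.max(ff.amplitude[mask]))


def assign_delta(
    qz: np.ndarray,
    breakpoint: float = DELTA_BREAKPOINT,
    low: float = DELTA_LOW,
    high: float = DELTA_HIGH,
) -> np.ndarray:
    """Per-point Δ: ``low`` for qz < breakpoint, ``high`` for qz ≥ breakpoint."""
    qz = np.asarray(qz, dtype=float)
    return np.where(qz < breakpoint, low, high)


def normalize_experimental(
    ff: FormFactor,
    minimum_threshold_fraction: float = 0.2,
    breakpoint: float = DELTA_BREAKPOINT,
    delta_low: float = DELTA_LOW,
    delta_high: float = DELTA_HIGH,
) -> FormFactor:
    """Scale an experimental curve so the lobe-2 maximum equals one and
    populate Δ by the qz-threshold rule."""
    lobes = find_lobes(ff, minimum_threshold_fraction)
    l2max = lobe_maximum(ff, lobes, 2)
    delta = assign_delta(ff.qz, breakpoint, delta_low, delta_high)
    return FormFactor(
        ff.qz, ff.amplitude / l2max, delta=delta, scale_status="lobe2_normalized"
    )


@dataclass(frozen=True)
class MinimaShift:
    """Per-minimum qz shifts of a perturbed lobe structure vs a reference."""

    delta_qz: tuple[float, ...]
    label: str  # "thinning" | "thickening" | "none"


def minima_shift(reference: LobeStructure, perturbed: LobeStructure) -> MinimaShift:
    """Shift of each minimum, perturbed − reference, up to the shared count.

    A mean shift to higher qz indicates bilayer thinning; to lower qz,
    thickening.
    """
    n = min(len(reference.minima_qz), len(perturbed.minima_qz))
    if n == 0:
        raise ValueError("empty lobe structures")
    dq = tuple(perturbed.minima_qz[i] - reference.minima_qz[i] for i in range(n))
    mean = float(np.mean(dq))
    if mean > 0:
        label = "thinning"
    elif mean < 0:
        label = "thickening"
    else:
        label = "none"
    return MinimaShift(delta_qz=dq, label=label)
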