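"""Density profiles along the bilayer normal.

Converts bead trajectories into per-component electron or mass density
profiles ρ(z), with per-frame recentering of the bilayer (hydrocarbon center
of mass moved to z = 0 under periodic wrap), time averaging over the analysis
window, and symmetrization about the bilayer center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Component labels treated as hydrocarbon-chain material for centering.
HYDROCARBON_LABELS = ("CH2", "CH3")


@dataclass(frozen=True)
class DensityProfile:
    """A binned density profile along z.

    Parameters
    ----------
    bin_centers : ndarray
        Uniform, ascending bin centers in Å.
    values : ndarray
        Density per bin, e/Å³ (electron weighting) or amu/Å³ (mass weighting).
    weighting : str
        ``"electron"`` or ``"mass"``.
    component : str
        Component label, or ``"total"``.
    n_frames : int
        Number of trajectory frames averaged (1 for analytic profiles).
    """

    bin_centers: np.ndarray
    values: np.ndarray
    weighting: str = "electron"
    component: str = "total"
    n_frames: int = 1

    def __post_init__(self):
        z = np.asarray(self.bin_centers, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("profile needs at least two bins")
        if v.shape != z.shape:
            raise ValueError("bin_centers and values must have equal length")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValueError("bin_centers must be strictly ascending")
        if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-9):
            raise ValueError("bin spacing must be uniform")
        object.__setattr__(self, "bin_centers", z)
        object.__setattr__(self, "values", v)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def is_symmetric_grid(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.bin_centers + self.bin_centers[::-1], 0.0, atol=atol))


def _component_mask(component: np.ndarray, labels: Iterable[str]) -> np.ndarray:
    labels = tuple(labels)
    return np.isin(component, labels)


def recenter_frame(frame, box: Sequence[float]):
    """Translate a frame so the hydrocarbon center of mass sits at z = 0.

    The center of mass of CH2+CH3 beads is located with a circular mean along
    the periodic z dimension (robust to bilayers wrapped across the boundary),
    all bead z coordinates are shifted, and then wrapped back into
    [-Lz/2, Lz/2).  Transverse coordinates are untouched.
    """
    lz = float(box[2])
    mask = _component_mask(frame.component, HYDROCARBON_LABELS)
    if not np.any(mask):
        raise ValueError("frame contains no hydrocarbon (CH2/CH3) beads to center on")
    w = frame.mass[mask]
    theta = 2.0 * np.pi * frame.z[mask] / lz
    s = np.average(np.sin(theta), weights=w)
    c = np.average(np.cos(theta), weights=w)
    center = np.arctan2(s, c) * lz / (2.0 * np.pi)
    znew = frame.z - center
    znew = (znew + lz / 2.0) % lz - lz / 2.0
    return replace(frame, z=znew)


def _analysis_frames(frames: Sequence, equilibration_fraction: float) -> Sequence:
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    start = int(np.floor(equilibration_fraction * len(frames)))
    retained = frames[start:]
    if len(retained) == 0:
        raise ValueError("no frames remain after discarding equilibration")
    return retained


def bin_density(
    traj,
    bin_width: float = 0.25,
    weighting: str = "electron",
    components: Sequence[str] | None = None,
    equilibration_fraction: float = 0.5,
    recenter: bool = True,
) -> dict[str, DensityProfile]:
    """Histogram a trajectory into per-component density profiles.

    Each bead's electrons (or mass) is accumulated into the z bin containing
    its recentered coordinate and divided by the bin volume Lx·Ly·bin_width;
    profiles are averaged over the retained (post-equilibration) frames.
    Returns a dict keyed by component label plus ``"total"`` (the bin-wise sum
    over the selected components).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if weighting not in ("electron", "mass"):
        raise ValueError("weighting must be 'electron' or 'mass'")
    lx, ly, lz = (float(b) for b in traj.box)
    frames = _analysis_frames(traj.frames, equilibration_fraction)

    n_half = int(np.ceil(lz / 2.0 / bin_width))
    edges = np.arange(-n_half, n_half + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    volume = lx * ly * bin_width

    present = sorted({lbl for f in frames for lbl in np.unique(f.component)})
    if components is None:
        selected = present
    else:
        selected = list(components)
        if len(selected) == 0:
            raise ValueError("empty component selection")
        missing = [c for c in selected if c not in present]
        if missing:
            raise ValueError(f"components not present in trajectory: {missing}")

    acc = {lbl: np.zeros(centers.size) for lbl in selected}
    for frame in frames:
        f = recenter_frame(frame, traj.box) if recenter else frame
        w = f.electrons if weighting == "electron" else f.mass
        for lbl in selected:
            m = f.component == lbl
            if np.any(m):
                hist, _ = np.histogram(f.z[m], bins=edges, weights=w[m])
                acc[lbl] += hist

    nf = len(frames)
    out: dict[str, DensityProfile] = {}
    total = np.zeros(centers.size)
    for lbl in selected:
        vals = acc[lbl] / (volume * nf)
        total += vals
        out[lbl] = DensityProfile(centers, vals, weighting=weighting, component=lbl, n_frames=nf)
    out["total"] = DensityProfile(centers, total, weighting=weighting, component="total", n_frames=nf)
    return out


def symmetrize(profile: DensityProfile) -> DensityProfile:
    """Average the profile with its mirror image: (ρ(z) + ρ(-z)) / 2.

    Requires a bin grid symmetric about z = 0; idempotent.
    """
    if not profile.is_symmetric_grid():
        raise ValueError("bin grid is not symmetric about z = 0")
    vals = 0.5 * (profile.values + profile.values[::-1])
    return replace(profile, values=vals)


def peak_density(profile: DensityProfile) -> tuple[float, float]:
    """Return (maximum density, z at maximum); ties broken toward smaller |z|."""
    v = profile.values
    if v.size == 0:
        raise ValueError("empty profile")
    vmax = np.max(v)
    candidates = np.flatnonzero(v == vmax)
    z = profile.bin_centers[candidates]
    best = candidates[np.argmin(np.abs(z))]
    return float(vmax), float(profile.bin_centers[best])
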