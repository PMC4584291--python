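"""Toy bead trajectories standing in for restrained peptide-bilayer MD.

A trajectory is an ordered list of frames of labeled beads in a box whose
transverse dimensions are fixed by the prescribed area per lipid
(Lx·Ly = n_lipids/2 · A_L, the NpAT constraint).  Bead z positions are drawn
frame by frame from the component densities of a :class:`~bilayerfit.model.
BilayerModel`; peptides are bead clusters whose center of mass jitters by
σ = 1 Å per frame around the prescribed depth ±z, emulating a stiff harmonic
depth restraint; an optional single-mode sinusoidal undulation
u(x) = A·sin(2πx/Lx) displaces all beads, reproducing the mechanism by which
bilayer bending satisfies a global depth restraint while smearing the
density profile.

Serialization is JSON-lines (one metadata line, then one frame per line) and
is transparently gzipped for ``.gz`` paths.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterator

import numpy as np

from .model import BilayerModel, condition_model

#: amu per (excess) electron used to assign bead masses, by component.
MASS_PER_ELECTRON = {
    "water": 1.80,  # H2O: 18 amu / 10 e
    "CH2": 1.75,  # 14 amu / 8 e
    "CH3": 1.88,  # 15 amu / 8 e
    "PC-head": 2.0,
    "PE-head": 2.0,
    "CG": 2.0,
    "peptide": 1.86,  # Tat(47-57): ~1560 amu / ~838 e
    "ion": 1.97,  # Cl-: 35.45 amu / 18 e
}

_FRAME_FIELDS = ("x", "y", "z", "electrons", "mass", "component", "leaflet", "mol")


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: parallel arrays over beads."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    electrons: np.ndarray
    mass: np.ndarray
    component: np.ndarray  # str labels
    leaflet: np.ndarray  # "upper" | "lower" | "none"
    mol: np.ndarray  # molecule id (peptide index), -1 elsewhere

    def __post_init__(self):
        n = self.x.size
        for name in _FRAME_FIELDS:
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"frame field {name!r} has inconsistent length")

    @property
    def n_beads(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class ToyTrajectory:
    frames: tuple[Frame, ...]
    box: tuple[float, float, float]  # Lx, Ly, Lz in Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        object.__setattr__(self, "box", tuple(float(b) for b in self.box))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    # -- serialization -----------------------------------------------------

    def to_jsonl(self, path) -> None:
        with _open_text(path, "wt") as fh:
            header = {"box": list(self.box), "metadata": self.metadata}
            fh.write(json.dumps(header) + "\n")
            for frame in self.frames:
                rec = {
                    "x": frame.x.tolist(),
                    "y": frame.y.tolist(),
                    "z": frame.z.tolist(),
                    "electrons": frame.electrons.tolist(),
                    "mass": frame.mass.tolist(),
                    "component": frame.component.tolist(),
                    "leaflet": frame.leaflet.tolist(),
                    "mol": frame.mol.tolist(),
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ToyTrajectory":
        with _open_text(path, "rt") as fh:
            header = json.loads(fh.readline())
            frames = []
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                frames.append(
                    Frame(
                        x=np.asarray(rec["x"], dtype=float),
                        y=np.asarray(rec["y"], dtype=float),
                        z=np.asarray(rec["z"], dtype=float),
                        electrons=np.asarray(rec["electrons"], dtype=float),
                        mass=np.asarray(rec["mass"], dtype=float),
                        component=np.asarray(rec["component"], dtype=object),
                        leaflet=np.asarray(rec["leaflet"], dtype=object),
                        mol=np.asarray(rec["mol"], dtype=int),
                    )
                )
        return cls(frames=tuple(frames), box=tuple(header["box"]), metadata=header["metadata"])


def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Conditions of one toy simulation.

    Defaults mirror the reference study conditions: a 128-lipid
    DOPC:DOPE (1:1) bilayer, optionally with peptides restrained at depth
    ±``peptide_depth`` (one peptide mole fraction unit = 2 peptides), eight
    chloride counterions per peptide, and a fixed transverse box set by
    ``area_per_lipid``.
    """

    n_lipids: int = 128
    n_peptides: int = 0
    area_per_lipid: float = 68.0
    peptide_depth: float = 18.0
    undulation_amplitude: float = 0.0
    n_ions: int | None = None  # default: 8 per peptide (Tat charge +8)
    n_frames: int = 40
    beads_per_lipid: dict = field(
        default_factory=lambda: {"PC-head": 2, "PE-head": 2, "CG": 2, "chain": 10, "water": 12}
    )
    peptide_beads: int = 12
    model: BilayerModel | None = None

    def resolved_ions(self) -> int:
        return 8 * self.n_peptides if self.n_ions is None else self.n_ions

    def resolved_model(self) -> BilayerModel:
        if self.model is not None:
            return self.model
        depth = self.peptide_depth if self.n_peptides > 0 else None
        return condition_model(
            self.area_per_lipid,
            peptide_depth=depth,
            n_peptides=max(self.n_peptides, 2),
            n_lipids=self.n_lipids,
        )


class _ShapeSampler:
    """Inverse-CDF sampler for a non-negative density shape on a z grid."""

    def __init__(self, z: np.ndarray, shape: np.ndarray):
        if np.any(shape < -1e-12):
            raise ValueError("density shape must be non-negative")
        shape = np.clip(shape, 0.0, None)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (shape[1:] + shape[:-1]) * np.diff(z))])
        self.integral = float(cdf[-1])
        if self.integral <= 0:
            raise ValueError("density shape integrates to zero")
        self.z = z
        self.cdf = cdf / self.integral

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self.cdf, self.z)


def generate_trajectory(config: TrajectoryConfig, seed: int = 0) -> ToyTrajectory:
    """Generate a seeded, reproducible toy trajectory for one condition.

    Bead z positions are drawn per frame from the condition model's component
    densities (headgroup/CG Gaussians per leaflet, the combined hydrocarbon
    chain density, the complementary water fill); bead weights carry the
    component's integrated (excess) electrons so that histogramming converges
    to the model density.  Identical ``(config, seed)`` pairs give
    bit-identical trajectories.
    """
    if config.area_per_lipid <= 0:
        raise ValueError("area_per_lipid must be positive")
    if config.undulation_amplitude < 0:
        raise ValueError("undulation_amplitude must be non-negative")
    if config.n_lipids <= 0 or config.n_lipids % 2 != 0:
        raise ValueError("n_lipids must be a positive even number")
    if config.n_frames <= 0:
        raise ValueError("n_frames must be positive")

    rng = np.random.default_rng(seed)
    model = config.resolved_model()
    area = (config.n_lipids / 2) * config.area_per_lipid
    lx = ly = math.sqrt(area)
    lz = 2.0 * model.box_halfheight

    zgrid = np.linspace(-model.box_halfheight, model.box_halfheight, 3201)
    slab = model.slab_shape(zgrid)
    gaussians = {g.label: g for g in model.gaussians}

    # Combined chain density: slab plateau plus the (negative) CH3 trough.
    chain_shape = model.hc_plateau * slab
    ch3 = gaussians.get("CH3")
    if ch3 is not None:
        chain_shape = chain_shape + ch3.density(zgrid)
    if np.any(chain_shape < -1e-9 * np.max(chain_shape)):
        raise ValueError("combined hydrocarbon density is negative; CH3 trough too deep")
    chain_shape = np.clip(chain_shape, 0.0, None)
    chain_sampler = _ShapeSampler(zgrid, chain_shape)
    water_sampler = _ShapeSampler(zgrid, model.water_density * (1.0 - slab))

    head_labels = [lbl for lbl in gaussians if lbl not in ("CH3", "peptide")]
    n_ions = config.resolved_ions()

    counts = config.beads_per_lipid
    n_chain = counts["chain"] * config.n_lipids
    n_water = counts["water"] * config.n_lipids
    n_heads = {lbl: counts.get(lbl, 2) * config.n_lipids for lbl in head_labels}

    # Peptide geometry: fixed internal bead offsets (center-of-mass exactly
    # zeroed) whose spread combines with the 1 Å restraint jitter to match the
    # model's peptide Gaussian width.
    peptides = []
    if config.n_peptides > 0:
        pep = gaussians.get("peptide")
        sigma_pep = pep.width if pep is not None else 3.5
        sigma_int = math.sqrt(max(sigma_pep**2 - 1.0, 0.25))
        e_pep = (
            2.0 * pep.areal_excess * area / config.n_peptides
            if pep is not None
            else 208.0
        )
        for p in range(config.n_peptides):
            offs = rng.normal(0.0, sigma_int, config.peptide_beads)
            offs -= offs.mean()
            sign = 1.0 if p % 2 == 0 else -1.0
            x0, y0 = rng.random(2) * lx
            peptides.append((sign, offs, x0, y0, e_pep))

    frames = []
    for _ in range(config.n_frames):
        xs, ys, zs, es, comps, leaf, mols = [], [], [], [], [], [], []

        def add(x, y, z, e, label, mol=-1, leaflet=None):
            n = np.size(z)
            xs.append(np.broadcast_to(np.asarray(x, float), (n,)).copy())
            ys.append(np.broadcast_to(np.asarray(y, float), (n,)).copy())
            zs.append(np.asarray(z, float))
            es.append(np.broadcast_to(np.asarray(e, float), (n,)).copy())
            comps.append(np.full(n, label, dtype=object) if isinstance(label, str) else label)
            if leaflet is None:
                lf = np.where(np.asarray(z) > 0, "upper", "lower").astype(object)
            else:
                lf = np.full(n, leaflet, dtype=object)
            leaf.append(lf)
            mols.append(np.full(n, mol, dtype=int))

        # hydrocarbon chains (split CH2/CH3 labels near the bilayer center)
        zc = chain_sampler.sample(rng, n_chain)
        w_chain = chain_sampler.integral * area / n_chain
        p_ch3 = 0.5 * np.exp(-(zc**2) / (2.0 * 2.5**2))
        is_ch3 = rng.random(n_chain) < p_ch3
        labels = np.where(is_ch3, "CH3", "CH2").astype(object)
        add(rng.random(n_chain) * lx, rng.random(n_chain) * ly, zc, w_chain, labels)

        # headgroup-region Gaussians, mirror copy chosen at random
        for lbl in head_labels:
            g = gaussians[lbl]
            n = n_heads[lbl]
            sign = rng.choice([-1.0, 1.0], size=n)
            zh = rng.normal(sign * g.center, g.width)
            w = 2.0 * g.areal_excess * area / n
            add(rng.random(n) * lx, rng.random(n) * ly, zh, w, lbl)

        # water fill
        zw = water_sampler.sample(rng, n_water)
        w_water = water_sampler.integral * area / n_water
        add(rng.random(n_water) * lx, rng.random(n_water) * ly, zw, w_water, "water",
            leaflet="none")

        # counterions, dissolved in the water region
        if n_ions > 0:
            zi = water_sampler.sample(rng, n_ions)
            add(rng.random(n_ions) * lx, rng.random(n_ions) * ly, zi, 18.0, "ion",
                leaflet="none")

        # peptides: restrained depth + per-frame center-of-mass jitter
        for p, (sign, offs, x0, y0, e_pep) in enumerate(peptides):
            com = sign * config.peptide_depth + rng.normal(0.0, 1.0)
            zp = com + offs
            xp = (x0 + rng.normal(0.0, 2.0, offs.size)) % lx
            yp = (y0 + rng.normal(0.0, 2.0, offs.size)) % ly
            add(xp, yp, zp, e_pep / offs.size, "peptide", mol=p,
                leaflet="upper" if sign > 0 else "lower")

        x = np.concatenate(xs)
        y = np.concatenate(ys)
        z = np.concatenate(zs)
        e = np.concatenate(es)
        component = np.concatenate(comps)
        leaflet = np.concatenate(leaf)
        mol = np.concatenate(mols)

        if config.undulation_amplitude > 0:
            z = z + config.undulation_amplitude * np.sin(2.0 * np.pi * x / lx)
        z = (z + lz / 2.0) % lz - lz / 2.0

        mass = e * np.vectorize(MASS_PER_ELECTRON.get)(component)
        frames.append(
            Frame(x=x, y=y, z=z, electrons=e, mass=mass, component=component,
                  leaflet=leaflet, mol=mol)
        )

    n_pep = config.n_peptides
    metadata = {
        "area_per_lipid": config.area_per_lipid,
        "n_lipids": config.n_lipids,
        "n_peptides": n_pep,
        "peptide_depth_z": config.peptide_depth if n_pep else None,
        "mole_fraction_x": n_pep / (config.n_lipids + n_pep),
        "undulation_amplitude": config.undulation_amplitude,
        "seed": seed,
    }
    return ToyTrajectory(frames=tuple(frames), box=(lx, ly, lz), metadata=metadata)
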