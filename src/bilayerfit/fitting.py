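"""Scoring simulation form factors against experiment and ranking models.

Because experimental |F(qz)| carry an unknown overall scale, each simulated
curve is first multiplied by the weighted least-squares factor

    a_sim = Σ w_i |F_exp,i||F_sim,i| / Σ w_i |F_sim,i|²,   w_i = 1/Δ_i²,

and goodness of fit is the reduced weighted squared deviation

    χ² = Σ ( (|F_exp,i| − a_sim |F_sim,i|) / Δ_i )² / (N − 1).

A grid scan evaluates χ² for every candidate (peptide depth z, area per
lipid A_L, replicate), aggregates replicates by their mean, and classifies
cells against an acceptance cutoff (χ² ≤ 3.4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formfactor import FormFactor

#: χ² at or below this value counts as fitting the experiment sufficiently well.
CHI2_CUTOFF = 3.4


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one simulated form factor to experiment."""

    a_sim: float
    chi2: float
    n_points: int
    residuals: np.ndarray  # per-point |F_exp| − a_sim·|F_sim|


@dataclass(frozen=True)
class RepeatStats:
    """Summary of χ² over repeat simulations (sample std, N−1 denominator)."""

    mean: float
    std: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class ScanCell:
    z: float
    area_per_lipid: float
    replicate: int
    chi2: float
    a_sim: float
    accepted: bool


@dataclass(frozen=True)
class ScanTable:
    """χ² per (z, A_L, replicate) cell with repeat summaries and the best cell."""

    cells: tuple[ScanCell, ...]
    stats: dict[tuple[float, float], RepeatStats]
    best_cell: tuple[float, float]
    cutoff: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "z": c.z,
                    "A_L": c.area_per_lipid,
                    "replicate": c.replicate,
                    "chi2": c.chi2,
                    "a_sim": c.a_sim,
                    "accepted": c.accepted,
                }
                for c in self.cells
            ]
        )

    def summary(self) -> dict:
        return {
            "best_cell": {"z": self.best_cell[0], "A_L": self.best_cell[1]},
            "cutoff": self.cutoff,
            "cells": [
                {
                    "z": z,
                    "A_L": al,
                    "mean": s.mean,
                    "std": s.std,
                    "min": s.min,
                    "max": s.max,
                    "n": s.n,
                }
                for (z, al), s in sorted(self.stats.items())
            ],
        }


def interpolate_to_experiment(sim: FormFactor, exp_qz: np.ndarray) -> FormFactor:
    """Linearly interpolate a simulated |F| onto the experimental qz points."""
    exp_qz = np.asarray(exp_qz, dtype=float)
    lo, hi = sim.qz[0], sim.qz[-1]
    bad = exp_qz[(exp_qz < lo) | (exp_qz > hi)]
    if bad.size:
        raise ValueError(
            f"experimental qz outside simulation range [{lo:g}, {hi:g}]: "
            f"{np.array2string(bad, precision=4)}"
        )
    amp = np.interp(exp_qz, sim.qz, sim.amplitude)
    return FormFactor(exp_qz, amp, scale_status=sim.scale_status)


def _check_aligned(exp: FormFactor, sim: FormFactor) -> None:
    if exp.delta is None:
        raise ValueError("experimental form factor must carry per-point errors Δ")
    if len(exp) != len(sim) or not np.allclose(exp.qz, sim.qz):
        raise ValueError("experiment and simulation must share the same qz grid")


def scale_factor(exp: FormFactor, sim: FormFactor) -> float:
    """Weighted least-squares scale a_sim mapping simulation onto experiment."""
    _check_aligned(exp, sim)
    w = 1.0 / exp.delta**2
    denom = float(np.sum(w * sim.amplitude**2))
    if denom == 0.0:
        raise ValueError("simulation amplitudes are all zero; scale undefined")
    return float(np.sum(w * exp.amplitude * sim.amplitude) / denom)


def chi_squared(exp: FormFactor, sim: FormFactor, root: bool = False) -> FitResult:
    """Reduced χ² between experiment and the optimally scaled simulation.

    ``root=True`` returns the square-root variant (root-mean weighted
    deviation) for sensitivity checks; the default is the plain reduced sum
    of squares.
    """
    _check_aligned(exp, sim)
    n = len(exp)
    if n < 2:
        raise ValueError("need at least two points to compute χ²")
    a = scale_factor(exp, sim)
    residuals = exp.amplitude - a * sim.amplitude
    chi2 = float(np.sum((residuals / exp.delta) ** 2) / (n - 1))
    if root:
        chi2 = float(np.sqrt(chi2))
    return FitResult(a_sim=a, chi2=chi2, n_points=n, residuals=residuals)


@dataclass(frozen=True)
class DisplaySet:
    """Form factors rescaled onto the best simulation's absolute units."""

    experiment: FormFactor
    simulations: tuple[FormFactor, ...]
    best_index: int


def scale_for_display(
    fits: Sequence[FitResult], sims: Sequence[FormFactor], exp: FormFactor
) -> DisplaySet:
    """Place everything on the best (lowest-χ²) simulation's absolute scale.

    The best simulation is left untouched; the experiment is multiplied by
    1/a_sim(best) (Δ rescaled likewise); every other simulation is multiplied
    by a_sim/a_sim(best).
    """
    if len(fits) == 0 or len(fits) != len(sims):
        raise ValueError("need one fit per simulation, at least one of each")
    best = int(np.argmin([f.chi2 for f in fits]))
    a_best = fits[best].a_sim
    exp_scaled = FormFactor(
        exp.qz,
        exp.amplitude / a_best,
        delta=None if exp.delta is None else exp.delta / a_best,
        scale_status="absolute",
    )
    out = []
    for i, (fit, sim) in enumerate(zip(fits, sims)):
        factor = 1.0 if i == best else fit.a_sim / a_best
        out.append(
            FormFactor(sim.qz, sim.amplitude * factor, scale_status="absolute")
        )
    return DisplaySet(experiment=exp_scaled, simulations=tuple(out), best_index=best)


def summarize_repeats(chi2_values: Sequence[float]) -> RepeatStats:
    """Mean, sample std (0 for a single value), min and max of repeat χ²."""
    vals = np.asarray(list(chi2_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no χ² values to summarize")
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RepeatStats(
        mean=float(np.mean(vals)),
        std=std,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        n=int(vals.size),
    )


def scan(
    exp: FormFactor,
    candidates: Mapping[tuple[float, float, int], FormFactor],
    cutoff: float = CHI2_CUTOFF,
) -> ScanTable:
    """Score every candidate (z, A_L, replicate) form factor against experiment.

    Candidates are interpolated onto the experimental qz grid, χ² is computed
    per cell, replicates are aggregated by their mean, and the best cell is
    the (z, A_L) pair with the lowest mean χ² (ties broken toward smaller z,
    then smaller A_L).  Cells with χ² ≤ cutoff are flagged accepted.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate form factors supplied")
    cells = []
    by_condition: dict[tuple[float, float], list[float]] = {}
    for (z, al, rep), sim in candidates.items():
        aligned = interpolate_to_experiment(sim, exp.qz)
        fit = chi_squared(exp, aligned)
        cells.append(
            ScanCell(
                z=float(z),
                area_per_lipid=float(al),
                replicate=int(rep),
                chi2=fit.chi2,
                a_sim=fit.a_sim,
                accepted=fit.chi2 <= cutoff,
            )
        )
        by_condition.setdefault((float(z), float(al)), []).append(fit.chi2)
    stats = {key: summarize_repeats(vals) for key, vals in by_condition.items()}
    best_cell = min(stats, key=lambda key: (stats[key].mean, key[0], key[1]))
    return ScanTable(cells=tuple(cells), stats=stats, best_cell=best_cell, cutoff=cutoff)
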