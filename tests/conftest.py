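import numpy as np
import pytest

from bilayerfit.density import DensityProfile
from bilayerfit.model import (
    BilayerModel,
    ComponentGaussian,
    condition_model,
)
from bilayerfit.trajectory import Frame, ToyTrajectory


@pytest.fixture
def control_model() -> BilayerModel:
    """Neat DOPC:DOPE (1:1) bilayer at the best-fit area per lipid."""
    return condition_model(66.0)


@pytest.fixture
def tat_model() -> BilayerModel:
    """Peptide in the headgroup region: z = 18 Å, A_L = 68 Å², 2 peptides."""
    return condition_model(68.0, peptide_depth=18.0, n_peptides=2)


@pytest.fixture
def fine_grid() -> np.ndarray:
    return np.arange(-40.0, 40.0 + 1e-9, 0.02)


def random_model(rng: np.random.Generator, with_peptide: bool = False) -> BilayerModel:
    """Draw a physically plausible Gaussian+slab model for property tests."""
    d_c = rng.uniform(12.0, 17.0)
    gaussians = [
        ComponentGaussian("PC-head", d_c + rng.uniform(3.5, 6.0), rng.uniform(2.0, 3.5),
                          rng.uniform(0.2, 0.5)),
        ComponentGaussian("PE-head", d_c + rng.uniform(1.5, 3.4), rng.uniform(2.0, 3.5),
                          rng.uniform(0.2, 0.5)),
        ComponentGaussian("CG", d_c + rng.uniform(0.5, 1.5), rng.uniform(2.0, 3.0),
                          rng.uniform(0.05, 0.2)),
        ComponentGaussian("CH3", 0.0, rng.uniform(2.0, 3.0), -rng.uniform(0.05, 0.2)),
    ]
    if with_peptide:
        gaussians.append(
            ComponentGaussian("peptide", rng.uniform(0.0, 18.0), rng.uniform(3.0, 4.0),
                              rng.uniform(0.02, 0.1))
        )
    return BilayerModel(
        gaussians=tuple(gaussians),
        hc_plateau=rng.uniform(0.27, 0.32),
        hc_halfwidth=d_c,
        hc_smoothing=rng.uniform(1.5, 3.0),
        water_density=0.333,
        box_halfheight=40.0,
    )


def make_frame(z, component, electrons=None, mass=None, x=None, y=None, mol=None) -> Frame:
    """Hand-build a frame from per-bead values for unit tests."""
    z = np.asarray(z, dtype=float)
    n = z.size
    component = np.asarray(component, dtype=object)
    electrons = np.full(n, 10.0) if electrons is None else np.asarray(electrons, float)
    mass = electrons * 1.8 if mass is None else np.asarray(mass, float)
    return Frame(
        x=np.zeros(n) if x is None else np.asarray(x, float),
        y=np.zeros(n) if y is None else np.asarray(y, float),
        z=z,
        electrons=electrons,
        mass=mass,
        component=component,
        leaflet=np.where(z > 0, "upper", "lower").astype(object),
        mol=np.full(n, -1, dtype=int) if mol is None else np.asarray(mol, int),
    )


def make_trajectory(frames, box=(66.0, 66.0, 80.0), metadata=None) -> ToyTrajectory:
    return ToyTrajectory(frames=tuple(frames), box=box, metadata=metadata or {})
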