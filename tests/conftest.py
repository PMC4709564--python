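import numpy as np
import pytest

from pepedit import (
    Atom, BeadComplexSpec, DomainMap, GaussianEnsembleSpec, Topology,
    Trajectory, bead_complex,
)


@pytest.fixture
def toy_peptide() -> Topology:
    """Three-residue chain with CA + CB atoms per residue."""
    atoms = []
    serial = 1
    for res in range(1, 4):
        for name, element in (("CA", "C"), ("CB", "C")):
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_index=res, residue_name="ALA",
                              chain_id="A",
                              position=np.array([3.8 * res, float(name == "CB"), 0.0])))
            serial += 1
    return Topology(atoms=atoms)


@pytest.fixture
def tapasin_like_topology() -> Topology:
    """CA-only chain T numbered 1..381, mirroring the tapasin TN/TC split."""
    atoms = [
        Atom(serial=i, name="CA", element="C", residue_index=i,
             residue_name="GLY", chain_id="T",
             position=np.array([3.8 * i, 0.0, 0.0]))
        for i in range(1, 382)
    ]
    return Topology(atoms=atoms)


@pytest.fixture
def seeded_bead_complex():
    """5x5-bead two-group complex with seeded random charges, 3 frames."""
    rng = np.random.default_rng(42)
    spec = BeadComplexSpec(
        positions_a=rng.uniform(0, 8, (5, 3)),
        positions_b=rng.uniform(0, 8, (5, 3)) + np.array([0.0, 0.0, 7.0]),
        charges_a=rng.uniform(-1, 1, 5),
        charges_b=rng.uniform(-1, 1, 5),
        sigma_a=rng.uniform(0.25, 0.4, 5),
        sigma_b=rng.uniform(0.25, 0.4, 5),
        epsilon_a=rng.uniform(0.1, 1.0, 5),
        epsilon_b=rng.uniform(0.1, 1.0, 5),
        jitter=0.3, n_frames=3, seed=7,
    )
    return spec, *bead_complex(spec)


def isotropic_gaussian_spec(n_particles: int, sigma2: float, seed: int,
                            n_frames: int = 50_000,
                            mass: float = 12.0) -> GaussianEnsembleSpec:
    """Independent isotropic particles, variance sigma2 per coordinate."""
    rng = np.random.default_rng(seed + 1000)
    mean = rng.uniform(0.0, 20.0, 3 * n_particles)
    return GaussianEnsembleSpec(
        masses=np.full(n_particles, mass),
        covariance=np.eye(3 * n_particles) * sigma2,
        mean=mean, n_frames=n_frames, seed=seed,
    )


@pytest.fixture
def static_trajectory() -> Trajectory:
    coords = np.tile(np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 2]]),
                     (5, 1, 1))
    return Trajectory(times=np.arange(5.0), coords=coords)
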