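"""Synthetic ensembles with known ground truth.

Every analysis stage in this package can be validated without the original
multi-microsecond trajectories, because each stage has a synthetic substrate
whose answer is known in closed form:

* :func:`gaussian_trajectory` — i.i.d. draws from a multivariate Gaussian
  with prescribed 3N x 3N covariance; the quasi-harmonic (Schlitter)
  entropy of that covariance is returned alongside.
* :func:`pd_pl_pair` — two Gaussian ensembles differing by a controlled
  covariance change confined to a particle subset, emulating the
  peptide-deficient (PD) vs peptide-loaded (PL) comparison with an exactly
  known per-domain entropy difference.
* :func:`bead_complex` — two groups of charged Lennard-Jones beads whose
  residue-pair forces have an analytic / brute-force answer.
* :func:`sphere_fixture` — pseudo-atoms with explicit radii for which
  solvent-accessible and buried areas follow the spherical-cap formulas.

Gaussian frames are i.i.d. (no autocorrelation): entropy and mean-force
estimators are ensemble averages, and i.i.d. sampling gives the sharpest
oracle. An optional AR(1) mode exists solely to exercise block averaging.
All generators are seeded and bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Atom, DomainMap, Topology, Trajectory

DEFAULT_TEMPERATURE = 300.0  # K, matching the simulated conditions


@dataclass
class GaussianEnsembleSpec:
    """Specification of a positional-fluctuation ensemble.

    masses in u (one per particle), covariance 3N x 3N in Å² (symmetric
    PSD), mean 3N-vector in Å. ``ar1`` in [0, 1) adds first-order
    autocorrelation (0 = i.i.d.) for block-averaging exercises only; the
    stationary distribution, and hence the analytic entropy, is unchanged.
    """

    masses: np.ndarray
    covariance: np.ndarray
    mean: np.ndarray
    n_frames: int
    seed: int
    dt: float = 1.0  # ps
    ar1: float = 0.0

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        n3 = 3 * len(self.masses)
        if self.covariance.shape != (n3, n3):
            raise ValueError(f"covariance must be {n3}x{n3}")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.mean.shape != (n3,):
            raise ValueError(f"mean must have length {n3}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must be in [0, 1)")

    @property
    def n_particles(self) -> int:
        return len(self.masses)


@dataclass
class BeadComplexSpec:
    """Two disjoint groups of charged LJ beads, one or more beads per
    'residue'. Positions in Å, charges in e, sigma in nm, epsilon in
    kJ/mol. ``residues_*`` assign each bead a 1-based residue index within
    its group (group A = chain 'A', group B = chain 'B')."""

    positions_a: np.ndarray
    positions_b: np.ndarray
    charges_a: np.ndarray
    charges_b: np.ndarray
    sigma_a: np.ndarray
    sigma_b: np.ndarray
    epsilon_a: np.ndarray
    epsilon_b: np.ndarray
    residues_a: np.ndarray | None = None
    residues_b: np.ndarray | None = None
    jitter: float = 0.0  # Å, Gaussian positional noise per frame
    n_frames: int = 1
    seed: int = 0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("positions_a", "positions_b", "charges_a", "charges_b",
                     "sigma_a", "sigma_b", "epsilon_a", "epsilon_b"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if len(self.positions_a) < 1 or len(self.positions_b) < 1:
            raise ValueError("each group needs at least one bead")
        if self.residues_a is None:
            self.residues_a = np.arange(1, len(self.positions_a) + 1)
        if self.residues_b is None:
            self.residues_b = np.arange(1, len(self.positions_b) + 1)
        self.residues_a = np.asarray(self.residues_a, dtype=int)
        self.residues_b = np.asarray(self.residues_b, dtype=int)


def _factor_covariance(cov: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Return L with L L^T = cov via eigendecomposition; eigenvalues in
    [-tol, 0) are clipped to 0, more negative ones are an error."""
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    scale = max(1.0, float(np.max(np.abs(w))))
    if np.min(w) < -tol * scale:
        raise ValueError(f"covariance is not PSD (min eigenvalue {np.min(w):g})")
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def gaussian_trajectory(
    spec: GaussianEnsembleSpec,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[Trajectory, float]:
    """Draw the ensemble and return it with its analytic Schlitter entropy.

    The analytic value is the closed-form quasi-harmonic entropy of the
    *specified* covariance and masses in J/(K mol); estimators working from
    the sampled frames should converge to it as n_frames grows.
    """
    from .entropy import schlitter_from_matrix

    rng = np.random.default_rng(spec.seed)
    L = _factor_covariance(spec.covariance)
    n3 = 3 * spec.n_particles
    z = rng.standard_normal((spec.n_frames, n3))
    if spec.ar1 > 0.0:
        # AR(1) in the latent white noise; rescaled to keep unit stationary
        # variance so the specified covariance (and entropy) still hold.
        phi = spec.ar1
        out = np.empty_like(z)
        out[0] = z[0]
        for t in range(1, spec.n_frames):
            out[t] = phi * out[t - 1] + np.sqrt(1.0 - phi * phi) * z[t]
        z = out
    flat = spec.mean + z @ L.T
    coords = flat.reshape(spec.n_frames, spec.n_particles, 3)
    times = spec.dt * np.arange(spec.n_frames)
    analytic = schlitter_from_matrix(spec.covariance, spec.masses, temperature)
    return Trajectory(times=times, coords=coords), analytic


def pd_pl_pair(
    spec_base: GaussianEnsembleSpec,
    scale: float,
    subset: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[Trajectory, Trajectory, float]:
    """Paired ensembles differing by a covariance change on a particle subset.

    The second ("PL") ensemble's covariance equals the first's with the
    subset's rows and columns scaled by ``scale`` (its diagonal block by
    ``scale``²), which preserves positive semi-definiteness. Returns
    (traj_pd, traj_pl, analytic ΔS = S_PL − S_PD) in J/(K mol); the ΔS is
    exact for the specified covariances whether or not the subset is
    independent of the rest.
    """
    from .entropy import schlitter_from_matrix

    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must not be empty")
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = spec_base.n_particles
    if np.any(subset < 0) or np.any(subset >= n):
        raise ValueError("subset indices out of range")
    d = np.ones(3 * n)
    for p in subset:
        d[3 * p: 3 * p + 3] = scale
    cov_pl = spec_base.covariance * np.outer(d, d)

    traj_pd, s_pd = gaussian_trajectory(spec_base, temperature)
    spec_pl = GaussianEnsembleSpec(
        masses=spec_base.masses, covariance=cov_pl, mean=spec_base.mean,
        n_frames=spec_base.n_frames, seed=spec_base.seed + 1,
        dt=spec_base.dt, ar1=spec_base.ar1,
    )
    traj_pl, s_pl = gaussian_trajectory(spec_pl, temperature)
    return traj_pd, traj_pl, s_pl - s_pd


def particle_topology(
    masses: np.ndarray,
    chain_id: str = "A",
    element: str = "C",
) -> Topology:
    """One CA pseudo-atom per particle, residues numbered 1..N on one chain,
    so Gaussian ensembles plug into the selection/domain machinery."""
    masses = np.asarray(masses, dtype=float)
    atoms = [
        Atom(serial=i + 1, name="CA", element=element, residue_index=i + 1,
             residue_name="GLY", chain_id=chain_id, position=np.zeros(3))
        for i in range(len(masses))
    ]
    return Topology(atoms=atoms, masses=masses)


def contiguous_domains(ranges: dict[str, tuple[int, int]],
                       chain_id: str = "A") -> DomainMap:
    """DomainMap from {name: (first_residue, last_residue)} on one chain."""
    return DomainMap({
        name: [(chain_id, lo, hi)] for name, (lo, hi) in ranges.items()
    })


def bead_complex(spec: BeadComplexSpec) -> tuple[Topology, Trajectory]:
    """Build the two-group bead system: Topology with full nonbonded
    parameters plus a static or jittered Trajectory."""
    rng = np.random.default_rng(spec.seed)
    na, nb = len(spec.positions_a), len(spec.positions_b)
    atoms = []
    for i in range(na):
        atoms.append(Atom(serial=i + 1, name="CA", element="C",
                          residue_index=int(spec.residues_a[i]),
                          residue_name="BEA", chain_id="A",
                          position=spec.positions_a[i]))
    for j in range(nb):
        atoms.append(Atom(serial=na + j + 1, name="CA", element="C",
                          residue_index=int(spec.residues_b[j]),
                          residue_name="BEB", chain_id="B",
                          position=spec.positions_b[j]))
    top = Topology(
        atoms=atoms,
        masses=np.full(na + nb, 12.011),
        charges=np.concatenate([spec.charges_a, spec.charges_b]),
        lj_sigma=np.concatenate([spec.sigma_a, spec.sigma_b]),
        lj_epsilon=np.concatenate([spec.epsilon_a, spec.epsilon_b]),
    )
    base = np.vstack([spec.positions_a, spec.positions_b])
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.jitter > 0.0:
        coords = coords + spec.jitter * rng.standard_normal(coords.shape)
    times = spec.dt * np.arange(spec.n_frames)
    return top, Trajectory(times=times, coords=coords)


def sphere_fixture(
    radii: list[float] | np.ndarray,
    centers: list | np.ndarray,
) -> tuple[Topology, Trajectory]:
    """Pseudo-atoms with explicit van der Waals radii for SAS oracles."""
    radii = np.asarray(radii, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if centers.shape != (len(radii), 3):
        raise ValueError("centers must be (n, 3)")
    atoms = [
        Atom(serial=i + 1, name="SPH", element="C", residue_index=i + 1,
             residue_name="SPH", chain_id="A", position=centers[i])
        for i in range(len(radii))
    ]
    top = Topology(atoms=atoms, radii=radii)
    traj = Trajectory(times=np.array([0.0]), coords=centers[None, :, :])
    return top, traj


# ---------------------------------------------------------------------------
# Analytic references for the sphere fixtures
# ---------------------------------------------------------------------------

def sphere_sas_analytic(radius: float, probe: float = 1.4) -> float:
    """Exposed area of an isolated sphere: 4 pi (r + probe)^2, Å²."""
    r = radius + probe
    return 4.0 * np.pi * r * r


def two_sphere_sas_analytic(r1: float, r2: float, d: float,
                            probe: float = 1.4) -> float:
    """Total exposed area of two intersecting probe-inflated spheres.

    Each sphere loses a spherical cap where it dips inside the other;
    cap height h_i follows from the radical plane of the two spheres.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return sphere_sas_analytic(r1, probe) + sphere_sas_analytic(r2, probe)
    if d + min(R1, R2) <= max(R1, R2):
        return sphere_sas_analytic(max(r1, r2), probe)  # one engulfs the other
    x = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)  # radical-plane offset
    h1 = R1 - x
    h2 = R2 - (d - x)
    area = 4.0 * np.pi * (R1 * R1 + R2 * R2)
    area -= 2.0 * np.pi * (R1 * h1 + R2 * h2)
    return area


def two_sphere_buried_analytic(r1: float, r2: float, d: float,
                               probe: float = 1.4) -> float:
    """Buried area SAS(1) + SAS(2) − SAS(1∪2) for the two-sphere system."""
    return (sphere_sas_analytic(r1, probe) + sphere_sas_analytic(r2, probe)
            - two_sphere_sas_analytic(r1, r2, d, probe))
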