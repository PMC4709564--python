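"""Configurational entropy from positional covariance (quasi-harmonic).

The central quantity is the Schlitter upper bound on the configurational
entropy of N particles,

    S = (R/2) ln det[ 1 + (k_B T e^2 / hbar^2) M^{1/2} C M^{1/2} ],

where C is the covariance matrix of Cartesian fluctuations after removal of
overall translation and rotation, M the diagonal mass matrix, T the
temperature, e Euler's number and R the gas constant (the result is per
mole, J/(K mol)). The determinant is evaluated through the eigenvalues of
the symmetrized mass-weighted covariance — never as a raw determinant — for
numerical stability: S = (R/2) sum_i ln(1 + alpha * lambda_i) with
alpha = k_B T e^2 m_u Å² / hbar² in inverse (u Å²).

Domain decomposition evaluates the same formula on the C-alpha atoms of
each named selection separately. This neglects inter-domain correlations
(the whole is not the sum of its parts) but localizes entropy changes to
structural elements. By default each domain is superposed onto its own
reference selection, measuring internal fluctuations rather than
inter-domain motion; a flag restores the global fit for sensitivity checks.

The sampling uncertainty follows the cumulative-sampling rule: the absolute
difference between the entropy over all frames and over the first 90% of
frames, both with growing-window covariances.

Solvent entropy is estimated from the change in polar and apolar
solvent-accessible surface area through a linear empirical relationship;
the coefficients must be supplied explicitly (shipped defaults are
literature-magnitude placeholders, flagged for verification before
quantitative use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .model_io import DomainMap, Topology, Trajectory, resolve_selection

R_GAS = constants.R  # J/(K mol)

# alpha(T) = k_B T e^2 / hbar^2, expressed per (u Å²) so it multiplies
# mass-weighted covariance eigenvalues in u Å² directly.
_ALPHA_PER_K = (
    constants.k * np.e ** 2 / constants.hbar ** 2
    * constants.atomic_mass * 1e-20
)


def schlitter_alpha(temperature: float) -> float:
    """k_B T e²/ħ² in inverse (u Å²)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return _ALPHA_PER_K * temperature


@dataclass
class CovarianceResult:
    """Covariance of fitted Cartesian fluctuations, Å², 3n x 3n."""

    matrix: np.ndarray
    selection_name: str = ""
    reference_frame: int = 0
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 3:
            raise ValueError("covariance must be square with 3n rows")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance must be symmetric")


@dataclass
class EntropyResult:
    """Configurational entropy S (J/(K mol)) with sampling uncertainty."""

    S_config: float
    uncertainty: float
    selection_name: str
    temperature: float
    n_frames: int


@dataclass
class SolventEntropyCoefficients:
    """Linear coefficients of the SAS-based solvent-entropy estimate,
    J/(K mol Å²). Construct explicitly, or use :meth:`default` which
    carries representative literature magnitudes and a provenance note
    demanding verification before quantitative use."""

    a_polar: float
    a_apolar: float
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a_polar) and np.isfinite(self.a_apolar)):
            raise ValueError("coefficients must be finite")

    @classmethod
    def default(cls) -> "SolventEntropyCoefficients":
        return cls(
            a_polar=-0.11,
            a_apolar=0.43,
            provenance=("literature-magnitude placeholder for the linear "
                        "SAS/solvent-entropy relation; verify against the "
                        "original parametrisation before quantitative use"),
        )


# ---------------------------------------------------------------------------
# Superposition and covariance
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation matrix aligning centered ``mobile`` onto
    centered ``reference`` in the least-squares sense."""
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose_frames(
    coords: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares superpose every frame onto ``reference``.

    The rotation/translation is determined on ``fit_indices`` (default: all
    atoms) and applied to all atoms of the frame. Proper rotations only.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(coords.shape[1])
    ref_sub = reference[fit_indices]
    ref_centroid = ref_sub.mean(axis=0)
    ref_centered = ref_sub - ref_centroid
    if np.allclose(ref_centered, 0.0):
        raise ValueError("degenerate fit selection: all reference atoms coincide")
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        sub = coords[f, fit_indices]
        centroid = sub.mean(axis=0)
        rot = kabsch_rotation(sub - centroid, ref_centered)
        out[f] = (coords[f] - centroid) @ rot.T + ref_centroid
    return out


def fit_and_covariance(
    traj: Trajectory,
    selection: np.ndarray,
    reference: int = 0,
    superpose: bool = True,
    selection_name: str = "",
) -> CovarianceResult:
    """Covariance of the selection's fitted coordinates about their time mean.

    Each frame is least-squares superposed (optimal proper rotation plus
    translation) onto the reference frame over the same selection, then the
    3n x 3n covariance of the fitted coordinates is taken about the time
    mean (normalisation by n_frames). Selections with fewer than 3 atoms
    cannot define a rotation and are used unfitted. ``superpose=False``
    skips fitting entirely, appropriate for ensembles with no rigid-body
    drift (e.g. the synthetic Gaussian oracles).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 1:
        raise ValueError("selection must contain at least one atom")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance")
    sub = traj.coords[:, selection, :]
    if superpose and selection.size >= 3:
        ref = sub[reference]
        if np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
            raise ValueError(
                f"degenerate selection {selection_name or selection!r}: "
                "reference atoms are collinear or coincident"
            )
        sub = superpose_frames(sub, ref)
    flat = sub.reshape(traj.n_frames, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / traj.n_frames
    cov = 0.5 * (cov + cov.T)
    return CovarianceResult(matrix=cov, selection_name=selection_name,
                            reference_frame=reference, n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# Schlitter entropy
# ---------------------------------------------------------------------------

def schlitter_from_matrix(
    cov: np.ndarray,
    masses: np.ndarray,
    temperature: float,
    eig_tol: float = 1e-8,
) -> float:
    """Schlitter entropy, J/(K mol), from a 3n x 3n covariance in Å² and
    per-particle masses in u, via eigenvalues of M^{1/2} C M^{1/2}."""
    cov = np.asarray(cov, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    n3 = cov.shape[0]
    if 3 * len(masses) != n3:
        raise ValueError("masses do not match covariance dimension")
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    mw = sqrt_m[:, None] * cov * sqrt_m[None, :]
    mw = 0.5 * (mw + mw.T)
    lam = np.linalg.eigvalsh(mw)  # u Å²
    scale = max(1.0, float(np.max(np.abs(lam))) if lam.size else 1.0)
    if np.min(lam) < -eig_tol * scale:
        raise ValueError(f"negative covariance eigenvalue {np.min(lam):g}")
    lam = np.clip(lam, 0.0, None)
    alpha = schlitter_alpha(temperature)
    return 0.5 * R_GAS * float(np.sum(np.log1p(alpha * lam)))


def schlitter_entropy(
    cov: CovarianceResult,
    masses: np.ndarray,
    temperature: float,
    uncertainty: float = 0.0,
) -> EntropyResult:
    """Wrap :func:`schlitter_from_matrix` for a covariance result; masses
    are per atom of the selection, in u."""
    s = schlitter_from_matrix(cov.matrix, masses, temperature)
    return EntropyResult(S_config=s, uncertainty=uncertainty,
                         selection_name=cov.selection_name,
                         temperature=temperature, n_frames=cov.n_frames)


def trajectory_entropy(
    traj: Trajectory,
    selection: np.ndarray,
    masses_all: np.ndarray,
    temperature: float,
    superpose: bool = True,
    selection_name: str = "",
) -> float:
    """Fit + covariance + Schlitter in one call; returns S in J/(K mol)."""
    cov = fit_and_covariance(traj, selection, superpose=superpose,
                             selection_name=selection_name)
    return schlitter_from_matrix(cov.matrix, np.asarray(masses_all)[selection],
                                 temperature)


def entropy_uncertainty(
    traj: Trajectory,
    selection: np.ndarray,
    masses_all: np.ndarray,
    temperature: float,
    superpose: bool = True,
    fraction: float = 0.90,
) -> float:
    """|S(all frames) − S(first ``fraction`` of frames)|, both cumulative.

    Quantifies sampling convergence: for a converged ensemble the two
    growing-window entropies agree and the uncertainty is small.
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for the convergence estimate")
    n_part = max(2, int(np.floor(fraction * traj.n_frames)))
    s_all = trajectory_entropy(traj, selection, masses_all, temperature,
                               superpose=superpose)
    s_part = trajectory_entropy(traj[slice(0, n_part)], selection, masses_all,
                                temperature, superpose=superpose)
    return abs(s_all - s_part)


def cumulative_entropy(
    traj: Trajectory,
    selection: np.ndarray,
    masses_all: np.ndarray,
    temperature: float,
    checkpoints: np.ndarray | None = None,
    superpose: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """S over growing windows [0, n) at the given frame-count checkpoints."""
    if checkpoints is None:
        checkpoints = np.unique(np.linspace(2, traj.n_frames, 20).astype(int))
    out = np.array([
        trajectory_entropy(traj[slice(0, int(n))], selection, masses_all,
                           temperature, superpose=superpose)
        for n in checkpoints
    ])
    return np.asarray(checkpoints), out


def entropy_by_domain(
    traj: Trajectory,
    topology: Topology,
    domain_map: DomainMap,
    temperature: float,
    fit: str = "domain",
    with_uncertainty: bool = True,
    whole_name: str = "all",
) -> dict[str, EntropyResult]:
    """Per-selection Schlitter entropy on C-alpha atoms, plus the whole.

    ``fit``: ``"domain"`` (default) superposes each domain onto its own
    reference selection, measuring internal fluctuations; ``"global"``
    fits once on all C-alpha atoms; ``"none"`` skips fitting.
    """
    if fit not in ("domain", "global", "none"):
        raise ValueError(f"unknown fit mode {fit!r}")
    masses = topology.masses
    work = traj
    superpose = fit == "domain"
    if fit == "global":
        all_ca = np.array([i for i, a in enumerate(topology.atoms)
                           if a.name == "CA"], dtype=int)
        fitted = superpose_frames(traj.coords, traj.coords[0], all_ca)
        work = Trajectory(times=traj.times, coords=fitted)

    results: dict[str, EntropyResult] = {}
    names = list(domain_map.names())
    for name in names + [whole_name]:
        if name == whole_name:
            idx = np.array(sorted({
                i for n in names
                for i in resolve_selection(domain_map, n, topology, "CA")
            }), dtype=int)
        else:
            idx = resolve_selection(domain_map, name, topology, "CA")
        s = trajectory_entropy(work, idx, masses, temperature,
                               superpose=superpose, selection_name=name)
        unc = 0.0
        if with_uncertainty and traj.n_frames >= 10:
            unc = entropy_uncertainty(work, idx, masses, temperature,
                                      superpose=superpose)
        results[name] = EntropyResult(
            S_config=s, uncertainty=unc, selection_name=name,
            temperature=temperature, n_frames=traj.n_frames,
        )
    return results


# ---------------------------------------------------------------------------
# Solvent entropy and totals
# ---------------------------------------------------------------------------

def solvent_entropy(
    delta_sas_polar: float,
    delta_sas_apolar: float,
    coeffs: SolventEntropyCoefficients,
) -> float:
    """ΔS_solv = a_polar·ΔSAS_polar + a_apolar·ΔSAS_apolar, J/(K mol)."""
    if coeffs is None:
        raise ValueError(
            "solvent-entropy coefficients must be supplied explicitly"
        )
    return coeffs.a_polar * delta_sas_polar + coeffs.a_apolar * delta_sas_apolar


def total_entropy(delta_s_config: float, delta_s_solvent: float) -> float:
    """ΔS_total = ΔS_config + ΔS_solv, J/(K mol)."""
    return delta_s_config + delta_s_solvent


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def write_entropy_table(
    rows: list[tuple[str, float, float]],
    path,
    header: tuple[str, str, str] = ("Domain", "dS_config_J_per_K_mol",
                                    "uncertainty_J_per_K_mol"),
) -> None:
    """TSV with Domain / ΔS_config / uncertainty columns."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for name, s, u in rows:
            fh.write(f"{name}\t{s:.6g}\t{u:.6g}\n")
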