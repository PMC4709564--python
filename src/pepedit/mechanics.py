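"""Pairwise residue-residue force distribution analysis (FDA).

Time-averaged nonbonded forces between two atom groups, decomposed into
residue-pair contributions. For every atom pair (i in group 1, j in group
2) the signed central-force scalar is

    f = -dU/dr,   U(r) = k_e q_i q_j / r + 4 eps [ (sigma/r)^12 - (sigma/r)^6 ],

truncated to zero beyond the cutoff (default 10 Å). The sign convention is
physical: negative = attractive, positive = repulsive. A residue pair's
force is the sum of its atom-pair scalars (additive and sign-preserving);
the alternative signed-vector-norm scalarization is available behind a
flag. Lorentz-Berthelot combination rules build sigma/epsilon for unlike
pairs.

Forces use plain truncation (no PME, no shift function): unlike potentials,
forces are unchanged by potential shifting, and reciprocal-space
contributions cannot be attributed to residue pairs. This is an
approximation relative to the simulation Hamiltonian and is documented as
such.

Statistical errors come from block averaging with doubling block sizes
until the standard error plateaus, appropriate for correlated time series.
State-difference tables (e.g. peptide-deficient vs peptide-loaded) match
pairs by residue identity; the combined error of a difference is the linear
sum of the two state errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .model_io import Topology, Trajectory

# Coulomb constant in kJ mol^-1 nm e^-2 and the force-unit bridge.
COULOMB_KE = (
    constants.e ** 2 / (4 * np.pi * constants.epsilon_0)
    * constants.Avogadro / 1e3 / 1e-9
)  # = 138.935458...
PN_PER_KJ_MOL_NM = 1e3 / constants.Avogadro / 1e-9 * 1e12  # = 1.66054...
ANGSTROM_PER_NM = 10.0


@dataclass
class NonbondedParams:
    """Cutoff in Å; Coulomb constant in kJ mol^-1 nm e^-2."""

    cutoff: float = 10.0
    coulomb_constant: float = COULOMB_KE
    combination_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.combination_rule != "lorentz-berthelot":
            raise ValueError("only the Lorentz-Berthelot rule is implemented")


@dataclass
class PairForce:
    """Signed mean force (pN) between one residue of each group.

    Negative = attractive. ``residue_a``/``residue_b`` are (chain_id,
    residue_index, residue_name) triples."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    F_mean: float
    F_err: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.F_err < 0:
            raise ValueError("F_err must be >= 0")


@dataclass
class PairForceTable:
    """Residue-pair forces sorted by |F_mean| descending."""

    pairs: list[PairForce]
    group1_label: str = "group1"
    group2_label: str = "group2"
    cutoff: float = 10.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        keys = [(p.residue_a, p.residue_b) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue pairs in table")
        self.pairs = sorted(self.pairs, key=lambda p: -abs(p.F_mean))

    def lookup(self, residue_a, residue_b) -> PairForce | None:
        for p in self.pairs:
            if p.residue_a == tuple(residue_a) and p.residue_b == tuple(residue_b):
                return p
        return None


# ---------------------------------------------------------------------------
# Atom-pair force
# ---------------------------------------------------------------------------

def pair_force_scalar(
    r_angstrom: np.ndarray | float,
    q1q2: np.ndarray | float,
    sigma_nm: np.ndarray | float,
    epsilon: np.ndarray | float,
    params: NonbondedParams,
) -> np.ndarray | float:
    """Signed central-force scalar −dU/dr in pN, vectorized over inputs.

    Positive = repulsive (force pushes the pair apart), negative =
    attractive. Zero beyond the cutoff.
    """
    r = np.asarray(r_angstrom, dtype=float)
    if np.any(r < 1e-3):
        raise ValueError("overlapping atoms: distance below 1e-3 Å")
    r_nm = r / ANGSTROM_PER_NM
    sr6 = np.where(sigma_nm > 0, (np.asarray(sigma_nm) / r_nm) ** 6, 0.0)
    f_kj = (params.coulomb_constant * np.asarray(q1q2) / r_nm ** 2
            + np.asarray(epsilon) * (48.0 * sr6 * sr6 - 24.0 * sr6) / r_nm)
    f_pn = f_kj * PN_PER_KJ_MOL_NM
    return np.where(r <= params.cutoff, f_pn, 0.0)


def atom_pair_force(
    r_vec: np.ndarray,
    q1: float,
    q2: float,
    sigma: float,
    epsilon: float,
    params: NonbondedParams | None = None,
) -> tuple[float, np.ndarray]:
    """Force between one atom pair: (signed scalar pN, force vector pN).

    ``r_vec`` points from atom 1 to atom 2 in Å; sigma in nm, epsilon in
    kJ/mol (already combined for the pair). The returned vector is the
    force ON atom 2 (repulsive pairs push atom 2 along +r̂).
    """
    params = params or NonbondedParams()
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    f = float(pair_force_scalar(r, q1 * q2, sigma, epsilon, params))
    vec = f * (r_vec / r)
    return f, vec


def combine_lj(
    sigma_i: np.ndarray, sigma_j: np.ndarray,
    eps_i: np.ndarray, eps_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Lorentz-Berthelot: arithmetic-mean sigma, geometric-mean epsilon."""
    return 0.5 * (sigma_i + sigma_j), np.sqrt(eps_i * eps_j)


# ---------------------------------------------------------------------------
# Residue-pair forces over a trajectory
# ---------------------------------------------------------------------------

def residue_pair_forces(
    traj: Trajectory,
    topology: Topology,
    group1: np.ndarray,
    group2: np.ndarray,
    params: NonbondedParams | None = None,
    threshold: float = 0.0,
    scalarization: str = "signed-sum",
    group1_label: str = "group1",
    group2_label: str = "group2",
) -> PairForceTable:
    """Time-averaged residue-pair forces between two disjoint atom groups.

    For each residue pair (a in group1, b in group2) and each frame, the
    atom-pair scalars are summed (``"signed-sum"``, default) or the
    atom-pair force vectors are summed and the norm signed by its
    projection on the residue-residue axis (``"vector-norm"``). F_mean is
    the time average; F_err the block-averaged standard error. Pairs whose
    force is exactly zero in every frame (all atoms beyond the cutoff) are
    dropped; surviving pairs with |F_mean| < ``threshold`` are filtered.
    """
    params = params or NonbondedParams()
    if scalarization not in ("signed-sum", "vector-norm"):
        raise ValueError(f"unknown scalarization {scalarization!r}")
    if not topology.has_parameters:
        missing = [a.serial for a in topology.atoms]
        raise ValueError(
            "topology lacks nonbonded parameters (charges/LJ); attach a "
            f"parameter sidecar first (atoms {missing[:5]}...)"
        )
    g1 = np.asarray(group1, dtype=int)
    g2 = np.asarray(group2, dtype=int)
    if np.intersect1d(g1, g2).size:
        raise ValueError("groups overlap at the atom level")

    res1, rmap1 = _residue_partition(topology, g1)
    res2, rmap2 = _residue_partition(topology, g2)
    n1, n2 = len(res1), len(res2)

    q = topology.charges
    sig, eps = combine_lj(
        topology.lj_sigma[g1][:, None], topology.lj_sigma[g2][None, :],
        topology.lj_epsilon[g1][:, None], topology.lj_epsilon[g2][None, :],
    )
    qq = q[g1][:, None] * q[g2][None, :]

    series = np.zeros((traj.n_frames, n1, n2))
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        diff = xyz[g2][None, :, :] - xyz[g1][:, None, :]  # vec 1 -> 2
        r = np.linalg.norm(diff, axis=2)
        fmat = pair_force_scalar(r, qq, sig, eps, params)
        if scalarization == "signed-sum":
            np.add.at(series[f], (rmap1[:, None], rmap2[None, :]), fmat)
        else:
            vec = fmat[:, :, None] * (diff / r[:, :, None])
            vsum = np.zeros((n1, n2, 3))
            np.add.at(vsum, (rmap1[:, None], rmap2[None, :]), vec)
            ssum = np.zeros((n1, n2))
            np.add.at(ssum, (rmap1[:, None], rmap2[None, :]), fmat)
            norm = np.linalg.norm(vsum, axis=2)
            series[f] = np.where(ssum >= 0, norm, -norm)

    pairs: list[PairForce] = []
    for a in range(n1):
        for b in range(n2):
            s = series[:, a, b]
            if not np.any(s != 0.0):
                continue
            mean = float(s.mean())
            if abs(mean) < threshold:
                continue
            err = block_error(s) if traj.n_frames >= 4 else 0.0
            pairs.append(PairForce(residue_a=res1[a], residue_b=res2[b],
                                   F_mean=mean, F_err=err,
                                   n_frames=traj.n_frames))
    return PairForceTable(pairs=pairs, group1_label=group1_label,
                          group2_label=group2_label, cutoff=params.cutoff,
                          threshold=threshold)


def _residue_partition(
    topology: Topology, indices: np.ndarray
) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    """Residue identity per atom index -> (unique residues, atom->residue map)."""
    residues: list[tuple[str, int, str]] = []
    lookup: dict[tuple[str, int, str], int] = {}
    rmap = np.empty(len(indices), dtype=int)
    for k, i in enumerate(indices):
        a = topology.atoms[i]
        rid = (a.chain_id, a.residue_index, a.residue_name)
        if rid not in lookup:
            lookup[rid] = len(residues)
            residues.append(rid)
        rmap[k] = lookup[rid]
    return residues, rmap


# ---------------------------------------------------------------------------
# Block averaging
# ---------------------------------------------------------------------------

def block_error(series: np.ndarray, plateau_tol: float = 0.05) -> float:
    """Standard error of the mean from block averaging.

    Block sizes double (1, 2, 4, ...) while at least 8 full blocks remain
    (fewer blocks make the estimate itself too noisy to trust); the
    estimate at each size is std(block means, ddof=1)/sqrt(n blocks). The
    first size at which the estimate changes by less than ``plateau_tol``
    over two consecutive doublings is taken as the plateau; if no plateau
    is reached the largest admissible block size is used. Deterministic
    for a given series.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 4:
        raise ValueError("block averaging needs at least 4 samples")
    if np.allclose(s, s[0]):
        return 0.0
    min_blocks = 8 if s.size >= 16 else 2
    estimates = []
    size = 1
    while s.size // size >= min_blocks:
        nb = s.size // size
        means = s[: nb * size].reshape(nb, size).mean(axis=1)
        estimates.append(float(np.std(means, ddof=1) / np.sqrt(nb)))
        size *= 2
    for k in range(2, len(estimates)):
        prev2, prev1, cur = estimates[k - 2], estimates[k - 1], estimates[k]
        if prev1 > 0 and cur > 0:
            if abs(cur - prev1) / cur < plateau_tol and \
               abs(prev1 - prev2) / prev1 < plateau_tol:
                return cur
    return estimates[-1]


# ---------------------------------------------------------------------------
# State-difference table
# ---------------------------------------------------------------------------

@dataclass
class DeltaForce:
    """Per-pair state comparison; ``delta`` is None when the pair is absent
    from one state (the '—' convention of the comparative table)."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    F_pd: float | None
    F_pd_err: float | None
    F_pl: float | None
    F_pl_err: float | None
    delta: float | None
    delta_err: float | None


def delta_force_table(
    table_pd: PairForceTable,
    table_pl: PairForceTable,
) -> list[DeltaForce]:
    """ΔF = F_PL − F_PD per residue pair, combined error = sum of errors.

    Pairs are matched by residue identity; a pair present in only one
    state keeps its per-state value with the Δ column marked absent.
    Sorted by |F| of the better-represented state, descending.
    """
    if (table_pd.group1_label, table_pd.group2_label) != \
       (table_pl.group1_label, table_pl.group2_label):
        raise ValueError("tables were built with different group definitions")
    by_key_pd = {(p.residue_a, p.residue_b): p for p in table_pd.pairs}
    by_key_pl = {(p.residue_a, p.residue_b): p for p in table_pl.pairs}
    rows: list[DeltaForce] = []
    for key in dict.fromkeys(list(by_key_pd) + list(by_key_pl)):
        pd_ = by_key_pd.get(key)
        pl_ = by_key_pl.get(key)
        if pd_ is not None and pl_ is not None:
            delta = pl_.F_mean - pd_.F_mean
            derr = pd_.F_err + pl_.F_err
        else:
            delta = derr = None
        rows.append(DeltaForce(
            residue_a=key[0], residue_b=key[1],
            F_pd=None if pd_ is None else pd_.F_mean,
            F_pd_err=None if pd_ is None else pd_.F_err,
            F_pl=None if pl_ is None else pl_.F_mean,
            F_pl_err=None if pl_ is None else pl_.F_err,
            delta=delta, delta_err=derr,
        ))
    rows.sort(key=lambda r: -max(abs(r.F_pd or 0.0), abs(r.F_pl or 0.0)))
    return rows


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def residue_label(rid: tuple[str, int, str]) -> str:
    """Compact label like 'K193' (one-letter code + crystal numbering)."""
    chain, idx, name = rid
    one = THREE_TO_ONE.get(name.upper(), name)
    return f"{one}{idx}"


def write_force_table(rows: list[DeltaForce], path,
                      group1_label: str = "group1",
                      group2_label: str = "group2") -> None:
    """TSV with per-state forces and the Δ column; '—' marks absent."""

    def fmt(x: float | None) -> str:
        return "—" if x is None else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write(f"{group1_label}\t{group2_label}\tF_PD_pN\tF_PD_err_pN"
                 "\tF_PL_pN\tF_PL_err_pN\tdF_PD_to_PL_pN\tdF_err_pN\n")
        for r in rows:
            fh.write("\t".join([
                residue_label(r.residue_a), residue_label(r.residue_b),
                fmt(r.F_pd), fmt(r.F_pd_err), fmt(r.F_pl), fmt(r.F_pl_err),
                fmt(r.delta), fmt(r.delta_err),
            ]) + "\n")
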