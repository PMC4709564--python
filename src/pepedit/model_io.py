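"""Shared data model and file I/O.

Defines the in-memory containers every analysis stage operates on
(:class:`Atom`, :class:`Topology`, :class:`Trajectory`, :class:`DomainMap`,
:class:`TimeSeries`) and the readers/writers for the external formats:

* protein structures as PDB (Biopython behind the scenes, highest-occupancy
  altloc kept),
* trajectories as DCD (MDAnalysis; coordinates in Å, times in ps),
* per-atom nonbonded parameters as a documented plain-text sidecar file,
* named residue-range selections ("domain maps") as YAML.

Unit discipline: coordinates and distances in Å, times in ps, masses in u,
charges in elementary charges, Lennard-Jones sigma in nm and epsilon in
kJ/mol. Residue numbering follows the source file (crystal numbering);
selections are closed intervals on that numbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("pepedit")

# Standard atomic masses (u) for elements that occur in protein systems.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078, "X": 12.011,
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Atom:
    """One atom record; positions in Å, numbering as printed in the source."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} ({self.name}): non-finite position")

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class Topology:
    """Ordered atom list plus optional per-atom physical parameters.

    ``masses`` are filled from the element table on construction when not
    given. ``charges`` / ``lj_sigma`` / ``lj_epsilon`` stay ``None`` until a
    parameter sidecar is attached (force analysis requires them; purely
    geometric analyses do not). ``radii`` optionally overrides the van der
    Waals radii used by the SAS stage (needed for pseudo-atom fixtures).
    """

    atoms: list[Atom]
    masses: np.ndarray | None = None
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if self.masses is None:
            self.masses = np.array(
                [ELEMENT_MASSES.get(a.element.upper(), 12.011) for a in self.atoms]
            )
        for attr in ("masses", "charges", "lj_sigma", "lj_epsilon", "radii"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{attr}: expected length {n}, got {v.shape}")
                setattr(self, attr, v)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.lj_sigma is not None and np.any(self.lj_sigma < 0):
            raise ValueError("lj_sigma must be >= 0")
        if self.lj_epsilon is not None and np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_parameters(self) -> bool:
        return self.charges is not None and self.lj_sigma is not None \
            and self.lj_epsilon is not None

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, residue) identifiers in atom order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)


@dataclass
class Trajectory:
    """Frames of coordinates (frame x atom x 3, Å) with times in ps."""

    times: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, frames) -> "Trajectory":
        return Trajectory(self.times[frames], self.coords[frames])


@dataclass
class DomainMap:
    """Named selections, each a list of (chain_id, first_residue, last_residue)
    closed intervals on the source-file residue numbering."""

    selections: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selections)) != len(self.selections):
            raise ValueError("selection names must be unique")

    def names(self) -> list[str]:
        return list(self.selections)

    def __contains__(self, name: str) -> bool:
        return name in self.selections


@dataclass
class TimeSeries:
    """A unit-tagged scalar observable over time (ps)."""

    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Structures (PDB)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a parameter-free Topology and a 1-frame Trajectory.

    Altloc handling keeps the highest-occupancy conformer (Biopython's
    default selection). Elements missing from the file are inferred from the
    atom name with a logged warning. Atom order, chains and residue
    numbering are preserved as printed.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # pragma: no cover - passthrough
        raise ParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            het, resseq, _icode = residue.get_id()
            for atom in residue:
                element = (atom.element or "").strip()
                if not element:
                    element = _element_from_name(atom.get_name())
                    logger.warning(
                        "%s: atom %s lacks an element record; inferred %s",
                        path.name, atom.get_fullname(), element,
                    )
                pos = atom.get_coord()
                if pos is None or not np.all(np.isfinite(pos)):
                    raise ParseError(
                        f"{path}: atom serial {atom.get_serial_number()} "
                        f"({atom.get_fullname()}) has missing coordinates"
                    )
                atoms.append(Atom(
                    serial=int(atom.get_serial_number() or len(atoms) + 1),
                    name=atom.get_name(),
                    element=element.upper(),
                    residue_index=int(resseq),
                    residue_name=residue.get_resname().strip(),
                    chain_id=str(chain.id).strip() or "A",
                    position=np.asarray(pos, dtype=float),
                ))
    if not atoms:
        raise ParseError(f"{path}: no atoms parsed")
    top = Topology(atoms=atoms)
    coords = np.array([a.position for a in atoms])[None, :, :]
    return top, Trajectory(times=np.array([0.0]), coords=coords)


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def write_structure(topology: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write one frame as a minimal PDB (ATOM records, Å, fixed columns)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coords must be (n_atoms, 3)")
    with open(path, "w") as fh:
        for atom, xyz in zip(topology.atoms, coords):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                f"ATOM  {atom.serial:>5d} {name:<4s}"
                f"{atom.residue_name:>4s} {atom.chain_id[:1]}{atom.residue_index:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectories (DCD)
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a DCD trajectory; times in ps, coordinates in Å."""
    from MDAnalysis.coordinates.DCD import DCDReader

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = DCDReader(str(path))
        if reader.n_atoms != topology.n_atoms:
            reader.close()
            raise ValueError(
                f"{path}: trajectory has {reader.n_atoms} atoms but topology "
                f"has {topology.n_atoms}"
            )
        times, frames = [], []
        for i, ts in enumerate(reader):
            xyz = np.asarray(ts.positions, dtype=float)
            if not np.all(np.isfinite(xyz)):
                reader.close()
                raise ParseError(f"{path}: corrupt coordinates in frame {i}")
            times.append(float(ts.time))
            frames.append(xyz)
        reader.close()
    return Trajectory(times=np.asarray(times), coords=np.asarray(frames))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as DCD. Times must be uniformly spaced (the DCD
    header stores a single timestep)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    if traj.n_frames > 2 and not np.allclose(np.diff(traj.times), dt):
        raise ValueError("DCD requires uniformly spaced frame times")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with DCDWriter(str(path), n_atoms=traj.n_atoms, dt=dt) as w:
            for frame in traj.coords:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Parameter sidecar (plain text, one atom per line)
# ---------------------------------------------------------------------------
# Format:   serial  mass_u  charge_e  sigma_nm  epsilon_kJ_mol
# Comment lines start with '#'. Atom count and order must match the topology.

def write_parameters(topology: Topology, path: str | Path) -> None:
    if not topology.has_parameters:
        raise ValueError("topology carries no nonbonded parameters to write")
    with open(path, "w") as fh:
        fh.write("# serial mass_u charge_e sigma_nm epsilon_kJ_mol\n")
        for atom, m, q, s, e in zip(
            topology.atoms, topology.masses, topology.charges,
            topology.lj_sigma, topology.lj_epsilon,
        ):
            fh.write(f"{atom.serial} {m:.17g} {q:.17g} {s:.17g} {e:.17g}\n")


def read_parameters(topology: Topology, path: str | Path) -> Topology:
    """Attach sidecar nonbonded parameters; returns the same Topology."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            rows.append([float(x) for x in parts])
    if len(rows) != topology.n_atoms:
        raise ValueError(
            f"{path}: {len(rows)} parameter rows for {topology.n_atoms} atoms"
        )
    arr = np.asarray(rows)
    serials = arr[:, 0].astype(int)
    expected = np.array([a.serial for a in topology.atoms])
    if not np.array_equal(serials, expected):
        raise ParseError(f"{path}: serial numbers do not match topology order")
    topology.masses = arr[:, 1]
    topology.charges = arr[:, 2]
    topology.lj_sigma = arr[:, 3]
    topology.lj_epsilon = arr[:, 4]
    topology.__post_init__()
    return topology


# ---------------------------------------------------------------------------
# Domain maps (YAML)
# ---------------------------------------------------------------------------
# selections:
#   TN:  [{chain: B, first: 1, last: 269}]
#   TC:  [{chain: B, first: 270, last: 381}]

def read_domain_map(path: str | Path) -> DomainMap:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "selections" not in data:
        raise ParseError(f"{path}: expected a mapping with a 'selections' key")
    selections: dict[str, list[tuple[str, int, int]]] = {}
    for name, entries in data["selections"].items():
        ranges = []
        for e in entries:
            ranges.append((str(e["chain"]), int(e["first"]), int(e["last"])))
        selections[str(name)] = ranges
    return DomainMap(selections=selections)


def write_domain_map(domain_map: DomainMap, path: str | Path) -> None:
    data = {
        "selections": {
            name: [{"chain": c, "first": lo, "last": hi} for c, lo, hi in ranges]
            for name, ranges in domain_map.selections.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_domain_map() -> DomainMap:
    """Domain map shipped for the tapasin-MHC I (B*44:02) system.

    The MHC I alpha1/alpha2/alpha3 boundaries are the canonical class I
    domain boundaries and are APPROXIMATE (user-overridable); the tapasin
    TN/TC split at residue 270 follows the crystal-structure domain
    definition. Chains: A = MHC I heavy chain, B = beta-2 microglobulin,
    C = antigenic peptide, T = tapasin.
    """
    import importlib.resources as res

    with res.files("pepedit").joinpath("data/domains_b4402.yaml").open() as fh:
        data = yaml.safe_load(fh)
    selections = {
        str(name): [(str(e["chain"]), int(e["first"]), int(e["last"])) for e in entries]
        for name, entries in data["selections"].items()
    }
    return DomainMap(selections=selections)


# ---------------------------------------------------------------------------
# Selection resolution
# ---------------------------------------------------------------------------

_AMINO_HEAVY = {"C", "N", "O", "S", "SE"}


def resolve_selection(
    domain_map: DomainMap,
    name: str,
    topology: Topology,
    atom_filter: str = "CA",
) -> np.ndarray:
    """Resolve a named selection to a sorted array of atom indices.

    ``atom_filter``: ``"all"`` keeps every atom in the residue ranges,
    ``"CA"`` keeps exactly the alpha-carbon of each amino-acid residue,
    ``"heavy"`` drops hydrogens. Raises ``KeyError`` for unknown names and
    ``ValueError`` when the selection resolves to no atoms (a silent no-op
    analysis would otherwise result).
    """
    if name not in domain_map:
        raise KeyError(f"selection {name!r} not in domain map "
                       f"(available: {domain_map.names()})")
    if atom_filter not in ("all", "CA", "heavy"):
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    ranges = domain_map.selections[name]
    idx = []
    for i, atom in enumerate(topology.atoms):
        in_range = any(
            atom.chain_id == c and lo <= atom.residue_index <= hi
            for c, lo, hi in ranges
        )
        if not in_range:
            continue
        if atom_filter == "CA" and atom.name != "CA":
            continue
        if atom_filter == "heavy" and atom.element.upper() == "H":
            continue
        idx.append(i)
    if not idx:
        raise ValueError(f"selection {name!r} resolves to no atoms "
                         f"with filter {atom_filter!r}")
    return np.array(sorted(idx), dtype=int)
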