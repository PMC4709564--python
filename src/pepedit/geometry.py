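"""Geometric and surface observables of trajectories.

Solvent-accessible surface (SAS) with a polar/apolar split, buried
interface area, RMSD with independent fit and measure selections, per-residue
RMSF, named inter-atom distances (e.g. the d1/d2 groove widths), threshold
fractions, equilibration windowing and moving averages.

SAS uses sphere-surface point sampling (Shrake-Rupley style, Fibonacci
point distribution via biotite) with a probe radius of 1.4 Å by default.
Polar area is that of nitrogen and oxygen atoms (hydrogens follow their
nearest heavy atom); everything else is apolar. Van der Waals radii come
from a standard per-element table (Bondi), overridable per atom through
``Topology.radii``.

The fit/measure RMSD follows the two-selection convention: every frame is
superposed on the fit selection's C-alpha atoms, then the RMSD is measured
over the (possibly distal) measure selection without re-fitting, so that
rigid motion of the measured part relative to the fitted part contributes
to the RMSD. With fit = measure it reduces to the ordinary RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import superpose_frames
from .model_io import TimeSeries, Topology, Trajectory

# Bondi van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "SE": 1.90, "FE": 1.80, "ZN": 1.39,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31, "X": 1.70,
}
POLAR_ELEMENTS = {"N", "O"}
DEFAULT_PROBE = 1.4  # Å
DEFAULT_SAS_POINTS = 960


@dataclass
class SASResult:
    """Total/polar/apolar solvent-accessible areas, Å²."""

    total: float
    polar: float
    apolar: float
    per_atom: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.total - (self.polar + self.apolar)) > 1e-6 * max(1.0, self.total):
            raise ValueError("polar + apolar must equal total")


@dataclass
class RmsdSpec:
    """Fit on one selection, measure on another (C-alpha based)."""

    fit_selection: np.ndarray
    measure_selection: np.ndarray
    reference: int | np.ndarray = 0  # frame index or (n_atoms, 3) coordinates


def atom_radii(topology: Topology) -> np.ndarray:
    """Per-atom van der Waals radii: explicit ``Topology.radii`` override
    where present, otherwise the element table."""
    if topology.radii is not None:
        return topology.radii
    radii = np.empty(topology.n_atoms)
    for i, a in enumerate(topology.atoms):
        el = a.element.upper()
        if el not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r} "
                           f"(atom serial {a.serial}); supply Topology.radii")
        radii[i] = VDW_RADII[el]
    return radii


def polar_mask(topology: Topology) -> np.ndarray:
    """True for polar atoms: N, O, and hydrogens nearest to an N/O."""
    elements = np.array([a.element.upper() for a in topology.atoms])
    mask = np.isin(elements, list(POLAR_ELEMENTS))
    h_idx = np.where(elements == "H")[0]
    if h_idx.size:
        heavy = np.where(elements != "H")[0]
        pos = np.array([a.position for a in topology.atoms])
        for h in h_idx:
            d = np.linalg.norm(pos[heavy] - pos[h], axis=1)
            mask[h] = mask[heavy[np.argmin(d)]]
    return mask


def sas(
    topology: Topology,
    coords: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SAS_POINTS,
    subset: np.ndarray | None = None,
) -> SASResult:
    """SAS of one frame by sphere-point sampling (biotite backend).

    ``subset`` restricts the computation to those atoms *in isolation*
    (other atoms neither contribute area nor occlude), which is what the
    buried-surface difference needs.
    """
    import biotite.structure as struc

    coords = np.asarray(coords, dtype=float)
    radii = atom_radii(topology)
    mask = polar_mask(topology)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        coords = coords[subset]
        radii = radii[subset]
        mask = mask[subset]
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C"] * n)  # radii supplied explicitly below
    per_atom = struc.sasa(arr, probe_radius=probe, point_number=n_points,
                          vdw_radii=radii, ignore_ions=False)
    per_atom = np.nan_to_num(np.asarray(per_atom, dtype=float))
    polar = float(per_atom[mask].sum())
    apolar = float(per_atom[~mask].sum())
    return SASResult(total=polar + apolar, polar=polar, apolar=apolar,
                     per_atom=per_atom)


def buried_surface(
    traj: Trajectory,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SAS_POINTS,
) -> TimeSeries:
    """Per-frame buried area SAS(a) + SAS(b) − SAS(a ∪ b), Å².

    Non-negative up to sampling noise and exactly symmetric in (a, b).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups overlap at the atom level")
    union = np.concatenate([group_a, group_b])
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        sa = sas(topology, xyz, probe, n_points, subset=group_a).total
        sb = sas(topology, xyz, probe, n_points, subset=group_b).total
        sab = sas(topology, xyz, probe, n_points, subset=union).total
        values[f] = sa + sb - sab
    return TimeSeries(times=traj.times, values=values, unit="A^2")


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, spec: RmsdSpec) -> TimeSeries:
    """Fit/measure RMSD per frame, Å (see module docstring)."""
    fit_sel = np.asarray(spec.fit_selection, dtype=int)
    mea_sel = np.asarray(spec.measure_selection, dtype=int)
    if fit_sel.size == 0 or mea_sel.size == 0:
        raise ValueError("fit and measure selections must be non-empty")
    if isinstance(spec.reference, (int, np.integer)):
        ref = traj.coords[int(spec.reference)]
    else:
        ref = np.asarray(spec.reference, dtype=float)
        if ref.shape != (traj.n_atoms, 3):
            raise ValueError(
                f"reference has {ref.shape} coordinates; expected "
                f"({traj.n_atoms}, 3) matching the trajectory"
            )
    fitted = superpose_frames(traj.coords, ref, fit_sel)
    dev = fitted[:, mea_sel, :] - ref[None, mea_sel, :]
    values = np.sqrt((dev ** 2).sum(axis=2).mean(axis=1))
    return TimeSeries(times=traj.times, values=values, unit="A")


def fraction_below(series: TimeSeries, threshold: float) -> float:
    """Exact count proportion of values strictly below the threshold."""
    if len(series) == 0:
        raise ValueError("series is empty")
    return float(np.count_nonzero(series.values < threshold) / len(series))


def rmsf(
    traj: Trajectory,
    selection: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom RMSF (Å) about the time-mean position after fitting.

    Fitting defaults to the measured selection itself. Returns one value
    per atom of ``selection``; use :func:`np.median` for the profile
    median.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    selection = np.asarray(selection, dtype=int)
    fit_sel = selection if fit_selection is None else np.asarray(fit_selection, int)
    fitted = superpose_frames(traj.coords, traj.coords[0], fit_sel)
    sub = fitted[:, selection, :]
    mean = sub.mean(axis=0)
    return np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def find_atom(topology: Topology, chain: str, residue: int, name: str) -> int:
    for i, a in enumerate(topology.atoms):
        if a.chain_id == chain and a.residue_index == residue and a.name == name:
            return i
    raise KeyError(f"no atom {name!r} in chain {chain!r} residue {residue}")


def named_distances(
    traj: Trajectory,
    topology: Topology,
    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]],
) -> list[TimeSeries]:
    """Euclidean distance per frame for each named atom pair, Å.

    Pairs are ((chain, residue, atom_name), (chain, residue, atom_name)),
    e.g. the groove widths d1 = I85-T138 and d2 = Y74-A149 CA-CA distances.
    """
    out = []
    for (c1, r1, n1), (c2, r2, n2) in pairs:
        i = find_atom(topology, c1, r1, n1)
        j = find_atom(topology, c2, r2, n2)
        d = np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=1)
        out.append(TimeSeries(times=traj.times, values=d, unit="A"))
    return out


def min_distance(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> TimeSeries:
    """Minimum over all inter-group atom pairs, per frame, Å."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        diff = traj.coords[f, a][:, None, :] - traj.coords[f, b][None, :, :]
        vals[f] = np.sqrt((diff ** 2).sum(axis=2)).min()
    return TimeSeries(times=traj.times, values=vals, unit="A")


# ---------------------------------------------------------------------------
# Windowing and moving averages
# ---------------------------------------------------------------------------

def discard_equilibration(obj, discard_fraction: float = 0.10):
    """Drop the leading fraction of frames (equilibration) before any
    equilibrium average; works on Trajectory and TimeSeries."""
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n = obj.n_frames if isinstance(obj, Trajectory) else len(obj)
    start = int(np.floor(discard_fraction * n))
    if isinstance(obj, Trajectory):
        return obj[slice(start, n)]
    return TimeSeries(times=obj.times[start:], values=obj.values[start:],
                      unit=obj.unit)


def moving_average(series: TimeSeries, window_ps: float) -> TimeSeries:
    """Centered moving average with edge truncation (shrinking windows at
    the ends). ``window_ps`` is the full window width in ps; a 1-ns moving
    average is ``window_ps=1000``."""
    if len(series) == 0:
        raise ValueError("series is empty")
    span = series.times[-1] - series.times[0]
    if window_ps > span and len(series) > 1:
        raise ValueError(f"window {window_ps} ps exceeds series span {span} ps")
    dt = series.times[1] - series.times[0] if len(series) > 1 else 1.0
    w = max(1, int(round(window_ps / dt)))
    kernel = np.ones(w)
    summed = np.convolve(series.values, kernel, mode="same")
    counts = np.convolve(np.ones_like(series.values), kernel, mode="same")
    return TimeSeries(times=series.times, values=summed / counts,
                      unit=series.unit)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_timeseries(series: TimeSeries, path, name: str = "value") -> None:
    with open(path, "w") as fh:
        fh.write(f"time_ps\t{name}\tunit\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6g}\t{v:.6g}\t{series.unit}\n")


def write_histogram(series: TimeSeries, path, bins: int = 50) -> None:
    counts, edges = np.histogram(series.values, bins=bins)
    with open(path, "w") as fh:
        fh.write("bin_left\tbin_right\tcount\n")
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{c}\n")
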