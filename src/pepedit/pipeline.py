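"""Configuration-driven pipeline chaining the analysis stages.

Reads a single YAML config describing topology, parameter sidecar, domain
map, per-state (PD/PL) trajectory replicas and per-stage options, runs the
requested stages, and writes comparative TSV reports (per-domain entropy
table with a ΔS column, residue-pair force table with a ΔF column, and the
geometric time series/histograms). Each run emits a JSON run report
listing exactly the files written.

Replicas are windowed per replica (leading equilibration fraction
discarded) and then pooled frame-wise into one ensemble per state; pooling
order is configurable because per-replica covariances and pooled
covariances are not equivalent in general.

Command-line interface (console script ``pepedit``)::

    pepedit entropy -c config.yaml
    pepedit fda -c config.yaml
    pepedit geometry -c config.yaml
    pepedit all -c config.yaml [--dry-run]
    pepedit synth -o fixtures/ --seed 7

Exit codes: 0 ok, 1 user/config error, 2 internal error. Logs go to
stderr; results never appear on stdout except with ``--print-table``.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from . import entropy as ent
from . import geometry as geo
from . import mechanics as mech
from . import model_io as io
from . import synthetic as syn

logger = logging.getLogger("pepedit")


class ConfigError(ValueError):
    """User-facing configuration problem (exit code 1)."""


@dataclass
class AnalysisConfig:
    structure: Path
    parameters: Path | None
    domain_map: Path | None
    states: dict[str, list[Path]]
    output_dir: Path
    temperature: float = 300.0
    seed: int = 0
    discard_fraction: float = 0.10
    moving_avg_ps: float | None = None
    entropy_opts: dict = field(default_factory=dict)
    fda_opts: dict = field(default_factory=dict)
    geometry_opts: dict = field(default_factory=dict)
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            top = data["topology"]
            cfg = cls(
                structure=_resolve(path, top["structure"]),
                parameters=_resolve(path, top.get("parameters")),
                domain_map=_resolve(path, data.get("domain_map")),
                states={
                    str(k): [_resolve(path, p) for p in v]
                    for k, v in data.get("states", {}).items()
                },
                output_dir=_resolve(path, data.get("output_dir", "pepedit_out")),
                temperature=float(data.get("temperature", 300.0)),
                seed=int(data.get("seed", 0)),
                discard_fraction=float(
                    data.get("windowing", {}).get("discard_fraction", 0.10)),
                moving_avg_ps=data.get("windowing", {}).get("moving_avg_ps"),
                entropy_opts=data.get("entropy", {}) or {},
                fda_opts=data.get("fda", {}) or {},
                geometry_opts=data.get("geometry", {}) or {},
                log_level=str(data.get("log_level", "INFO")),
                raw=data,
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing config key {exc}") from exc
        if cfg.temperature <= 0:
            raise ConfigError("temperature must be positive")
        for p in [cfg.structure, cfg.parameters, cfg.domain_map,
                  *[q for v in cfg.states.values() for q in v]]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        return cfg


def _resolve(cfg_path: Path, p) -> Path | None:
    if p is None:
        return None
    p = Path(p)
    return p if p.is_absolute() else (cfg_path.parent / p)


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    version: str = __version__
    config: dict = field(default_factory=dict)

    def add_stage(self, name: str, status: str, seconds: float,
                  outputs: list[Path]) -> None:
        self.stages[name] = {
            "status": status,
            "seconds": round(seconds, 3),
            "outputs": [str(p) for p in outputs],
        }
        self.files.extend(str(p) for p in outputs)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "stages": self.stages,
                       "files": self.files, "config": self.config},
                      fh, indent=2, default=str)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Shared loading
# ---------------------------------------------------------------------------

def load_system(config: AnalysisConfig) -> tuple[io.Topology, io.DomainMap]:
    top, _frame = io.read_structure(config.structure)
    if config.parameters is not None:
        io.read_parameters(top, config.parameters)
    dmap = (io.read_domain_map(config.domain_map)
            if config.domain_map is not None else io.default_domain_map())
    return top, dmap


def load_state(config: AnalysisConfig, state: str,
               topology: io.Topology) -> io.Trajectory:
    """Window each replica then pool frames into one ensemble."""
    paths = config.states.get(state)
    if not paths:
        raise ConfigError(f"no trajectories configured for state {state!r}")
    pieces = [
        geo.discard_equilibration(io.read_trajectory(p, topology),
                                  config.discard_fraction)
        for p in paths
    ]
    coords = np.concatenate([t.coords for t in pieces], axis=0)
    n = coords.shape[0]
    dt = pieces[0].times[1] - pieces[0].times[0] if pieces[0].n_frames > 1 else 1.0
    return io.Trajectory(times=dt * np.arange(n), coords=coords)


def _selection_union(dmap: io.DomainMap, names: list[str],
                     topology: io.Topology, atom_filter: str) -> np.ndarray:
    idx: set[int] = set()
    for name in names:
        idx.update(io.resolve_selection(dmap, name, topology, atom_filter))
    return np.array(sorted(idx), dtype=int)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_entropy_stage(config: AnalysisConfig, report: RunReport,
                      dry_run: bool = False) -> list[Path]:
    """Per-domain Schlitter entropies per state, ΔS = S_PL − S_PD, and the
    configurational + solvent totals row when configured."""
    t0 = time.time()
    outdir = config.output_dir
    states = [s for s in ("PD", "PL") if s in config.states]
    if not states:
        states = list(config.states)
    outputs = [outdir / f"entropy_{s}.tsv" for s in states]
    if len(states) == 2:
        outputs.append(outdir / "entropy_delta.tsv")
    if dry_run:
        report.add_stage("entropy", "dry-run", time.time() - t0, outputs)
        return outputs

    top, dmap = load_system(config)
    fit = config.entropy_opts.get("fit", "domain")
    per_state: dict[str, dict[str, ent.EntropyResult]] = {}
    outdir.mkdir(parents=True, exist_ok=True)
    for s in states:
        traj = load_state(config, s, top)
        per_state[s] = ent.entropy_by_domain(traj, top, dmap,
                                             config.temperature, fit=fit)
        ent.write_entropy_table(
            [(name, r.S_config, r.uncertainty)
             for name, r in per_state[s].items()],
            outdir / f"entropy_{s}.tsv",
            header=("Domain", "S_config_J_per_K_mol", "uncertainty_J_per_K_mol"),
        )
    if len(states) == 2:
        if set(config.states) >= {"PD", "PL"}:
            a, b = "PD", "PL"
        else:
            a, b = states
        rows = [
            (name, per_state[b][name].S_config - per_state[a][name].S_config,
             per_state[a][name].uncertainty + per_state[b][name].uncertainty)
            for name in per_state[a]
        ]
        solvent = config.entropy_opts.get("solvent")
        if solvent:
            coeffs = ent.SolventEntropyCoefficients(
                a_polar=float(solvent["a_polar"]),
                a_apolar=float(solvent["a_apolar"]),
            )
            ds_solv = ent.solvent_entropy(
                float(solvent.get("delta_sas_polar", 0.0)),
                float(solvent.get("delta_sas_apolar", 0.0)), coeffs)
            whole = dict(rows)["all"]
            rows.append(("solvent", ds_solv, 0.0))
            rows.append(("total", ent.total_entropy(whole[0], ds_solv),
                         whole[1]))
        ent.write_entropy_table(
            rows, outdir / "entropy_delta.tsv",
            header=("Domain", "dS_J_per_K_mol", "uncertainty_J_per_K_mol"))
    elif len(states) == 1:
        logger.warning("only one state configured; wrote absolute entropies "
                       "without a ΔS table")
    report.add_stage("entropy", "ok", time.time() - t0, outputs)
    return outputs


def run_fda_stage(config: AnalysisConfig, report: RunReport,
                  dry_run: bool = False) -> list[Path]:
    """Residue-pair force tables per state and the ΔF table."""
    t0 = time.time()
    outdir = config.output_dir
    states = [s for s in ("PD", "PL") if s in config.states] or list(config.states)
    outputs = [outdir / f"forces_{s}.tsv" for s in states]
    outputs.append(outdir / "forces_delta.tsv")
    if dry_run:
        report.add_stage("fda", "dry-run", time.time() - t0, outputs)
        return outputs

    top, dmap = load_system(config)
    if not top.has_parameters:
        raise ConfigError(
            "force analysis requires charges and LJ parameters; configure "
            "topology.parameters with a sidecar file")
    opts = config.fda_opts
    g1 = _selection_union(dmap, list(opts.get("group1", ["TN", "Ag"])), top, "all")
    g2 = _selection_union(dmap, list(opts.get("group2", ["alpha1", "alpha2"])),
                          top, "all")
    params = mech.NonbondedParams(cutoff=float(opts.get("cutoff", 10.0)))
    threshold = float(opts.get("threshold", 200.0))
    scal = opts.get("scalarization", "signed-sum")
    tables: dict[str, mech.PairForceTable] = {}
    outdir.mkdir(parents=True, exist_ok=True)
    for s in states:
        traj = load_state(config, s, top)
        tables[s] = mech.residue_pair_forces(
            traj, top, g1, g2, params, threshold=threshold,
            scalarization=scal, group1_label="group1", group2_label="group2")
        with open(outdir / f"forces_{s}.tsv", "w") as fh:
            fh.write("residue_1\tresidue_2\tF_pN\tF_err_pN\n")
            for p in tables[s].pairs:
                fh.write(f"{mech.residue_label(p.residue_a)}\t"
                         f"{mech.residue_label(p.residue_b)}\t"
                         f"{p.F_mean:.6g}\t{p.F_err:.6g}\n")
    if len(tables) == 2:
        a, b = ("PD", "PL") if set(tables) >= {"PD", "PL"} else tuple(tables)
        delta = mech.delta_force_table(tables[a], tables[b])
    else:
        only = next(iter(tables.values()))
        delta = mech.delta_force_table(only, only)
    mech.write_force_table(delta, outdir / "forces_delta.tsv",
                           group1_label="group1", group2_label="group2")
    report.add_stage("fda", "ok", time.time() - t0, outputs)
    return outputs


def run_geometry_stage(config: AnalysisConfig, report: RunReport,
                       dry_run: bool = False) -> list[Path]:
    """Buried surface, named distances, fit/measure RMSD and RMSF per state."""
    t0 = time.time()
    outdir = config.output_dir
    opts = config.geometry_opts
    states = [s for s in ("PD", "PL") if s in config.states] or list(config.states)
    outputs: list[Path] = []
    planned: list[tuple] = []
    for s in states:
        for pair in opts.get("buried", []):
            planned.append(("buried", s, pair))
            outputs += [outdir / f"buried_{s}_{pair[0]}_{pair[1]}.tsv",
                        outdir / f"buried_{s}_{pair[0]}_{pair[1]}_hist.tsv"]
        for d in opts.get("distances", []):
            planned.append(("distance", s, d))
            outputs += [outdir / f"distance_{s}_{d['name']}.tsv",
                        outdir / f"distance_{s}_{d['name']}_hist.tsv"]
        if "rmsd" in opts:
            planned.append(("rmsd", s, opts["rmsd"]))
            outputs.append(outdir / f"rmsd_{s}.tsv")
        for sel in opts.get("rmsf", []):
            planned.append(("rmsf", s, sel))
            outputs.append(outdir / f"rmsf_{s}_{sel}.tsv")
    if dry_run:
        report.add_stage("geometry", "dry-run", time.time() - t0, outputs)
        return outputs

    top, dmap = load_system(config)
    outdir.mkdir(parents=True, exist_ok=True)
    sas_points = int(opts.get("sas_points", geo.DEFAULT_SAS_POINTS))
    trajs = {s: load_state(config, s, top) for s in states}
    for kind, s, payload in planned:
        traj = trajs[s]
        if kind == "buried":
            ga = io.resolve_selection(dmap, payload[0], top, "heavy")
            gb = io.resolve_selection(dmap, payload[1], top, "heavy")
            series = geo.buried_surface(traj, top, ga, gb, n_points=sas_points)
            if config.moving_avg_ps:
                series = geo.moving_average(series, config.moving_avg_ps)
            stem = f"buried_{s}_{payload[0]}_{payload[1]}"
            geo.write_timeseries(series, outdir / f"{stem}.tsv", "buried_A2")
            geo.write_histogram(series, outdir / f"{stem}_hist.tsv")
        elif kind == "distance":
            (series,) = geo.named_distances(
                traj, top, [(tuple(payload["a"]), tuple(payload["b"]))])
            stem = f"distance_{s}_{payload['name']}"
            geo.write_timeseries(series, outdir / f"{stem}.tsv", "distance_A")
            geo.write_histogram(series, outdir / f"{stem}_hist.tsv")
        elif kind == "rmsd":
            fit_sel = io.resolve_selection(dmap, payload["fit"], top, "CA")
            mea_sel = io.resolve_selection(dmap, payload["measure"], top, "CA")
            series = geo.rmsd_series(traj, geo.RmsdSpec(fit_sel, mea_sel, 0))
            geo.write_timeseries(series, outdir / f"rmsd_{s}.tsv", "rmsd_A")
        elif kind == "rmsf":
            sel = io.resolve_selection(dmap, payload, top, "CA")
            vals = geo.rmsf(traj, sel)
            with open(outdir / f"rmsf_{s}_{payload}.tsv", "w") as fh:
                fh.write("chain\tresidue\trmsf_A\n")
                for i, v in zip(sel, vals):
                    a = top.atoms[i]
                    fh.write(f"{a.chain_id}\t{a.residue_index}\t{v:.6g}\n")
    report.add_stage("geometry", "ok", time.time() - t0, outputs)
    return outputs


# ---------------------------------------------------------------------------
# Demo fixture generation (synth subcommand)
# ---------------------------------------------------------------------------

def generate_demo_fixture(outdir: Path, seed: int, n_frames: int = 200) -> list[Path]:
    """Write a small self-consistent PD/PL bead-complex fixture set:
    structure PDB, parameter sidecar, domain map and one DCD per state.
    In the PL state the second group sits 2 Å farther away, weakening
    every inter-group contact (and separating the d1 distance modes by
    2 Å, a miniature of the groove-width comparison)."""
    pos_a = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
    pos_b = pos_a + np.array([0.0, 0.0, 6.0])
    base = dict(
        positions_a=pos_a,
        charges_a=np.array([1.0, -0.5, 0.5]),
        charges_b=np.array([-1.0, 0.5, -0.5]),
        sigma_a=np.full(3, 0.32), sigma_b=np.full(3, 0.32),
        epsilon_a=np.full(3, 0.5), epsilon_b=np.full(3, 0.5),
        jitter=0.15, n_frames=n_frames,
    )
    spec_pd = syn.BeadComplexSpec(positions_b=pos_b, seed=seed, **base)
    spec_pl = syn.BeadComplexSpec(
        positions_b=pos_b + np.array([0.0, 0.0, 2.0]), seed=seed + 1, **base)
    outdir.mkdir(parents=True, exist_ok=True)
    top, traj_pd = syn.bead_complex(spec_pd)
    _, traj_pl = syn.bead_complex(spec_pl)
    files = [outdir / "complex.pdb", outdir / "complex.params",
             outdir / "domains.yaml", outdir / "pd.dcd", outdir / "pl.dcd",
             outdir / "config.yaml"]
    io.write_structure(top, traj_pd.coords[0], files[0])
    io.write_parameters(top, files[1])
    io.write_domain_map(io.DomainMap({
        "groupA": [("A", 1, 3)], "groupB": [("B", 1, 3)],
    }), files[2])
    io.write_trajectory(traj_pd, files[3])
    io.write_trajectory(traj_pl, files[4])
    with open(files[5], "w") as fh:
        yaml.safe_dump({
            "topology": {"structure": "complex.pdb",
                         "parameters": "complex.params"},
            "domain_map": "domains.yaml",
            "states": {"PD": ["pd.dcd"], "PL": ["pl.dcd"]},
            "output_dir": "out",
            "temperature": 300.0,
            "seed": seed,
            "fda": {"group1": ["groupA"], "group2": ["groupB"],
                    "cutoff": 10.0, "threshold": 0.0},
            "entropy": {"fit": "none"},
            "geometry": {"buried": [["groupA", "groupB"]],
                         "distances": [{"name": "d1", "a": ["A", 1, "CA"],
                                        "b": ["B", 1, "CA"]}],
                         "rmsd": {"fit": "groupA", "measure": "groupB"},
                         "rmsf": ["groupA"]},
        }, fh, sort_keys=False)
    return files


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _setup_logging(level: str) -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s", force=True)


def _run(stage_fns: list, config_path: str, dry_run: bool,
         print_table: bool) -> None:
    try:
        config = AnalysisConfig.from_yaml(config_path)
        _setup_logging(config.log_level)
        report = RunReport(config=config.raw)
        for fn in stage_fns:
            outs = fn(config, report, dry_run=dry_run)
            logger.info("%s: %d outputs", fn.__name__, len(outs))
            if print_table and not dry_run:
                for p in outs:
                    if str(p).endswith(".tsv") and Path(p).exists():
                        sys.stdout.write(f"# {p}\n" + Path(p).read_text())
        if not dry_run:
            config.output_dir.mkdir(parents=True, exist_ok=True)
            report.write(config.output_dir / "run_report.json")
    except (ConfigError, io.ParseError, FileNotFoundError, KeyError,
            ValueError) as exc:
        logger.error("%s", exc)
        raise SystemExit(1)
    except SystemExit:
        raise
    except Exception as exc:  # pragma: no cover - internal failure path
        logger.exception("internal error: %s", exc)
        raise SystemExit(2)


_cfg_opt = click.option("--config", "-c", "config_path", required=True,
                        type=click.Path(exists=True),
                        help="YAML analysis configuration")
_dry_opt = click.option("--dry-run", is_flag=True,
                        help="validate and list outputs without writing")
_print_opt = click.option("--print-table", is_flag=True,
                          help="echo TSV outputs to stdout")


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Comparative trajectory analysis of the tapasin-MHC I system."""


@main.command("entropy")
@_cfg_opt
@_dry_opt
@_print_opt
def cmd_entropy(config_path: str, dry_run: bool, print_table: bool) -> None:
    """Per-domain configurational entropy tables."""
    _run([run_entropy_stage], config_path, dry_run, print_table)


@main.command("fda")
@_cfg_opt
@_dry_opt
@_print_opt
def cmd_fda(config_path: str, dry_run: bool, print_table: bool) -> None:
    """Residue-pair force tables."""
    _run([run_fda_stage], config_path, dry_run, print_table)


@main.command("geometry")
@_cfg_opt
@_dry_opt
@_print_opt
def cmd_geometry(config_path: str, dry_run: bool, print_table: bool) -> None:
    """Buried surface, distances, RMSD and RMSF."""
    _run([run_geometry_stage], config_path, dry_run, print_table)


@main.command("all")
@_cfg_opt
@_dry_opt
@_print_opt
def cmd_all(config_path: str, dry_run: bool, print_table: bool) -> None:
    """Run every stage."""
    _run([run_entropy_stage, run_fda_stage, run_geometry_stage],
         config_path, dry_run, print_table)


@main.command("synth")
@click.option("--out", "-o", "outdir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-frames", default=200, show_default=True, type=int)
def cmd_synth(outdir: str, seed: int, n_frames: int) -> None:
    """Generate a small self-consistent PD/PL demo fixture set."""
    _setup_logging("INFO")
    files = generate_demo_fixture(Path(outdir), seed, n_frames)
    for f in files:
        logger.info("wrote %s", f)


if __name__ == "__main__":
    main()
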