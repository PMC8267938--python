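"""End-to-end analysis orchestration.

``run_analysis`` executes the full descriptor → ensemble-statistics →
landscape chain over one system (one topology plus one or more replicate
trajectories) and writes a report directory atomically (all files or none).
``compare_systems`` aggregates several reports into per-descriptor
mean ± SD tables, the induced D1 ranking, and a pairs × systems
hydrogen-bond occupancy matrix.

Replicates are analyzed independently and pooled; both views are written.
All tables use 6-significant-digit formatting so identical (inputs, config,
seed) reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .ensemble_stats import (DEFAULT_HBOND_PAIRS, HBondSpec, cluster_representative,
                             dccm, hbond_occupancy)
from .geometry import (D1_SPEC, D2_SPEC, D3_SPECS, Y239_DIHEDRAL_ATOMS,
                       DescriptorSeries, dihedral_series, distance_series,
                       rmsd_series, rmsf, rog_series)
from .landscape import (StateDefinition, classify_states, occupancy_table, pmf)
from .structure_io import (MolecularStructure, SelectionSpec, Trajectory,
                           read_pdb, read_xyz, write_frames)

__all__ = ["RunConfig", "AnalysisReport", "run_analysis", "compare_systems"]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Defaults reproduce the standard clamp-motion monitoring set: centroid
    distances D1 (42-48 vs 298-302), D2 (209-227 vs 363-365), D3
    (sidechains of 183 vs 239), the residue-239 CA-CB-CG-CD2 torsion, the
    five interface hydrogen-bond pairs, 0.1 Å landscape bins at 300 K, and
    state boundaries 9.5 / 12.0 Å.
    """

    system: str = "system"
    topology_path: Optional[str] = None
    trajectory_paths: Tuple[str, ...] = ()
    chain: Optional[str] = None
    temperature: float = 300.0
    bin_width: float = 0.1
    state_bounds: Tuple[float, float] = (9.5, 12.0)
    cluster_count: int = 3
    hbond_pairs: Tuple[Tuple[str, int, int], ...] = DEFAULT_HBOND_PAIRS
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        d = json.loads(text)
        if "trajectory_paths" in d:
            d["trajectory_paths"] = tuple(d["trajectory_paths"])
        if "state_bounds" in d:
            d["state_bounds"] = tuple(d["state_bounds"])
        if "hbond_pairs" in d:
            d["hbond_pairs"] = tuple(tuple(p) for p in d["hbond_pairs"])
        return RunConfig(**d)


@dataclass
class AnalysisReport:
    """In-memory results of one system plus the written report directory."""

    system: str
    config: RunConfig
    descriptors: Dict[str, DescriptorSeries]
    rmsf_series: DescriptorSeries
    dccm_matrix: "object"
    hbond_occupancies: Dict[str, float]
    state_occupancy: Dict[str, float]
    pmf_1d: "object"
    pmf_2d: "object"
    representatives: Dict[str, List[int]]
    out_dir: Optional[str] = None


def _load_trajectory(path: str, topology: Optional[MolecularStructure]):
    if path.endswith(".xyz"):
        return read_xyz(path, topology=topology)
    loaded = read_pdb(path, model_policy="all")
    if isinstance(loaded, MolecularStructure):
        loaded = Trajectory(topology=loaded, coords=loaded.coord[None])
    return loaded


def _analyze_one(traj: Trajectory, config: RunConfig, warnings: List[str]):
    """Descriptor chain for a single (replicate or pooled) trajectory."""
    chain = config.chain
    descriptors: Dict[str, DescriptorSeries] = {}
    descriptors["RoG"] = rog_series(traj, SelectionSpec(chain=chain))

    def preset(name, builder):
        try:
            descriptors[name] = builder()
        except (ValueError, KeyError) as exc:
            warnings.append(f"preset {name} skipped: {exc}")

    preset("D1", lambda: distance_series(
        traj, _with_chain(D1_SPEC[0], chain), _with_chain(D1_SPEC[1], chain),
        name="D1"))
    preset("D2", lambda: distance_series(
        traj, _with_chain(D2_SPEC[0], chain), _with_chain(D2_SPEC[1], chain),
        name="D2"))
    preset("D3", lambda: distance_series(
        traj, _with_chain(D3_SPECS[0], chain), _with_chain(D3_SPECS[1], chain),
        name="D3"))
    res, atoms = Y239_DIHEDRAL_ATOMS
    preset("dihedral_Y239", lambda: dihedral_series(
        traj, res, atoms, chain=chain, name="dihedral_Y239"))
    descriptors["RMSD"] = rmsd_series(traj, selection=SelectionSpec(
        chain=chain, atom_names=frozenset({"CA"})))

    fluct = rmsf(traj, SelectionSpec(chain=chain)) if traj.n_frames >= 2 else None
    cc = dccm(traj, SelectionSpec(chain=chain)) if traj.n_frames >= 2 else None

    hb: Dict[str, float] = {}
    masks: Dict[str, np.ndarray] = {}
    for label, donor, acceptor in config.hbond_pairs:
        spec = HBondSpec(label=label, donor_residue=donor,
                         acceptor_residue=acceptor, chain=chain)
        try:
            occ = hbond_occupancy(traj, spec)
        except KeyError as exc:
            warnings.append(f"hbond pair {label} skipped: {exc}")
            continue
        hb[label] = occ.occupancy
        masks[label] = occ.mask

    states = StateDefinition(*config.state_bounds)
    pmf1 = pmf2 = None
    occ_tab = None
    if "D1" in descriptors:
        labels = classify_states(descriptors["D1"], states)
        occ_tab = occupancy_table(labels)
        pmf1 = pmf(descriptors["D1"], bin_width=config.bin_width,
                   temperature=config.temperature)
        pmf2 = pmf(descriptors["D1"], descriptors["RMSD"],
                   bin_width=config.bin_width, temperature=config.temperature)

    reps: Dict[str, List[int]] = {}
    k = min(config.cluster_count, len(np.unique(descriptors["RoG"].values)))
    if k >= 1:
        try:
            _, rep_idx = cluster_representative(descriptors["RoG"], k,
                                                seed=config.seed)
            reps["RoG"] = [int(i) for i in rep_idx]
        except ValueError as exc:
            warnings.append(f"clustering skipped: {exc}")
    return descriptors, fluct, cc, hb, masks, occ_tab, pmf1, pmf2, reps


def _with_chain(spec: SelectionSpec, chain):
    if chain is None:
        return spec
    from dataclasses import replace

    return replace(spec, chain=chain)


def run_analysis(
    config: RunConfig,
    out_dir: Optional[str] = None,
    trajectories: Optional[Sequence[Trajectory]] = None,
    topology: Optional[MolecularStructure] = None,
) -> AnalysisReport:
    """Run the full analysis for one system.

    Inputs may be given as paths in the config or directly as in-memory
    trajectories.  When ``out_dir`` is set, the report directory is written
    atomically: results land in a temporary sibling first and are renamed
    into place, so a failed run leaves no partial report.
    """
    warnings: List[str] = []
    if trajectories is None:
        if topology is None and config.topology_path:
            topology = read_pdb(config.topology_path, model_policy="first")
        if not config.trajectory_paths:
            raise ValueError("no trajectories given")
        for p in config.trajectory_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        trajectories = [_load_trajectory(p, topology)
                        for p in config.trajectory_paths]
    n_atoms = trajectories[0].topology.n_atoms
    for t in trajectories:
        if t.coords.shape[1] != n_atoms:
            raise ValueError("replicate trajectories disagree on atom count")

    pooled = (trajectories[0] if len(trajectories) == 1 else Trajectory(
        topology=trajectories[0].topology,
        coords=np.concatenate([t.coords for t in trajectories], axis=0),
        frame_interval_ps=trajectories[0].frame_interval_ps))

    per_replicate = [_analyze_one(t, config, warnings) for t in trajectories]
    (descriptors, fluct, cc, hb, masks, occ_tab, pmf1, pmf2, reps) = (
        per_replicate[0] if len(trajectories) == 1
        else _analyze_one(pooled, config, warnings))

    report = AnalysisReport(
        system=config.system, config=config, descriptors=descriptors,
        rmsf_series=fluct, dccm_matrix=cc, hbond_occupancies=hb,
        state_occupancy=(occ_tab.fractions if occ_tab else {}),
        pmf_1d=pmf1, pmf_2d=pmf2, representatives=reps)

    if out_dir is not None:
        parent = os.path.dirname(os.path.abspath(out_dir)) or "."
        os.makedirs(parent, exist_ok=True)
        tmp = tempfile.mkdtemp(prefix=".clampmd-", dir=parent)
        try:
            _write_report(tmp, report, per_replicate, trajectories,
                          masks, warnings)
            if os.path.exists(out_dir):
                shutil.rmtree(out_dir)
            os.rename(tmp, out_dir)
        except Exception:
            shutil.rmtree(tmp, ignore_errors=True)
            raise
        report.out_dir = out_dir
    return report


def _write_report(out, report, per_replicate, trajectories, masks, warnings):
    cfg = report.config
    for name, series in report.descriptors.items():
        series.to_csv(os.path.join(out, f"descriptor_{name}.csv"))
    if len(per_replicate) > 1:
        for r, (desc, *_rest) in enumerate(per_replicate):
            for name, series in desc.items():
                series.to_csv(os.path.join(out, f"replicate{r}_{name}.csv"))
    if report.rmsf_series is not None:
        df = pd.DataFrame({
            "residue": report.rmsf_series.residue_numbers,
            "rmsf_A": report.rmsf_series.values,
        })
        df.to_csv(os.path.join(out, "rmsf.csv"), index=False,
                  float_format=_FLOAT_FMT)
    if report.dccm_matrix is not None:
        report.dccm_matrix.to_frame().to_csv(
            os.path.join(out, "dccm.csv"), float_format=_FLOAT_FMT)
    if report.hbond_occupancies:
        pd.DataFrame({
            "pair": list(report.hbond_occupancies),
            report.system: list(report.hbond_occupancies.values()),
        }).to_csv(os.path.join(out, "hbond_occupancy.csv"), index=False,
                  float_format=_FLOAT_FMT)
        pd.DataFrame({k: v.astype(int) for k, v in masks.items()}).to_csv(
            os.path.join(out, "hbond_masks.csv"), index=False)
    if report.state_occupancy:
        pd.DataFrame({
            "state": list(report.state_occupancy),
            "occupancy_percent": list(report.state_occupancy.values()),
        }).to_csv(os.path.join(out, "state_occupancy.csv"), index=False,
                  float_format=_FLOAT_FMT)
    for tag, grid in (("1d", report.pmf_1d), ("2d", report.pmf_2d)):
        if grid is None:
            continue
        df = grid.to_frame()
        df.loc[~df["occupied"], "delta_G_kcal_mol"] = np.nan  # blank, not capped
        df.to_csv(os.path.join(out, f"pmf_{tag}.csv"), index=False,
                  float_format=_FLOAT_FMT)
        sidecar = {"axes": list(grid.axis_names), "units": list(grid.axis_units),
                   "temperature_K": grid.temperature,
                   "bin_width": cfg.bin_width}
        with open(os.path.join(out, f"pmf_{tag}.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
    for name, frames in report.representatives.items():
        for rank, fidx in enumerate(frames):
            sub = Trajectory(topology=trajectories[0].topology,
                             coords=_pooled_frame(trajectories, fidx)[None],
                             frame_interval_ps=trajectories[0].frame_interval_ps)
            with open(os.path.join(out,
                                   f"representative_{name}_{rank}.pdb"), "w") as fh:
                fh.write(write_frames(sub, format="pdb"))
    provenance = {
        "system": report.system,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "seed": cfg.seed,
        "software_version": __version__,
        "warnings": warnings,
        "representative_frames": report.representatives,
    }
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    with open(os.path.join(out, "config.json"), "w") as fh:
        fh.write(cfg.to_json())


def _pooled_frame(trajectories, fidx):
    for t in trajectories:
        if fidx < t.n_frames:
            return t.coords[fidx]
        fidx -= t.n_frames
    raise IndexError("representative frame index out of range")


def compare_systems(reports: Sequence[AnalysisReport]) -> Dict[str, pd.DataFrame]:
    """Cross-system summary: per-descriptor mean ± SD, the D1-mean ranking
    (largest hinge opening first), and a pairs × systems occupancy matrix."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    names = set(reports[0].descriptors)
    for r in reports[1:]:
        if set(r.descriptors) != names:
            raise ValueError("reports have mismatched descriptor definitions")
    rows = []
    for r in reports:
        for name, series in r.descriptors.items():
            rows.append({"system": r.system, "descriptor": name,
                         "mean": float(series.values.mean()),
                         "sd": float(series.values.std(ddof=0))})
    summary = pd.DataFrame(rows)
    d1 = summary[summary["descriptor"] == "D1"].sort_values(
        "mean", ascending=False)
    ranking = pd.DataFrame({"rank": np.arange(1, len(d1) + 1),
                            "system": d1["system"].to_numpy(),
                            "mean_D1_A": d1["mean"].to_numpy()})
    occ = pd.DataFrame({r.system: pd.Series(r.hbond_occupancies)
                        for r in reports})
    states = pd.DataFrame({r.system: pd.Series(r.state_occupancy)
                           for r in reports})
    return {"summary": summary, "ranking": ranking,
            "hbond_occupancy": occ, "state_occupancy": states}
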