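"""Trajectory-level statistics: cross-correlation maps, hydrogen-bond
occupancy, and descriptor-based clustering for representative frames.

The dynamic cross-correlation map (DCCM) is the normalized covariance of
per-residue CA displacement vectors after superposing every frame onto the
trajectory-average structure:

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

Hydrogen bonds are detected geometrically.  A residue pair is counted as
bonded in a frame when ANY candidate donor/acceptor heavy-atom combination
(in either direction) satisfies a heavy-heavy distance cutoff (default
3.5 Å) and, when hydrogens are present, a donor-H-acceptor angle cutoff
(default 135°).  Structures without hydrogens fall back to the distance
criterion alone.  Occupancy is the exact percentage of frames in which the
bond is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .geometry import DescriptorSeries, _average_structure
from .structure_io import MolecularStructure, SelectionSpec, Trajectory, resolve_selection

__all__ = [
    "DCCMatrix",
    "HBondSpec",
    "HBondOccupancy",
    "dccm",
    "detect_hbond",
    "hbond_occupancy",
    "cluster_representative",
    "DEFAULT_HBOND_PAIRS",
]

# Donor/acceptor heavy-atom candidates per residue type, covering the
# interface pairs monitored in the two-lobe clamp analysis.  Backbone N is a
# donor and backbone O an acceptor for every residue.
_SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "SER": ("OG",),
    "THR": ("OG1",), "TYR": ("OH",), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",), "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}

# The five interface pairs monitored by default: (donor residue, acceptor
# residue) in author numbering, labelled the way the field labels them.
DEFAULT_HBOND_PAIRS = (
    ("R14-D262", 14, 262),
    ("M242-R265", 242, 265),
    ("A188-H404", 188, 404),
    ("S44-V193", 44, 193),
    ("K42-E295", 42, 295),
)


@dataclass
class DCCMatrix:
    """Residue-labelled cross-correlation matrix.

    ``undefined`` flags residues with zero displacement variance, whose
    entries are reported as 0.
    """

    residue_numbers: np.ndarray
    matrix: np.ndarray
    undefined: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("DCCM must be square")
        self.matrix = m

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.residue_numbers,
                            columns=self.residue_numbers)


@dataclass(frozen=True)
class HBondSpec:
    """Geometric hydrogen-bond criteria for one residue pair.

    ``donor_atoms`` / ``acceptor_atoms`` override the per-residue-type
    candidate tables; ``mode='heavy-only'`` drops the angle criterion (used
    for hydrogen-free structures).  The pair is evaluated in both directions
    (either residue may donate).
    """

    label: str
    donor_residue: int
    acceptor_residue: int
    chain: Optional[str] = None
    donor_atoms: Optional[Tuple[str, ...]] = None
    acceptor_atoms: Optional[Tuple[str, ...]] = None
    distance_cutoff: float = 3.5
    angle_cutoff: float = 135.0
    mode: str = "auto"  # auto | with-hydrogens | heavy-only

    def __post_init__(self) -> None:
        if not self.distance_cutoff > 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


class ResidueLookupError(KeyError):
    """A residue named in an HBondSpec is absent from the topology."""


def _residue_atoms(structure: MolecularStructure, resnum: int,
                   chain: Optional[str]) -> np.ndarray:
    spec = SelectionSpec.residues(resnum, chain=chain, atom_class="all")
    idx = resolve_selection(structure, spec)
    if len(idx) == 0:
        raise ResidueLookupError(f"residue {resnum} not found in topology")
    return idx


def _candidates(structure: MolecularStructure, idx: np.ndarray,
                table: dict, override: Optional[Tuple[str, ...]],
                backbone_atom: str) -> np.ndarray:
    names = structure.atom_name[idx]
    resname = str(structure.res_name[idx[0]]).upper()
    if override is not None:
        wanted = set(override)
    else:
        wanted = set(table.get(resname, ())) | {backbone_atom}
    return idx[np.isin(names, list(wanted))]


def _attached_hydrogens(structure: MolecularStructure, coords: np.ndarray,
                        heavy: int, residue_idx: np.ndarray) -> np.ndarray:
    """Hydrogens of the same residue within 1.2 Å of the donor heavy atom,
    with a name beginning H (after digits)."""
    hyd = residue_idx[structure.is_hydrogen()[residue_idx]]
    if len(hyd) == 0:
        return hyd
    d = np.linalg.norm(coords[hyd] - coords[heavy], axis=1)
    return hyd[d <= 1.2]


def _pair_satisfied(structure, coords, don_res_idx, acc_res_idx,
                    spec: HBondSpec, use_hydrogens: bool) -> bool:
    donors = _candidates(structure, don_res_idx, _SIDECHAIN_DONORS,
                         spec.donor_atoms, "N")
    acceptors = _candidates(structure, acc_res_idx, _SIDECHAIN_ACCEPTORS,
                            spec.acceptor_atoms, "O")
    cos_cut = np.cos(np.radians(spec.angle_cutoff))
    for d in donors:
        for a in acceptors:
            dist = np.linalg.norm(coords[a] - coords[d])
            if dist > spec.distance_cutoff or dist < 1e-6:
                continue
            if not use_hydrogens:
                return True
            for h in _attached_hydrogens(structure, coords, d, don_res_idx):
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 < 1e-9 or n2 < 1e-9:
                    continue
                cos_ang = float(v1 @ v2) / (n1 * n2)
                # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
                if cos_ang <= cos_cut + 1e-12:
                    return True
    return False


def detect_hbond(structure: MolecularStructure, coords: np.ndarray,
                 spec: HBondSpec) -> bool:
    """True iff the residue pair forms a hydrogen bond in this frame.

    Both donation directions are tried.  ``mode='auto'`` uses the angle
    criterion when the structure contains any hydrogens, else heavy-only.
    """
    coords = np.asarray(coords, dtype=float)
    don_idx = _residue_atoms(structure, spec.donor_residue, spec.chain)
    acc_idx = _residue_atoms(structure, spec.acceptor_residue, spec.chain)
    if spec.mode == "with-hydrogens":
        use_h = True
    elif spec.mode == "heavy-only":
        use_h = False
    elif spec.mode == "auto":
        use_h = bool(structure.is_hydrogen().any())
    else:
        raise ValueError(f"unknown hbond mode {spec.mode!r}")
    if _pair_satisfied(structure, coords, don_idx, acc_idx, spec, use_h):
        return True
    # reversed polarity: acceptor residue donates
    rev = HBondSpec(label=spec.label, donor_residue=spec.acceptor_residue,
                    acceptor_residue=spec.donor_residue, chain=spec.chain,
                    donor_atoms=spec.acceptor_atoms,
                    acceptor_atoms=spec.donor_atoms,
                    distance_cutoff=spec.distance_cutoff,
                    angle_cutoff=spec.angle_cutoff, mode=spec.mode)
    return _pair_satisfied(structure, coords, acc_idx, don_idx, rev, use_h)


@dataclass
class HBondOccupancy:
    """Occupancy (exact percent of frames bonded) plus the per-frame mask."""

    label: str
    occupancy: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = 100.0 * self.mask.sum() / len(self.mask)
        if abs(expected - self.occupancy) > 1e-9:
            raise ValueError("occupancy inconsistent with mask")


def hbond_occupancy(trajectory: Trajectory, spec: HBondSpec) -> HBondOccupancy:
    """Fraction of frames (as a percentage) in which the pair is bonded."""
    top = trajectory.topology
    mask = np.array([
        detect_hbond(top, trajectory.coords[f], spec)
        for f in range(trajectory.n_frames)
    ])
    return HBondOccupancy(label=spec.label,
                          occupancy=100.0 * mask.sum() / len(mask),
                          mask=mask)


def dccm(
    trajectory: Trajectory,
    selection: Optional[SelectionSpec] = None,
    fit_selection: Optional[SelectionSpec] = None,
) -> DCCMatrix:
    """Dynamic cross-correlation map over CA atoms.

    Frames are superposed onto the iterated average structure first, so the
    map is invariant under global rigid motion of the input frames.
    """
    if trajectory.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    top = trajectory.topology
    sel_spec = selection or SelectionSpec(atom_class="all")
    ca_spec = SelectionSpec(chain=sel_spec.chain,
                            residue_intervals=sel_spec.residue_intervals,
                            atom_names=frozenset({"CA"}), atom_class="heavy")
    ca_idx = resolve_selection(top, ca_spec)
    if len(ca_idx) < 2:
        raise ValueError("DCCM needs at least 2 residues with CA atoms")
    fit_idx = (resolve_selection(top, fit_selection)
               if fit_selection is not None else ca_idx)
    fitted = _average_structure(trajectory, fit_idx, top.mass[fit_idx])
    x = fitted[:, ca_idx]                       # (F, R, 3)
    dx = x - x.mean(axis=0)
    cov = np.einsum("fid,fjd->ij", dx, dx) / trajectory.n_frames
    var = np.einsum("fid,fid->i", dx, dx) / trajectory.n_frames
    undefined = var <= 1e-300
    denom = np.sqrt(np.outer(np.where(undefined, 1.0, var),
                             np.where(undefined, 1.0, var)))
    mat = cov / denom
    mat[undefined, :] = 0.0
    mat[:, undefined] = 0.0
    np.fill_diagonal(mat, np.where(undefined, 0.0, 1.0))
    mat = np.clip(mat, -1.0, 1.0)
    mat = (mat + mat.T) / 2.0
    return DCCMatrix(residue_numbers=top.res_id[ca_idx], matrix=mat,
                     undefined=undefined)


# ---------------------------------------------------------------------------
# 1-D k-means for representative frames
# ---------------------------------------------------------------------------

class DegenerateClusteringError(ValueError):
    """k exceeds the number of distinct series values."""


def cluster_representative(series: DescriptorSeries, k: int, seed: int = 0):
    """Deterministic 1-D k-means over a descriptor series.

    Seeding is farthest-point (k-means++ style, made deterministic by the
    seed choosing the first center); Lloyd iterations run to convergence at
    1e-6 or 100 iterations.  The representative of each cluster is the frame
    whose value is nearest the cluster mean; ties resolve to the earliest
    frame.  Returns ``(labels, representative_frame_indices)`` with clusters
    ordered by ascending center value.
    """
    values = np.asarray(series.values, dtype=float)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("series shorter than k")
    if len(np.unique(values)) < k:
        raise DegenerateClusteringError(
            f"k={k} exceeds {len(np.unique(values))} distinct values")
    rng = np.random.default_rng(seed)
    centers = [values[int(rng.integers(n))]]
    while len(centers) < k:
        d = np.min(np.abs(values[:, None] - np.array(centers)[None, :]), axis=1)
        centers.append(values[int(np.argmax(d))])  # farthest point, first on tie
    centers = np.array(centers)
    for _ in range(100):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array([
            values[labels == c].mean() if np.any(labels == c) else centers[c]
            for c in range(k)
        ])
        if np.max(np.abs(new - centers)) < 1e-6:
            centers = new
            break
        centers = new
    order = np.argsort(centers)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)]
    centers = centers[order]
    reps = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        dist = np.abs(values[members] - centers[c])
        reps.append(int(members[np.argmin(dist)]))  # argmin -> earliest on tie
    return labels, np.array(reps)
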