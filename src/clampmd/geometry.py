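"""Per-frame geometric descriptors of domain motion.

Implements the standard trajectory-analysis observables: weighted optimal
rigid-body superposition (Kabsch), mass-weighted RMSD

    RMSD = sqrt( sum_i m_i |X_i - Y_i|^2 / M ),    M = sum_i m_i,

radius of gyration, centroid-centroid group distances (with the D1/D2/D3
presets used to monitor the clamp-like motion of a two-lobed
methyltransferase), torsion angles mapped to [0, 360) degrees, and
per-residue RMSF against the iterated average structure.

The D1/D2/D3 presets encode the monitoring distances of the SMYD3 CTD
hinge: D1 spans the top of the substrate cleft (MYND domain residues 42-48
to CTD residues 298-302), D2 the bottom (SET residues 209-227 to CTD
residues 363-365), and D3 the lysine-channel width (sidechain centroids of
residues 183 and 239).  Centroids are mass-weighted over heavy atoms by
default; a geometric (unweighted) mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import MolecularStructure, SelectionSpec, Trajectory, resolve_selection

__all__ = [
    "DescriptorSeries",
    "SuperpositionResult",
    "superpose",
    "rmsd",
    "radius_of_gyration",
    "group_distance",
    "dihedral",
    "rmsf",
    "rmsd_series",
    "rog_series",
    "distance_series",
    "dihedral_series",
    "D1_SPEC",
    "D2_SPEC",
    "D3_SPECS",
    "Y239_DIHEDRAL_ATOMS",
]

# Preset selections for the clamp-motion descriptors (author numbering).
D1_SPEC = (SelectionSpec.residues((42, 48)), SelectionSpec.residues((298, 302)))
D2_SPEC = (SelectionSpec.residues((209, 227)), SelectionSpec.residues((363, 365)))
D3_SPECS = (
    SelectionSpec.residues(183, atom_class="sidechain"),
    SelectionSpec.residues(239, atom_class="sidechain"),
)
# The monitored tyrosine ring torsion: chi-2-like CA-CB-CG-CD2 of residue 239.
Y239_DIHEDRAL_ATOMS = (239, ("CA", "CB", "CG", "CD2"))


@dataclass
class DescriptorSeries:
    """A named per-frame scalar observable with units (Å or degrees)."""

    name: str
    units: str
    values: np.ndarray
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in descriptor {self.name!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval_ps

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frame_index": np.arange(len(self.values)),
            "time_ps": self.times_ps,
            "value": self.values,
        })

    def to_csv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# name={self.name} units={self.units}\n")
            df.to_csv(fh, index=False, float_format="%.6g")


@dataclass
class SuperpositionResult:
    """A proper rigid transform fitted by weighted Kabsch.

    ``transformed`` holds the full mobile frame after applying
    ``x -> rotation @ (x - mobile_center) + ref_center``; ``fit_rmsd`` is the
    weighted RMSD over the fit selection after the transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    transformed: np.ndarray
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


class FitError(ValueError):
    """Degenerate superposition input (too few or collinear fit atoms)."""


class DegenerateGeometryError(ValueError):
    """Collinear atoms where a torsion/angle is undefined."""


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (w[:, None] * x).sum(axis=0) / w.sum()


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: Optional[Sequence[int]] = None,
    weights: Optional[np.ndarray] = None,
) -> SuperpositionResult:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    ``fit_selection`` indexes both frames (equal length after indexing);
    ``weights`` (typically masses) apply to the fit atoms.  Reflections are
    excluded; det(rotation) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = (np.arange(len(mobile)) if fit_selection is None
           else np.asarray(fit_selection, dtype=int))
    mob = mobile[sel]
    ref_sel = reference[sel] if reference.shape[0] == mobile.shape[0] else reference
    if mob.shape != ref_sel.shape:
        raise FitError("fit selections have different lengths")
    if len(mob) < 3:
        raise FitError("superposition needs at least 3 fit atoms")
    w = np.ones(len(mob)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(mob):
        raise FitError("weights length does not match fit selection")
    mob_c = _weighted_mean(mob, w)
    ref_c = _weighted_mean(ref_sel, w)
    a = mob - mob_c
    b = ref_sel - ref_c
    # collinearity check: rank of the weighted coordinate cloud
    if np.linalg.matrix_rank(a * np.sqrt(w)[:, None], tol=1e-9) < 2:
        raise FitError("fit atoms are collinear or coincident")
    rot, _ = Rotation.align_vectors(b, a, weights=w)
    R = rot.as_matrix()
    translation = ref_c - R @ mob_c
    transformed = mobile @ R.T + translation
    diff = transformed[sel] - ref_sel
    fit_rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum() / w.sum()))
    return SuperpositionResult(rotation=R, translation=translation,
                               transformed=transformed, fit_rmsd=fit_rmsd)


def rmsd(
    X: np.ndarray,
    Y: np.ndarray,
    selection: Optional[Sequence[int]] = None,
    masses: Optional[np.ndarray] = None,
    fit: bool = True,
    fit_selection: Optional[Sequence[int]] = None,
) -> float:
    """Mass-weighted RMSD between frames ``X`` (mobile) and ``Y`` (reference).

    With ``fit=True`` the mobile frame is first superposed onto the
    reference over ``fit_selection`` (defaults to ``selection``) using the
    same weights.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    sel = np.arange(len(X)) if selection is None else np.asarray(selection, int)
    if len(sel) == 0:
        raise ValueError("empty selection for RMSD")
    m_all = np.ones(len(X)) if masses is None else np.asarray(masses, float)
    if fit:
        fsel = sel if fit_selection is None else np.asarray(fit_selection, int)
        res = superpose(X, Y, fit_selection=fsel, weights=m_all[fsel])
        X = res.transformed
    m = m_all[sel]
    d2 = ((X[sel] - Y[sel]) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def radius_of_gyration(
    coords: np.ndarray,
    selection: Optional[Sequence[int]] = None,
    masses: Optional[np.ndarray] = None,
) -> float:
    """Mass-weighted RMS distance of the selected atoms from their centroid."""
    coords = np.asarray(coords, dtype=float)
    sel = np.arange(len(coords)) if selection is None else np.asarray(selection, int)
    if len(sel) == 0:
        raise ValueError("empty selection for radius of gyration")
    m = (np.ones(len(sel)) if masses is None
         else np.asarray(masses, float)[sel] if len(masses) == len(coords)
         else np.asarray(masses, float))
    x = coords[sel]
    c = _weighted_mean(x, m)
    r2 = ((x - c) ** 2).sum(axis=1)
    return float(np.sqrt((m * r2).sum() / m.sum()))


def group_distance(
    coords: np.ndarray,
    selection_a: Sequence[int],
    selection_b: Sequence[int],
    masses: Optional[np.ndarray] = None,
    weighting: str = "mass",
    preset: str = "",
) -> float:
    """Distance between the (weighted) centroids of two atom groups."""
    coords = np.asarray(coords, dtype=float)
    sa = np.asarray(selection_a, int)
    sb = np.asarray(selection_b, int)
    label = f" for preset {preset}" if preset else ""
    if len(sa) == 0:
        raise ValueError(f"empty selection A{label}")
    if len(sb) == 0:
        raise ValueError(f"empty selection B{label}")
    if weighting == "mass":
        if masses is None:
            raise ValueError("mass weighting requires masses")
        m = np.asarray(masses, float)
        ca = _weighted_mean(coords[sa], m[sa])
        cb = _weighted_mean(coords[sb], m[sb])
    elif weighting == "geometric":
        ca = coords[sa].mean(axis=0)
        cb = coords[sb].mean(axis=0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(np.linalg.norm(ca - cb))


def dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle a-b-c-d in degrees, mapped to [0, 360).

    The IUPAC sign convention is used before mapping, so a trans arrangement
    is 180° and the mirror of an angle θ is 360 - θ.
    """
    coords = np.asarray(coords, dtype=float)
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear atoms in dihedral")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang % 360.0)


def _average_structure(traj: Trajectory, fit_selection: np.ndarray,
                       weights: np.ndarray) -> np.ndarray:
    """Two-pass iterated average: fit all frames to frame 0, average, refit
    to the average, re-average."""
    ref = traj.coords[0]
    fitted = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        fitted[f] = superpose(traj.coords[f], ref, fit_selection,
                              weights).transformed
    avg = fitted.mean(axis=0)
    for f in range(traj.n_frames):
        fitted[f] = superpose(traj.coords[f], avg, fit_selection,
                              weights).transformed
    return fitted


def rmsf(
    trajectory: Trajectory,
    selection: Optional[SelectionSpec] = None,
    fit_selection: Optional[SelectionSpec] = None,
) -> DescriptorSeries:
    """Per-residue RMSF of CA atoms about the iterated average structure.

    Returned series is indexed by residue (``times_ps`` is meaningless);
    the residue numbers are stored in ``values_index``-order matching the
    topology's CA order.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = trajectory.topology
    sel_spec = selection or SelectionSpec(atom_class="all")
    ca_spec = SelectionSpec(chain=sel_spec.chain,
                            residue_intervals=sel_spec.residue_intervals,
                            atom_names=frozenset({"CA"}),
                            atom_class="heavy")
    ca_idx = resolve_selection(top, ca_spec)
    if len(ca_idx) == 0:
        raise ValueError("selection contains no CA atoms")
    fit_spec = fit_selection or ca_spec
    fit_idx = resolve_selection(top, fit_spec)
    fitted = _average_structure(trajectory, fit_idx, top.mass[fit_idx])
    mean_pos = fitted[:, ca_idx].mean(axis=0)
    dev2 = ((fitted[:, ca_idx] - mean_pos) ** 2).sum(axis=2)
    values = np.sqrt(dev2.mean(axis=0))
    series = DescriptorSeries(name="RMSF", units="A", values=values,
                              frame_interval_ps=trajectory.frame_interval_ps)
    series.residue_numbers = top.res_id[ca_idx]
    return series


# ---------------------------------------------------------------------------
# Series builders over trajectories
# ---------------------------------------------------------------------------

def rmsd_series(
    trajectory: Trajectory,
    reference: Optional[np.ndarray] = None,
    selection: Optional[SelectionSpec] = None,
    fit: bool = True,
    name: str = "RMSD",
) -> DescriptorSeries:
    """Per-frame mass-weighted RMSD to a reference frame (default frame 0),
    by default over CA atoms with best-fit superposition."""
    top = trajectory.topology
    spec = selection or SelectionSpec(atom_names=frozenset({"CA"}))
    idx = resolve_selection(top, spec)
    if len(idx) == 0:
        raise ValueError("empty RMSD selection")
    ref = trajectory.coords[0] if reference is None else np.asarray(reference)
    vals = [rmsd(trajectory.coords[f], ref, selection=idx, masses=top.mass,
                 fit=fit) for f in range(trajectory.n_frames)]
    return DescriptorSeries(name=name, units="A", values=np.array(vals),
                            frame_interval_ps=trajectory.frame_interval_ps)


def rog_series(trajectory: Trajectory,
               selection: Optional[SelectionSpec] = None) -> DescriptorSeries:
    top = trajectory.topology
    spec = selection or SelectionSpec(atom_class="heavy")
    idx = resolve_selection(top, spec)
    vals = [radius_of_gyration(trajectory.coords[f], idx, top.mass)
            for f in range(trajectory.n_frames)]
    return DescriptorSeries(name="RoG", units="A", values=np.array(vals),
                            frame_interval_ps=trajectory.frame_interval_ps)


def distance_series(
    trajectory: Trajectory,
    spec_a: SelectionSpec,
    spec_b: SelectionSpec,
    weighting: str = "mass",
    name: str = "distance",
) -> DescriptorSeries:
    """Per-frame centroid-centroid distance between two selections.

    Use with :data:`D1_SPEC` / :data:`D2_SPEC` / :data:`D3_SPECS` for the
    clamp-motion presets.
    """
    top = trajectory.topology
    ia = resolve_selection(top, spec_a)
    ib = resolve_selection(top, spec_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty selection for preset {name}")
    vals = [group_distance(trajectory.coords[f], ia, ib, top.mass,
                           weighting=weighting, preset=name)
            for f in range(trajectory.n_frames)]
    return DescriptorSeries(name=name, units="A", values=np.array(vals),
                            frame_interval_ps=trajectory.frame_interval_ps)


def dihedral_series(
    trajectory: Trajectory,
    residue: int,
    atom_names: Sequence[str],
    chain: Optional[str] = None,
    name: str = "dihedral",
) -> DescriptorSeries:
    """Per-frame torsion over four named atoms of one residue."""
    top = trajectory.topology
    idx = []
    for an in atom_names:
        spec = SelectionSpec.residues(residue, chain=chain,
                                      atom_names={an}, atom_class="all")
        found = resolve_selection(top, spec)
        if len(found) != 1:
            raise ValueError(
                f"residue {residue} atom {an}: expected 1 atom, found {len(found)}"
            )
        idx.append(int(found[0]))
    vals = [dihedral(trajectory.coords[f], *idx)
            for f in range(trajectory.n_frames)]
    return DescriptorSeries(name=name, units="deg", values=np.array(vals),
                            frame_interval_ps=trajectory.frame_interval_ps)
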