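"""Desk-scale surrogate dynamics with the statistical structure the
analysis pipeline assumes.

The generator provides four pieces:

* a coarse two-lobe structure whose residue numbering mirrors the landmarks
  of the analyzed methyltransferase, so every preset selection (residues
  42-48, 183, 209-227, 239, 298-302, 363-365 and the five monitored
  hydrogen-bond pairs) resolves;
* overdamped Langevin dynamics of the scalar hinge coordinate D1 on a
  smooth triple-well potential whose minima sit at the closed /
  intermediate / open state centers (defaults 8.5, 10.5, 13.5 Å);
* a rigid-body embedding that rotates the C-lobe about a hinge so the D1
  preset recomputed from the 3-D coordinates reproduces the driving series
  (and D2 varies oppositely to D1, the clamp signature), with per-frame
  on/off hydrogen-bond geometry for named residue pairs;
* a toy well-tempered metadynamics engine on the same coordinate
  (tempered Gaussian deposition, half-harmonic walls, FES estimate
  F = -(gamma/(gamma-1)) V).

Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.interpolate import CubicHermiteSpline

from .geometry import D1_SPEC, DescriptorSeries, group_distance
from .landscape import KB_KCAL, StateDefinition
from .structure_io import MolecularStructure, Trajectory, atomic_mass, resolve_selection

__all__ = [
    "ToyModelConfig",
    "MetadynamicsConfig",
    "ToyTrajectoryBundle",
    "TripleWellPotential",
    "HarmonicPotential",
    "FlatPotential",
    "build_toy_structure",
    "simulate_langevin_d1",
    "embed_d1_to_coordinates",
    "run_wt_metadynamics",
    "generate_bundle",
    "series_from_states",
]

KJ_PER_KCAL = 4.184


class StabilityError(RuntimeError):
    """Trajectory diverged; suggests a smaller timestep."""


class GeometryError(ValueError):
    """Requested hinge coordinate outside the reachable range."""


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelConfig:
    """Three-state toy model of the hinge coordinate.

    ``well_energies`` are the energies of the three minima and
    ``barrier_energies`` the two barrier tops (kcal/mol, common zero).
    Defaults keep closed and intermediate near-degenerate, the open state
    0.5 kcal/mol up, and 1.5 kcal/mol barriers, so all three states are
    visited at 300 K in short runs.  ``friction`` is the overdamped friction
    coefficient gamma_f in the update rule
    ``x <- x - (dt/gamma_f) U'(x) + sqrt(2 kB T dt / gamma_f) eta``
    (units kcal mol^-1 ps Å^-2).
    """

    centers: Tuple[float, ...] = (8.5, 10.5, 13.5)
    well_energies: Tuple[float, ...] = (0.0, 0.1, 0.5)
    barrier_energies: Tuple[float, ...] = (1.5, 1.5)
    temperature: float = 300.0
    friction: float = 0.5
    timestep: float = 0.01
    frame_stride: int = 10
    well_stiffness: float = 1.0  # used only for a single-center (harmonic) model
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if len(c) == 0 or np.any(np.diff(c) <= 0):
            raise ValueError("well centers must be strictly increasing")
        if len(c) > 1 and len(self.barrier_energies) != len(c) - 1:
            raise ValueError("need one barrier per adjacent well pair")
        for i, b in enumerate(self.barrier_energies):
            if b <= max(self.well_energies[i], self.well_energies[i + 1]):
                raise ValueError("barrier tops must exceed adjacent minima")
        if not (self.temperature >= 0 and self.friction > 0 and self.timestep > 0):
            raise ValueError("temperature, friction and timestep must be positive")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    def potential(self):
        if len(self.centers) == 1:
            return HarmonicPotential(self.centers[0], self.well_stiffness)
        return TripleWellPotential(self.centers, self.well_energies,
                                   self.barrier_energies)

    def state_definition(self) -> StateDefinition:
        """Half-open state partition cut at the barrier positions."""
        c = self.centers
        if len(c) != 3:
            raise ValueError("state definition needs a three-well model")
        return StateDefinition(b1=(c[0] + c[1]) / 2, b2=(c[1] + c[2]) / 2)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "ToyModelConfig":
        d = json.loads(text)
        for k in ("centers", "well_energies", "barrier_energies"):
            if k in d:
                d[k] = tuple(d[k])
        return ToyModelConfig(**d)


@dataclass(frozen=True)
class MetadynamicsConfig:
    """Well-tempered metadynamics parameters (biased-sampling inputs in
    kJ/mol as customarily specified; internal energies are kcal/mol).

    A Gaussian hill of width ``gaussian_width`` is deposited every
    ``deposition_pace_ps``; its height is tempered as
    ``h exp(-V(x)/((gamma-1) kB T))`` with bias factor ``gamma``.
    Half-harmonic walls with force constant ``wall_k_kj`` (kJ mol^-1 Å^-2)
    confine the coordinate to [wall_lower, wall_upper]; the bias grid spans
    [grid_lower, grid_upper].
    """

    gaussian_height_kj: float = 1.0
    gaussian_width: float = 0.5
    deposition_pace_ps: float = 1.0
    bias_factor: float = 15.0
    wall_lower: float = 6.0
    wall_upper: float = 20.0
    wall_k_kj: float = 5000.0
    grid_lower: float = 5.0
    grid_upper: float = 25.0
    grid_spacing: float = 0.1
    temperature: float = 300.0
    run_length_ns: float = 50.0
    timestep: float = 0.0005

    def __post_init__(self) -> None:
        if not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")
        if not self.gaussian_width > 0:
            raise ValueError("gaussian width must be positive")
        if not (self.grid_lower < self.wall_lower < self.wall_upper
                < self.grid_upper):
            raise ValueError("walls must lie inside the grid bounds")
        if not (self.timestep > 0 and self.run_length_ns > 0):
            raise ValueError("timestep and run length must be positive")

    @property
    def wall_k_kcal(self) -> float:
        return self.wall_k_kj / KJ_PER_KCAL

    @property
    def height_kcal(self) -> float:
        return self.gaussian_height_kj / KJ_PER_KCAL


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

class TripleWellPotential:
    """C1-smooth multi-well potential: piecewise-cubic Hermite through the
    well minima and barrier tops (all with zero slope), continued
    quadratically outside the outermost knots."""

    def __init__(self, centers, well_energies, barrier_energies,
                 outer_offset: float = 2.0, outer_rise: float = 4.0,
                 outer_k: float = 2.0):
        centers = np.asarray(centers, dtype=float)
        wells = np.asarray(well_energies, dtype=float)
        barriers = np.asarray(barrier_energies, dtype=float)
        mids = (centers[:-1] + centers[1:]) / 2
        xs = [centers[0] - outer_offset]
        ys = [wells[0] + outer_rise]
        for i in range(len(centers) - 1):
            xs += [centers[i], mids[i]]
            ys += [wells[i], barriers[i]]
        xs += [centers[-1], centers[-1] + outer_offset]
        ys += [wells[-1], wells[-1] + outer_rise]
        self._knots_x = np.array(xs)
        self._knots_y = np.array(ys)
        self._spline = CubicHermiteSpline(self._knots_x, self._knots_y,
                                          np.zeros(len(xs)))
        self._dspline = self._spline.derivative()
        self.centers = centers
        self.outer_k = outer_k

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self._knots_x[0], self._knots_x[-1]
        out = self._spline(np.clip(x, lo, hi))
        below, above = x < lo, x > hi
        out = np.where(below, self._knots_y[0] + 0.5 * self.outer_k * (x - lo) ** 2, out)
        out = np.where(above, self._knots_y[-1] + 0.5 * self.outer_k * (x - hi) ** 2, out)
        return out

    def force(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self._knots_x[0], self._knots_x[-1]
        out = -self._dspline(np.clip(x, lo, hi))
        out = np.where(x < lo, -self.outer_k * (x - lo), out)
        out = np.where(x > hi, -self.outer_k * (x - hi), out)
        return out

    @property
    def barrier_positions(self) -> np.ndarray:
        return (self.centers[:-1] + self.centers[1:]) / 2

    def equilibrium_state_weights(self, kT: float,
                                  n_points: int = 200001) -> np.ndarray:
        """Boltzmann weight of each well by numerical integration of
        exp(-U/kT) between barrier positions."""
        lo = self.centers[0] - 6.0
        hi = self.centers[-1] + 6.0
        x = np.linspace(lo, hi, n_points)
        w = np.exp(-(self.energy(x) - self.energy(x).min()) / kT)
        bounds = np.concatenate(([lo], self.barrier_positions, [hi]))
        weights = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            m = (x >= a) & (x <= b)
            weights.append(np.trapezoid(w[m], x[m]))
        weights = np.array(weights)
        return weights / weights.sum()


class HarmonicPotential:
    """Single harmonic well 0.5 k (x - c)^2."""

    def __init__(self, center: float, stiffness: float):
        self.center = float(center)
        self.stiffness = float(stiffness)
        self.centers = np.array([self.center])

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 0.5 * self.stiffness * (x - self.center) ** 2

    def force(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return -self.stiffness * (x - self.center)


class FlatPotential:
    """Zero potential everywhere (used with metadynamics walls)."""

    centers = np.array([13.0])

    def energy(self, x) -> np.ndarray:
        return np.zeros_like(np.asarray(x, dtype=float))

    def force(self, x) -> np.ndarray:
        return np.zeros_like(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Integrator kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lin_interp(x, lo, inv_dx, table):
    pos = (x - lo) * inv_dx
    if pos <= 0.0:
        return table[0]
    i = int(pos)
    if i >= table.size - 1:
        return table[table.size - 1]
    frac = pos - i
    return table[i] * (1.0 - frac) + table[i + 1] * frac


@njit(cache=True)
def _integrate(x0, n_steps, dt, gamma, kT,
               flo, finv_dx, ftable,
               stride, out,
               wall_lo, wall_hi, wall_k,
               pace_steps, h0, width, gfac,
               blo, binv_dx, vgrid, fgrid,
               hill_centers, hill_heights,
               avg_from_hill, vavg,
               seed, diverge_lo, diverge_hi):
    """Overdamped Langevin with optional tempered Gaussian deposition.

    Returns (exit_code, n_out, n_hills, n_avg); exit_code 1 = divergence.
    ``vavg`` accumulates the bias grid after every deposition with index
    >= ``avg_from_hill`` (time-averaged bias estimator); ``n_avg`` counts
    the accumulated snapshots.  The RNG draws exactly one normal per step
    regardless of biasing, so a zero-height biased run is bit-identical to
    the unbiased run.
    """
    np.random.seed(seed)
    x = x0
    sig = np.sqrt(2.0 * kT * dt / gamma)
    mob = dt / gamma
    n_out = 0
    n_hills = 0
    n_avg = 0
    w2 = width * width
    for step in range(n_steps):
        f = _lin_interp(x, flo, finv_dx, ftable)
        if pace_steps > 0:
            f += _lin_interp(x, blo, binv_dx, fgrid)
            if x < wall_lo:
                f += wall_k * (wall_lo - x)
            elif x > wall_hi:
                f -= wall_k * (x - wall_hi)
        x = x + mob * f + sig * np.random.standard_normal()
        if x < diverge_lo or x > diverge_hi:
            return 1, n_out, n_hills, n_avg
        if (step + 1) % stride == 0:
            out[n_out] = x
            n_out += 1
        if pace_steps > 0 and (step + 1) % pace_steps == 0:
            v_here = _lin_interp(x, blo, binv_dx, vgrid)
            h = h0 * np.exp(-v_here / gfac)
            hill_centers[n_hills] = x
            hill_heights[n_hills] = h
            n_hills += 1
            if h > 0.0:
                for i in range(vgrid.size):
                    d = blo + i / binv_dx - x
                    e = h * np.exp(-d * d / (2.0 * w2))
                    vgrid[i] += e
                    fgrid[i] += e * d / w2
            if n_hills > avg_from_hill:
                for i in range(vgrid.size):
                    vavg[i] += vgrid[i]
                n_avg += 1
    return 0, n_out, n_hills, n_avg


def _force_table(potential, lo: float, hi: float,
                 spacing: float = 2e-4):
    n = int(np.ceil((hi - lo) / spacing)) + 1
    grid = lo + spacing * np.arange(n)
    return lo, 1.0 / spacing, potential.force(grid).astype(float)


def _check_stability(potential, config_dt, friction, lo, hi) -> None:
    x = np.linspace(lo, hi, 4001)
    f = potential.force(x)
    kappa = np.max(np.abs(np.gradient(f, x)))
    if config_dt * kappa / friction >= 2.0:
        raise StabilityError(
            f"timestep {config_dt} ps unstable for local stiffness "
            f"{kappa:.3g} kcal/mol/A^2; use a smaller timestep")


# ---------------------------------------------------------------------------
# Unbiased Langevin
# ---------------------------------------------------------------------------

def simulate_langevin_d1(
    config: ToyModelConfig,
    n_steps: int,
    x0: Optional[float] = None,
    potential=None,
) -> Tuple[DescriptorSeries, np.ndarray]:
    """Overdamped Langevin dynamics of D1 on the configured multi-well
    potential.

    Returns the strided D1 series and per-frame ground-truth state labels
    (well membership delimited by the barrier positions).  Bit-reproducible
    for a given (config, seed).
    """
    pot = potential if potential is not None else config.potential()
    centers = np.asarray(pot.centers, dtype=float)
    lo = centers[0] - 10.0
    hi = centers[-1] + 14.0
    _check_stability(pot, config.timestep, config.friction, lo, hi)
    flo, finv, ftable = _force_table(pot, lo, hi)
    n_frames = n_steps // config.frame_stride
    out = np.empty(n_frames)
    start = float(x0) if x0 is not None else float(centers[len(centers) // 2])
    dummy = np.empty(1)
    code, n_out, _, _ = _integrate(
        start, n_steps, config.timestep, config.friction, config.kT,
        flo, finv, ftable,
        config.frame_stride, out,
        0.0, 0.0, 0.0,
        0, 0.0, 1.0, 1.0,
        0.0, 1.0, dummy, dummy,
        dummy, dummy,
        0, dummy,
        config.seed, lo - 10.0, hi + 10.0)
    if code != 0:
        raise StabilityError(
            "trajectory diverged; use a smaller timestep or higher friction")
    series = DescriptorSeries(
        name="D1", units="A", values=out[:n_out],
        frame_interval_ps=config.timestep * config.frame_stride)
    if len(centers) > 1:
        bounds = (centers[:-1] + centers[1:]) / 2
        idx = np.searchsorted(bounds, series.values, side="left")
    else:
        idx = np.zeros(len(series.values), dtype=int)
    names = np.array(["closed", "intermediate", "open"], dtype="U12")
    labels = (names[idx] if len(centers) == 3
              else np.array([f"well{i}" for i in idx], dtype="U12"))
    return series, labels


def series_from_states(labels: Sequence[str],
                       config: ToyModelConfig) -> DescriptorSeries:
    """A D1 series sitting exactly at the well center of each scheduled
    state — handy for constructing trajectories with known occupancies."""
    centers = {"closed": config.centers[0], "intermediate": config.centers[1],
               "open": config.centers[2]}
    vals = np.array([centers[str(l)] for l in labels], dtype=float)
    return DescriptorSeries(name="D1", units="A", values=vals,
                            frame_interval_ps=config.timestep * config.frame_stride)


# ---------------------------------------------------------------------------
# Toy structure
# ---------------------------------------------------------------------------

_N_LOBE_LAST = 269          # C-lobe (rigid, hinged) is residues 270..428
_HINGE_AXIS_Z = True        # hinge = rotation about the z axis through origin
_RADIUS = 11.0              # anchor-cluster radius from the hinge axis
_Z_RING = 5.0

#: named hydrogen-bond pairs of the toy structure: label -> (donor residue,
#: donor heavy atom, hydrogen, acceptor residue, acceptor heavy atom)
TOY_HBOND_ATOMS = {
    "R14-D262": (14, "NH1", "HH11", 262, "OD1"),
    "M242-R265": (242, "N", "H", 265, "O"),
    "A188-H404": (188, "N", "H", 404, "ND1"),
    "S44-V193": (44, "OG", "HG", 193, "O"),
    "K42-E295": (42, "NZ", "HZ1", 295, "OE1"),
}


def _ring_positions(center: np.ndarray, n: int, radius: float = 0.8):
    t = 2 * np.pi * np.arange(n) / max(n, 1)
    pts = np.stack([np.zeros(n), np.cos(t), np.sin(t)], axis=1) * radius
    pts -= pts.mean(axis=0)  # exact centroid at `center`
    return center + pts


def _polar(angle_deg: float, radius: float, z: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def _scatter_position(res: int, angle_lo: float, angle_span: float) -> np.ndarray:
    """Deterministic pseudo-random placement for filler residues."""
    angle = angle_lo + (res * 137.508) % angle_span
    radius = 6.0 + 7.0 * ((res * 0.37) % 1.0)
    z = 10.0 * ((res * 0.61) % 1.0)
    return _polar(angle, radius, z)


def _sidechain_atoms(res: int, ca: np.ndarray):
    """Minimal heavy sidechains (plus donor hydrogens) for the special
    residues of the toy structure."""
    def off(*d):
        return ca + np.array(d)

    if res == 14:    # Arg donor
        return [("CB", "C", off(1.5, 0, 0)), ("NH1", "N", off(2.6, 0.9, 0.2)),
                ("HH11", "H", off(3.3, 1.5, 0.3))]
    if res == 42:    # Lys donor
        return [("CB", "C", off(1.5, 0, 0)), ("CG", "C", off(2.4, 1.1, 0)),
                ("CD", "C", off(3.6, 1.2, 0.4)), ("CE", "C", off(4.7, 2.0, 0.2)),
                ("NZ", "N", off(5.8, 2.2, 0.7)), ("HZ1", "H", off(6.5, 2.8, 0.9))]
    if res == 44:    # Ser donor
        return [("CB", "C", off(1.4, -0.5, 0.3)), ("OG", "O", off(2.3, -1.4, 0.5)),
                ("HG", "H", off(3.0, -2.0, 0.7))]
    if res in (183, 239):  # aromatic ring; 239 also carries OH
        ring = [("CB", "C", off(1.5, 0, 0)), ("CG", "C", off(2.3, 1.2, 0.1)),
                ("CD1", "C", off(3.6, 1.1, -0.6)), ("CD2", "C", off(2.0, 2.5, 0.7)),
                ("CE1", "C", off(4.4, 2.2, -0.7)), ("CE2", "C", off(2.8, 3.6, 0.6)),
                ("CZ", "C", off(4.0, 3.5, -0.1))]
        if res == 239:
            ring.append(("OH", "O", off(4.9, 4.6, -0.2)))
        return ring
    if res in (188, 242):  # backbone amide donors
        return [("N", "N", off(-1.2, 0.6, 0.2)), ("H", "H", off(-1.9, 1.3, 0.3)),
                ("CB", "C", off(1.5, 0, 0))]
    if res == 262:   # Asp acceptor
        return [("CB", "C", off(1.5, 0, 0)), ("OD1", "O", off(2.4, 1.0, 0.3))]
    if res in (193, 265):  # backbone carbonyl acceptors
        return [("C", "C", off(1.3, 0.5, 0)), ("O", "O", off(2.0, 1.4, 0.2))]
    if res == 295:   # Glu acceptor
        return [("CB", "C", off(1.5, 0, 0)), ("OE1", "O", off(2.5, 1.0, 0.4))]
    if res == 404:   # His acceptor
        return [("CB", "C", off(1.5, 0, 0)), ("ND1", "N", off(2.4, 1.1, 0.2))]
    return []


_RES_NAMES = {14: "ARG", 42: "LYS", 44: "SER", 183: "PHE", 188: "ALA",
              193: "VAL", 239: "TYR", 242: "MET", 262: "ASP", 265: "ARG",
              295: "GLU", 404: "HIS"}


def build_toy_structure(config: ToyModelConfig) -> MolecularStructure:
    """A coarse two-lobe structure: one CA per residue 1-428, anchor-cluster
    rings for the preset residue ranges, minimal sidechains for the special
    residues, and donor/H/acceptor triads for the five monitored pairs.

    Built in the closed pose: the D1 preset evaluates to the configured
    closed-state center (first well center) at hinge angle zero, which is
    enforced by placing the CTD anchor ring at a numerically solved hinge
    angle.  Deterministic for a given config.
    """
    records = []  # (atom_name, res_name, res_id, element, xyz)

    def add(res, name, element, xyz):
        records.append((name, _RES_NAMES.get(res, "GLY"), res, element,
                        np.asarray(xyz, dtype=float)))

    # --- N lobe -----------------------------------------------------------
    ring_4248 = _ring_positions(_polar(0.0, _RADIUS, _Z_RING), 7)
    ring_209227 = _ring_positions(_polar(150.0, _RADIUS, _Z_RING), 19)
    for res in range(1, _N_LOBE_LAST + 1):
        if 42 <= res <= 48:
            ca = ring_4248[res - 42]
        elif 209 <= res <= 227:
            ca = ring_209227[res - 209]
        else:
            ca = _scatter_position(res, 140.0, 200.0)
        add(res, "CA", "C", ca)
        for name, element, xyz in _sidechain_atoms(res, ca):
            add(res, name, element, xyz)

    # --- C lobe (placed at a solved hinge angle so D1 = closed center) ----
    # Heavy-atom, mass-weighted centroid of residues 42-48 as group_distance
    # will compute it:
    coords_4248, masses_4248 = [], []
    for name, rname, res, element, xyz in records:
        if 42 <= res <= 48 and element != "H":
            coords_4248.append(xyz)
            masses_4248.append(atomic_mass(element))
    coords_4248 = np.array(coords_4248)
    masses_4248 = np.array(masses_4248)
    anchor = (masses_4248[:, None] * coords_4248).sum(0) / masses_4248.sum()

    target = float(config.centers[0])

    def d1_at(phi_deg: float) -> float:
        return float(np.linalg.norm(_polar(phi_deg, _RADIUS, _Z_RING) - anchor))

    lo_phi, hi_phi = 3.0, 178.0
    if not (d1_at(lo_phi) <= target <= d1_at(hi_phi)):
        raise GeometryError(
            f"closed-state center {target} Å outside constructible range "
            f"[{d1_at(lo_phi):.2f}, {d1_at(hi_phi):.2f}] Å")
    for _ in range(200):
        mid = (lo_phi + hi_phi) / 2
        if d1_at(mid) < target:
            lo_phi = mid
        else:
            hi_phi = mid
    phi1 = (lo_phi + hi_phi) / 2

    ring_298302 = _ring_positions(_polar(phi1, _RADIUS, _Z_RING), 5)
    # D2 partner placed on the other rotational side of its N-lobe anchor so
    # that the hinge rotation that widens D1 narrows D2 (clamp signature).
    d2_closed = 12.0
    dphi2 = np.degrees(2 * np.arcsin(min(d2_closed / (2 * _RADIUS), 1.0)))
    ring_363365 = _ring_positions(_polar(150.0 - dphi2, _RADIUS, _Z_RING), 3)
    for res in range(_N_LOBE_LAST + 1, 429):
        if 298 <= res <= 302:
            ca = ring_298302[res - 298]
        elif 363 <= res <= 365:
            ca = ring_363365[res - 363]
        else:
            ca = _scatter_position(res, 45.0, 65.0)
        add(res, "CA", "C", ca)
        for name, element, xyz in _sidechain_atoms(res, ca):
            add(res, name, element, xyz)

    n = len(records)
    structure = MolecularStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([r[0] for r in records], dtype="U6"),
        res_name=np.array([r[1] for r in records], dtype="U4"),
        chain_id=np.array(["A"] * n, dtype="U4"),
        res_id=np.array([r[2] for r in records], dtype=int),
        element=np.array([r[3] for r in records], dtype="U4"),
        mass=np.array([atomic_mass(r[3]) for r in records]),
        coord=np.array([r[4] for r in records]),
        hetero=np.zeros(n, dtype=bool),
    )
    return structure


# ---------------------------------------------------------------------------
# Embedding D1 onto 3-D coordinates
# ---------------------------------------------------------------------------

@dataclass
class ToyTrajectoryBundle:
    """A synthetic trajectory with its ground truth.

    ``d1`` is the driving hinge-coordinate series; recomputing D1 from the
    3-D coordinates via the geometry presets reproduces it to 1e-6 Å.
    """

    trajectory: Trajectory
    d1: DescriptorSeries
    state_labels: np.ndarray
    hbond_schedule: Dict[str, np.ndarray]
    config: ToyModelConfig
    seed: int


def _rotate_z(coords: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    out = coords.copy()
    out[:, 0] = c * coords[:, 0] - s * coords[:, 1]
    out[:, 1] = s * coords[:, 0] + c * coords[:, 1]
    return out


def embed_d1_to_coordinates(
    structure: MolecularStructure,
    d1_series: DescriptorSeries,
    hbond_schedule: Optional[Dict[str, np.ndarray]] = None,
    config: Optional[ToyModelConfig] = None,
    state_labels: Optional[np.ndarray] = None,
    seed: int = 0,
) -> ToyTrajectoryBundle:
    """Realize a D1 series as rigid-body hinge motion of the C-lobe.

    Per frame the C-lobe (residues > 269) is rotated about the hinge axis by
    an angle solved by bisection so the D1 preset reproduces the input value
    to 1e-6 Å; scheduled hydrogen-bond pairs then have their acceptor atom
    placed inside (on) or outside (off) the detection criteria.
    """
    cfg = config or ToyModelConfig()
    sel_a = resolve_selection(structure, D1_SPEC[0])
    sel_b = resolve_selection(structure, D1_SPEC[1])
    clobe = np.nonzero(structure.res_id > _N_LOBE_LAST)[0]
    base = structure.coord
    m = structure.mass
    anchor = (m[sel_a, None] * base[sel_a]).sum(0) / m[sel_a].sum()

    def d1_of_theta(theta: float) -> float:
        moved = _rotate_z(base[sel_b], theta)
        cb = (m[sel_b, None] * moved).sum(0) / m[sel_b].sum()
        return float(np.linalg.norm(cb - anchor))

    # reachable range over the physical hinge sweep
    th_lo, th_hi = np.radians(-60.0), np.radians(170.0)
    d_lo, d_hi = d1_of_theta(th_lo), d1_of_theta(th_hi)
    # d1_of_theta is monotone only past the closest approach; restrict to
    # the increasing branch through theta = 0
    grid = np.linspace(th_lo, th_hi, 231)
    dg = np.array([d1_of_theta(t) for t in grid])
    i_min = int(np.argmin(dg))
    th_lo, d_lo = grid[i_min], dg[i_min]

    frames = np.empty((len(d1_series), structure.n_atoms, 3))
    schedule = hbond_schedule or {}
    for label in schedule:
        if label not in TOY_HBOND_ATOMS:
            raise KeyError(f"unknown toy hydrogen-bond pair {label!r}")
    for f, target in enumerate(d1_series.values):
        if not (d_lo - 1e-9 <= target <= d_hi + 1e-9):
            raise GeometryError(
                f"frame {f}: D1 = {target:.3f} Å outside reachable hinge "
                f"range [{d_lo:.3f}, {d_hi:.3f}] Å")
        a, b = th_lo, th_hi
        for _ in range(80):
            mid = (a + b) / 2
            if d1_of_theta(mid) < target:
                a = mid
            else:
                b = mid
        theta = (a + b) / 2
        coords = base.copy()
        coords[clobe] = _rotate_z(base[clobe], theta)
        for label, mask in schedule.items():
            dres, datom, hatom, ares, aatom = TOY_HBOND_ATOMS[label]
            di = _named_atom(structure, dres, datom)
            hi_ = _named_atom(structure, dres, hatom)
            ai = _named_atom(structure, ares, aatom)
            u = coords[hi_] - coords[di]
            u = u / np.linalg.norm(u)
            dist = 2.8 if bool(mask[f]) else 6.0
            coords[ai] = coords[di] + dist * u
        frames[f] = coords
    traj = Trajectory(topology=structure, coords=frames,
                      frame_interval_ps=d1_series.frame_interval_ps)
    labels = (state_labels if state_labels is not None
              else np.array([cfg.state_definition().label(v)
                             for v in d1_series.values], dtype="U12")
              if len(cfg.centers) == 3 else
              np.array(["well0"] * len(d1_series), dtype="U12"))
    return ToyTrajectoryBundle(trajectory=traj, d1=d1_series,
                               state_labels=np.asarray(labels),
                               hbond_schedule={k: np.asarray(v, dtype=bool)
                                               for k, v in schedule.items()},
                               config=cfg, seed=seed)


def _named_atom(structure: MolecularStructure, res: int, name: str) -> int:
    hit = np.nonzero((structure.res_id == res)
                     & (structure.atom_name == name))[0]
    if len(hit) != 1:
        raise KeyError(f"residue {res} atom {name}: found {len(hit)}")
    return int(hit[0])


def generate_bundle(
    config: ToyModelConfig,
    n_steps: int,
    hbond_duty_cycles: Optional[Dict[str, float]] = None,
    d1_series: Optional[DescriptorSeries] = None,
    state_labels: Optional[np.ndarray] = None,
) -> ToyTrajectoryBundle:
    """Full generator: Langevin D1 series (unless one is supplied), toy
    structure, hinge embedding, and deterministic periodic hydrogen-bond
    schedules with the requested duty cycles."""
    if d1_series is None:
        d1_series, state_labels = simulate_langevin_d1(config, n_steps)
    structure = build_toy_structure(config)
    n_frames = len(d1_series)
    schedule: Dict[str, np.ndarray] = {}
    for label, duty in (hbond_duty_cycles or {}).items():
        if not 0 <= duty <= 1:
            raise ValueError(f"duty cycle for {label} must be in [0, 1]")
        # deterministic periodic schedule with an exact on-fraction
        n_on = int(round(duty * n_frames))
        mask = np.zeros(n_frames, dtype=bool)
        if n_on:
            mask[np.round(np.linspace(0, n_frames - 1, n_on)).astype(int)] = True
            # rounding collisions would lower the count; fill greedily
            short = n_on - mask.sum()
            if short:
                mask[np.nonzero(~mask)[0][:short]] = True
        schedule[label] = mask
    return embed_d1_to_coordinates(structure, d1_series, schedule,
                                   config=config, state_labels=state_labels,
                                   seed=config.seed)


# ---------------------------------------------------------------------------
# Toy well-tempered metadynamics
# ---------------------------------------------------------------------------

@dataclass
class MetadynamicsResult:
    """Bias history and free-energy estimate of a toy run.

    ``fes`` is -(gamma/(gamma-1)) times the bias potential on ``grid``,
    min-shifted to zero (kcal/mol); the bias is time-averaged over the
    second half of the depositions to suppress hill-sized ripple.  ``bias``
    holds the final (un-averaged) V(x, t_end).
    """

    d1: DescriptorSeries
    grid: np.ndarray
    bias: np.ndarray
    fes: np.ndarray
    hill_centers: np.ndarray
    hill_heights: np.ndarray
    config: MetadynamicsConfig
    model: ToyModelConfig


def run_wt_metadynamics(
    config: MetadynamicsConfig,
    model: ToyModelConfig,
    potential=None,
    n_steps: Optional[int] = None,
) -> MetadynamicsResult:
    """Well-tempered metadynamics on the hinge coordinate.

    Langevin dynamics on U(x) plus the accumulated bias V(x, t); every
    deposition interval a Gaussian of tempered height
    ``h exp(-V/( (gamma-1) kB T ))`` is added; half-harmonic walls confine
    the coordinate.  With zero deposition height the trajectory is
    bit-identical to :func:`simulate_langevin_d1` at the same seed and
    timestep.
    """
    pot = potential if potential is not None else model.potential()
    kT = KB_KCAL * config.temperature
    if n_steps is None:
        n_steps = int(round(config.run_length_ns * 1000.0 / config.timestep))
    pace_steps = max(1, int(round(config.deposition_pace_ps / config.timestep)))
    lo = min(np.min(pot.centers) - 10.0, config.grid_lower - 2.0)
    hi = max(np.max(pot.centers) + 14.0, config.grid_upper + 2.0)
    _check_stability(pot, config.timestep, model.friction, lo, hi)
    if config.timestep * config.wall_k_kcal / model.friction >= 2.0:
        raise StabilityError(
            "timestep unstable against the wall stiffness; reduce timestep")
    flo, finv, ftable = _force_table(pot, lo, hi)
    nb = int(round((config.grid_upper - config.grid_lower)
                   / config.grid_spacing)) + 1
    bgrid = config.grid_lower + config.grid_spacing * np.arange(nb)
    vgrid = np.zeros(nb)
    fgrid = np.zeros(nb)
    n_hills_max = n_steps // pace_steps + 1
    hill_centers = np.empty(n_hills_max)
    hill_heights = np.empty(n_hills_max)
    n_frames = n_steps // model.frame_stride
    out = np.empty(n_frames)
    start = float(np.asarray(pot.centers)[len(np.asarray(pot.centers)) // 2])
    gfac = (config.bias_factor - 1.0) * kT
    # time-averaged bias estimator: average V(x, t) over the second half of
    # the depositions, which suppresses the hill-sized ripple of the final
    # bias snapshot without shifting the converged profile
    avg_from = n_hills_max // 2
    vavg = np.zeros(nb)
    code, n_out, n_hills, n_avg = _integrate(
        start, n_steps, config.timestep, model.friction, kT,
        flo, finv, ftable,
        model.frame_stride, out,
        config.wall_lower, config.wall_upper, config.wall_k_kcal,
        pace_steps, config.height_kcal, config.gaussian_width, gfac,
        config.grid_lower, 1.0 / config.grid_spacing, vgrid, fgrid,
        hill_centers, hill_heights,
        avg_from, vavg,
        model.seed, config.grid_lower - 10.0, config.grid_upper + 10.0)
    if code != 0:
        raise StabilityError(
            "metadynamics trajectory diverged; use a smaller timestep")
    gamma = config.bias_factor
    v_est = vavg / n_avg if n_avg > 0 else vgrid
    fes = -(gamma / (gamma - 1.0)) * v_est
    fes = fes - fes.min()
    series = DescriptorSeries(
        name="D1", units="A", values=out[:n_out],
        frame_interval_ps=config.timestep * model.frame_stride)
    return MetadynamicsResult(
        d1=series, grid=bgrid, bias=vgrid.copy(), fes=fes,
        hill_centers=hill_centers[:n_hills].copy(),
        hill_heights=hill_heights[:n_hills].copy(),
        config=config, model=model)
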