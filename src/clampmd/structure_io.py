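"""Reading, writing and atom selection for molecular structures and trajectories.

Structures are plain records of atoms (names, residues, chains, elements,
masses in amu, coordinates in Å); trajectories are stacks of coordinate
frames over a fixed topology with a frame interval in ps.  PDB parsing and
writing is delegated to :mod:`biotite`; the XYZ dialect (count line, comment
line, ``element x y z`` records) is handled directly.

Conventions
-----------
* Author residue numbering is used verbatim and never renumbered.
* Atom indices are 0-based internally; residue numbers are 1-based author
  numbers.
* Alternate locations are resolved by keeping the highest-occupancy
  conformer (ties resolve to altloc ``A``, the file-order first).
* HETATM records (cofactors, ions, waters) are parsed and retained but are
  excluded from protein selections unless a selection explicitly opts in.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import biotite.structure as _struc
import biotite.structure.info as _info
import biotite.structure.io.pdb as _pdb

__all__ = [
    "MolecularStructure",
    "Trajectory",
    "SelectionSpec",
    "PDBParseError",
    "TopologyMismatchError",
    "FormatError",
    "read_pdb",
    "read_xyz",
    "write_frames",
    "resolve_selection",
    "element_from_atom_name",
    "atomic_mass",
]

# Backbone heavy atoms of a peptide unit; the "sidechain" class is every
# heavy atom not in this set.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# Two-letter element symbols that occur as the first characters of PDB atom
# names and must not be mistaken for carbon/nitrogen + remainder.
_TWO_LETTER_ELEMENTS = frozenset({
    "ZN", "FE", "MG", "MN", "NA", "CL", "BR", "CA", "CU", "NI", "CO",
    "SE", "CD", "HG", "LI",
})


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB records; names the line number."""


class TopologyMismatchError(ValueError):
    """Raised when trajectory models/frames disagree on atom count."""


class FormatError(ValueError):
    """Raised when a structure cannot be represented in the requested format."""


def element_from_atom_name(atom_name: str, res_name: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Used only when the element columns (77-78) are blank.  Leading digits
    are stripped (``1HG1`` → hydrogen); known two-letter metal/halogen
    symbols are recognized, otherwise the first alphabetic character wins.
    """
    name = atom_name.strip().upper()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[0] == "H":
        return "H"
    # Metals/ions are usually named identically to their element and live in
    # HETATM records (e.g. ZN); amino-acid CA is calcium only when the
    # residue itself is CA.
    if stripped[:2] in _TWO_LETTER_ELEMENTS and (
        res_name.strip().upper() == stripped or stripped[:2] not in {"CA"}
    ):
        if stripped[:2] == "CA" and res_name.strip().upper() != "CA":
            return "C"
        return stripped[:2].capitalize()
    return stripped[0]


def atomic_mass(element: str) -> float:
    """Standard atomic weight (amu) for an element symbol."""
    mass = _info.mass(element.capitalize() if len(element) > 1 else element)
    if mass is None or not mass > 0:
        raise ValueError(f"no positive mass for element {element!r}")
    return float(mass)


@dataclass
class MolecularStructure:
    """An ordered set of atoms with author numbering, masses and coordinates.

    Field arrays all share length ``n_atoms``; ``coord`` is ``(n_atoms, 3)``
    in Å.  Atom order is file order and is preserved across round trips.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    coord: np.ndarray
    hetero: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.mass > 0):
            raise ValueError("non-positive atomic mass")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def __len__(self) -> int:
        return self.n_atoms

    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) == "H"

    def copy_with_coords(self, coord: np.ndarray) -> "MolecularStructure":
        return replace(self, coord=np.array(coord, dtype=float))


@dataclass
class Trajectory:
    """Coordinate frames over a fixed topology.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å;
    ``frame_interval_ps`` is the time between saved frames.
    """

    topology: MolecularStructure
    coords: np.ndarray
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must be (n_frames, n_atoms, 3) with >= 1 frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite trajectory coordinates")
        if not self.frame_interval_ps > 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class SelectionSpec:
    """A declarative atom selection.

    ``residue_intervals`` are closed author-numbering intervals; ``atom_class``
    is one of ``all`` (every atom), ``heavy`` (no hydrogens), ``backbone``
    (N, CA, C, O) or ``sidechain`` (heavy atoms excluding the backbone set).
    Resolution is a pure function of (structure, spec) and yields an ordered,
    possibly empty index list.
    """

    chain: Optional[str] = None
    residue_intervals: tuple = ()
    atom_names: Optional[frozenset] = None
    atom_class: Literal["all", "heavy", "backbone", "sidechain"] = "heavy"
    include_hetero: bool = False

    @staticmethod
    def residues(*intervals, chain=None, atom_class="heavy",
                 atom_names=None, include_hetero=False) -> "SelectionSpec":
        """Build a spec from residue numbers or ``(lo, hi)`` interval tuples."""
        norm = tuple(
            (int(iv), int(iv)) if np.isscalar(iv) else (int(iv[0]), int(iv[1]))
            for iv in intervals
        )
        names = frozenset(atom_names) if atom_names is not None else None
        return SelectionSpec(chain=chain, residue_intervals=norm,
                             atom_names=names, atom_class=atom_class,
                             include_hetero=include_hetero)


def resolve_selection(structure: MolecularStructure, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to an ordered 0-based index array."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    if not spec.include_hetero:
        mask &= ~structure.hetero.astype(bool)
    if spec.chain is not None:
        mask &= structure.chain_id.astype(str) == spec.chain
    if spec.residue_intervals:
        res_mask = np.zeros(structure.n_atoms, dtype=bool)
        rid = structure.res_id
        for lo, hi in spec.residue_intervals:
            res_mask |= (rid >= lo) & (rid <= hi)
        mask &= res_mask
    names = np.char.strip(structure.atom_name.astype(str))
    if spec.atom_names is not None:
        mask &= np.isin(names, list(spec.atom_names))
    hydrogen = structure.is_hydrogen()
    if spec.atom_class == "heavy":
        mask &= ~hydrogen
    elif spec.atom_class == "backbone":
        mask &= np.isin(names, list(BACKBONE_ATOMS)) & ~hydrogen
    elif spec.atom_class == "sidechain":
        mask &= ~np.isin(names, list(BACKBONE_ATOMS)) & ~hydrogen
    elif spec.atom_class != "all":
        raise ValueError(f"unknown atom class {spec.atom_class!r}")
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _validate_pdb_lines(lines: Sequence[str]) -> None:
    """Check fixed-column numeric fields of ATOM/HETATM records up front so
    parse failures can name the offending line."""
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(
                f"line {lineno}: ATOM/HETATM record shorter than coordinate "
                f"columns (54 needed, got {len(line.rstrip())})"
            )
        for start, stop, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fielded = line[start:stop]
            try:
                float(fielded)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: non-numeric {what} coordinate field "
                    f"{fielded!r}"
                ) from None


def _structure_from_atom_array(arr: "_struc.AtomArray") -> MolecularStructure:
    elements = []
    for el, name, res in zip(arr.element, arr.atom_name, arr.res_name):
        el = str(el).strip()
        if not el:
            el = element_from_atom_name(str(name), str(res))
        elements.append(el)
    masses = np.array([atomic_mass(el) for el in elements])
    serial = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, arr.array_length() + 1))
    return MolecularStructure(
        serial=np.asarray(serial, dtype=int),
        atom_name=np.char.strip(arr.atom_name.astype(str)),
        res_name=np.char.strip(arr.res_name.astype(str)),
        chain_id=np.char.strip(arr.chain_id.astype(str)),
        res_id=np.asarray(arr.res_id, dtype=int),
        element=np.array(elements, dtype="U4"),
        mass=masses,
        coord=np.asarray(arr.coord, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
    )


def read_pdb(
    source: Union[str, io.TextIOBase],
    model_policy: Literal["first", "all"] = "first",
    frame_interval_ps: float = 10.0,
) -> Union[MolecularStructure, Trajectory]:
    """Read a PDB file or text stream.

    With ``model_policy='first'`` the first MODEL (or the sole coordinate
    block) becomes a :class:`MolecularStructure`.  With ``'all'`` every
    MODEL/ENDMDL block becomes a frame of a :class:`Trajectory` sharing the
    first model's topology; differing atom counts raise
    :class:`TopologyMismatchError`.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = text.splitlines()
    _validate_pdb_lines(lines)
    pdb_file = _pdb.PDBFile.read(io.StringIO(text))
    n_models = pdb_file.get_model_count()
    extra = ["atom_id", "occupancy"]
    first = pdb_file.get_structure(model=1, altloc="occupancy", extra_fields=extra)
    structure = _structure_from_atom_array(first)
    if model_policy == "first":
        return structure
    if model_policy != "all":
        raise ValueError(f"unknown model_policy {model_policy!r}")
    try:
        stack = pdb_file.get_structure(model=None, altloc="occupancy",
                                       extra_fields=extra)
    except Exception as exc:  # biotite raises on ragged models
        raise TopologyMismatchError(
            f"MODEL blocks have differing atom counts: {exc}"
        ) from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != structure.n_atoms:
        raise TopologyMismatchError(
            f"MODEL blocks have {coords.shape[1]} atoms, first model has "
            f"{structure.n_atoms}"
        )
    return Trajectory(topology=structure, coords=coords,
                      frame_interval_ps=frame_interval_ps)


def _to_atom_array(structure: MolecularStructure,
                   coord: np.ndarray) -> "_struc.AtomArray":
    arr = _struc.AtomArray(structure.n_atoms)
    arr.coord = np.asarray(coord, dtype=np.float32)
    arr.atom_name = structure.atom_name
    arr.res_name = structure.res_name
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_id
    arr.element = np.char.upper(structure.element.astype(str))
    arr.hetero = structure.hetero
    arr.set_annotation("atom_id", np.asarray(structure.serial, dtype=int))
    arr.set_annotation("occupancy", np.ones(structure.n_atoms))
    return arr


def write_frames(trajectory: Trajectory,
                 format: Literal["pdb", "xyz"] = "pdb") -> str:
    """Serialize a trajectory as multi-model PDB or XYZ text.

    Round trip guarantee: PDB coordinates survive to 3 decimal places
    (5e-4 Å), XYZ to the full printed precision (6 decimals).
    """
    top = trajectory.topology
    if format == "pdb":
        if any(len(n) > 4 for n in top.atom_name):
            bad = max(top.atom_name, key=len)
            raise FormatError(f"atom name {bad!r} exceeds PDB 4-column field")
        stack = _struc.AtomArrayStack(trajectory.n_frames, top.n_atoms)
        stack.coord = np.asarray(trajectory.coords, dtype=np.float32)
        template = _to_atom_array(top, trajectory.coords[0])
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        out = _pdb.PDBFile()
        out.set_structure(stack)
        buf = io.StringIO()
        out.write(buf)
        text = buf.getvalue()
        if "MODEL" not in text:
            # single-model stacks are written bare; keep the multi-model
            # dialect so every trajectory round-trips through MODEL blocks
            lines = text.splitlines(keepends=True)
            first = next(i for i, l in enumerate(lines)
                         if l.startswith(("ATOM", "HETATM")))
            last = max(i for i, l in enumerate(lines)
                       if l.startswith(("ATOM", "HETATM", "TER")))
            lines.insert(last + 1, "ENDMDL\n")
            lines.insert(first, "MODEL        1\n")
            text = "".join(lines)
        return text
    if format == "xyz":
        return write_xyz(trajectory)
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# XYZ (count line / comment line / "element x y z" records)
# ---------------------------------------------------------------------------

def write_xyz(trajectory: Trajectory) -> str:
    top = trajectory.topology
    chunks = []
    for f in range(trajectory.n_frames):
        chunks.append(f"{top.n_atoms}\n")
        chunks.append(f"frame {f} t={f * trajectory.frame_interval_ps:g} ps\n")
        for el, (x, y, z) in zip(top.element, trajectory.coords[f]):
            chunks.append(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
    return "".join(chunks)


def read_xyz(
    source: Union[str, io.TextIOBase],
    topology: Optional[MolecularStructure] = None,
    frame_interval_ps: float = 10.0,
) -> Trajectory:
    """Read an XYZ frame series.

    Without a topology a minimal one is synthesized (one pseudo-residue per
    atom, chain ``A``); with a topology the frames must match its atom count.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = text.splitlines()
    frames, elements = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise PDBParseError(f"line {i + 1}: expected atom count") from None
        block = lines[i + 2:i + 2 + count]
        if len(block) < count:
            raise PDBParseError(f"line {i + 1}: truncated XYZ frame")
        els, xyz = [], []
        for j, rec in enumerate(block):
            parts = rec.split()
            if len(parts) < 4:
                raise PDBParseError(f"line {i + 3 + j}: malformed XYZ record")
            els.append(parts[0])
            try:
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise PDBParseError(
                    f"line {i + 3 + j}: non-numeric XYZ coordinate"
                ) from None
        if elements is None:
            elements = els
        elif len(els) != len(elements):
            raise TopologyMismatchError("XYZ frames have differing atom counts")
        frames.append(xyz)
        i += 2 + count
    coords = np.array(frames, dtype=float)
    if topology is None:
        n = len(elements)
        topology = MolecularStructure(
            serial=np.arange(1, n + 1),
            atom_name=np.array(elements, dtype="U4"),
            res_name=np.array(["UNK"] * n, dtype="U4"),
            chain_id=np.array(["A"] * n, dtype="U4"),
            res_id=np.arange(1, n + 1),
            element=np.array(elements, dtype="U4"),
            mass=np.array([atomic_mass(e) for e in elements]),
            coord=coords[0],
            hetero=np.zeros(n, dtype=bool),
        )
    return Trajectory(topology=topology, coords=coords,
                      frame_interval_ps=frame_interval_ps)
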