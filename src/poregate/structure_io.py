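"""Structures, trajectories and profile tables.

Coordinate convention: Angstrom everywhere.  PDB parsing and writing is
delegated to biotite; multi-model PDB is the native trajectory format.
Profile tables are CSV with ``# key = value`` metadata header lines; a
``units`` key is mandatory so no profile changes meaning silently.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


class CongruenceError(ValueError):
    """Raised when trajectory frames disagree with their topology."""


@dataclass(frozen=True)
class Atom:
    """A single atom record (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} has invalid position {self.position}")
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered collection of atoms for one model.

    Stored column-wise (numpy arrays) for geometry; :meth:`atoms` yields
    :class:`Atom` records in file order.  Residue iteration order is
    deterministic: chain, then residue number, then file order.
    """

    def __init__(self, serial, name, element, residue_name, residue_number,
                 chain_id, coord, model_id: int = 1, metadata: dict | None = None):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.residue_name = np.asarray(residue_name, dtype="U4")
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype="U1")
        self.coord = np.asarray(coord, dtype=float).reshape(n, 3)
        self.model_id = int(model_id)
        self.metadata = dict(metadata or {})
        for arr in (self.name, self.element, self.residue_name,
                    self.residue_number, self.chain_id):
            if len(arr) != n:
                raise ValueError("column lengths disagree")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_id, self.residue_number, self.name))
        if len(set(keys)) != n:
            raise ValueError("(chain, residue_number, name) not unique within model")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], model_id: int = 1) -> "Structure":
        return cls(
            serial=[a.serial for a in atoms],
            name=[a.name for a in atoms],
            element=[a.element for a in atoms],
            residue_name=[a.residue_name for a in atoms],
            residue_number=[a.residue_number for a in atoms],
            chain_id=[a.chain_id for a in atoms],
            coord=[a.position for a in atoms],
            model_id=model_id,
        )

    # -- basic protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    @property
    def atoms(self) -> list[Atom]:
        return [Atom(int(s), str(n), str(e), str(rn), int(ri), str(c), p)
                for s, n, e, rn, ri, c, p in zip(
                    self.serial, self.name, self.element, self.residue_name,
                    self.residue_number, self.chain_id, self.coord)]

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        return Structure(self.serial[mask], self.name[mask], self.element[mask],
                         self.residue_name[mask], self.residue_number[mask],
                         self.chain_id[mask], self.coord[mask],
                         model_id=self.model_id, metadata=dict(self.metadata))

    def select(self, selection: str) -> np.ndarray:
        """Boolean mask for a selection string (mini-grammar).

        Clauses joined by ``and``: ``chain A``, ``resid 200-220`` (or a
        single number, or a comma list), ``name CA,CG``, ``resname HOH``.
        """
        return select_atoms(self, selection)

    def residues(self) -> Iterator[tuple[tuple[str, int], np.ndarray]]:
        """Yield ((chain_id, residue_number), atom index array), ordered by
        chain then residue number."""
        order = np.lexsort((self.residue_number, self.chain_id))
        seen: dict[tuple[str, int], list[int]] = {}
        for i in order:
            seen.setdefault((str(self.chain_id[i]), int(self.residue_number[i])), []).append(i)
        for key, idx in seen.items():
            yield key, np.array(sorted(idx), dtype=int)

    def residue_index(self) -> dict[tuple[str, int], np.ndarray]:
        return dict(self.residues())

    def with_coord(self, coord: np.ndarray) -> "Structure":
        return Structure(self.serial, self.name, self.element, self.residue_name,
                         self.residue_number, self.chain_id, coord,
                         model_id=self.model_id, metadata=dict(self.metadata))


@dataclass
class Trajectory:
    """Frames of coordinates congruent with a topology.

    frames: (n_frames, n_atoms, 3) Angstrom.  times (ns) optional,
    strictly increasing when present.  box: orthorhombic lengths, Angstrom.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise CongruenceError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise CongruenceError(
                f"frames have {self.frames.shape[1]} atoms, topology has {len(self.topology)}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise CongruenceError("times length mismatch")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coord(self.frames[i])


@dataclass
class ProfileTable:
    """Binned quantities along the pore (z) axis.

    z: bin centers (Angstrom), strictly increasing on a uniform grid.
    columns: named value arrays of the same length.  metadata must carry
    ``units`` and may carry a reference convention.
    """

    z: np.ndarray
    columns: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1 or len(self.z) < 1:
            raise ValueError("z must be a 1-D array")
        if len(self.z) > 1:
            dz = np.diff(self.z)
            if np.any(dz <= 0):
                raise ValueError("z must be strictly increasing")
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        for k, v in self.columns.items():
            if v.shape != self.z.shape:
                raise ValueError(f"column {k!r} length mismatch")

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if len(self.z) < 3:
            return True
        dz = np.diff(self.z)
        return bool(np.all(np.abs(dz - dz[0]) <= rtol * abs(dz[0])))

    @property
    def bin_width(self) -> float:
        return float(np.diff(self.z)[0]) if len(self.z) > 1 else np.nan


# ---------------------------------------------------------------------------
# selection mini-grammar
# ---------------------------------------------------------------------------

_RESID_RE = re.compile(r"^(-?\d+)(?:[-:](-?\d+))?$")


def select_atoms(structure: Structure, selection: str) -> np.ndarray:
    """Evaluate ``chain A and resid 200-220 and name CA`` style selections."""
    mask = np.ones(len(structure), dtype=bool)
    sel = selection.strip()
    if not sel:
        return mask
    for clause in re.split(r"\s+and\s+", sel):
        parts = clause.strip().split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"cannot parse selection clause {clause!r}")
        key, value = parts[0].lower(), parts[1].strip()
        if key == "chain":
            ids = {v.strip() for v in value.split(",")}
            mask &= np.isin(structure.chain_id, list(ids))
        elif key == "resid":
            sub = np.zeros(len(structure), dtype=bool)
            for item in value.split(","):
                m = _RESID_RE.match(item.strip())
                if not m:
                    raise ParseError(f"cannot parse resid term {item!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                sub |= (structure.residue_number >= lo) & (structure.residue_number <= hi)
            mask &= sub
        elif key == "name":
            names = {v.strip().upper() for v in value.split(",")}
            mask &= np.isin(np.char.upper(structure.name), list(names))
        elif key == "resname":
            names = {v.strip().upper() for v in value.split(",")}
            mask &= np.isin(np.char.upper(structure.residue_name), list(names))
        else:
            raise ParseError(f"unknown selection keyword {key!r}")
    return mask


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _source_to_pdbfile(source) -> tuple[_pdb.PDBFile, str]:
    if isinstance(source, (str, Path)) and str(source).strip() and "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise ParseError(f"no such file: {path}")
        text = path.read_text()
        label = str(path)
    else:
        text = str(source)
        label = "<string>"
    if not text.strip():
        raise ParseError(f"{label}: empty PDB input")
    try:
        return _pdb.PDBFile.read(io.StringIO(text)), label
    except Exception as exc:  # pragma: no cover - biotite raises early only rarely
        raise ParseError(f"{label}: {exc}") from exc


def _atomarray_to_structure(arr: struc.AtomArray, model_id: int) -> Structure:
    element = arr.element
    # biotite may leave element blank for nonstandard names; fall back to
    # the first alphabetic character of the atom name
    element = [e if e else re.sub(r"[^A-Za-z].*", "", n)[:1]
               for e, n in zip(element, arr.atom_name)]
    serial = arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories() \
        else np.arange(1, arr.array_length() + 1)
    return Structure(
        serial=serial, name=arr.atom_name, element=element,
        residue_name=arr.res_name, residue_number=arr.res_id,
        chain_id=arr.chain_id, coord=arr.coord, model_id=model_id,
    )


def read_structure(source, model: int = 1) -> Structure:
    """Read one model from PDB text or a PDB file path.

    The first model is returned unless ``model`` says otherwise.
    Coordinates are Angstrom, atoms in file order.
    """
    pdbfile, label = _source_to_pdbfile(source)
    try:
        arr = pdbfile.get_structure(model=model, altloc="first")
    except Exception as exc:
        line = _offending_line(pdbfile)
        raise ParseError(f"{label}: malformed PDB record{line}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{label}: no ATOM/HETATM records")
    return _atomarray_to_structure(arr, model_id=model)


def _offending_line(pdbfile: _pdb.PDBFile) -> str:
    for i, line in enumerate(pdbfile.lines, start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) < 54:
            return f" (line {i})"
    return ""


def read_trajectory(source, topology: Structure | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    All models must be congruent (same atom count and order); the first
    model (or the supplied ``topology``) defines atom identities.
    """
    pdbfile, label = _source_to_pdbfile(source)
    n_models = pdbfile.get_model_count()
    if n_models < 1:
        raise ParseError(f"{label}: no models")
    try:
        stack = pdbfile.get_structure(model=None, altloc="first")
    except Exception as exc:
        raise CongruenceError(
            f"{label}: models are not congruent (differing atom sets): {exc}") from exc
    top = topology if topology is not None else _atomarray_to_structure(stack[0], 1)
    if stack.array_length() != len(top):
        raise CongruenceError(
            f"{label}: {stack.array_length()} atoms per model, topology has {len(top)}")
    box = None
    if stack.box is not None:
        b = stack.box[0]
        box = np.array([b[0, 0], b[1, 1], b[2, 2]], dtype=float)
    return Trajectory(topology=top, frames=stack.coord.copy(), box=box)


def _structure_to_atomarray(structure: Structure) -> struc.AtomArray:
    arr = struc.AtomArray(len(structure))
    arr.coord = structure.coord.astype(np.float32)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.residue_number
    arr.res_name = structure.residue_name
    arr.atom_name = structure.name
    arr.element = np.char.upper(structure.element)
    arr.hetero = np.isin(structure.residue_name, ["HOH", "SOL", "WAT", "NA", "CL"])
    return arr


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as PDB (coordinates rounded to PDB's 1e-3 Angstrom)."""
    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(_structure_to_atomarray(structure))
    pdbfile.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB."""
    stack = struc.AtomArrayStack(traj.n_frames, len(traj.topology))
    template = _structure_to_atomarray(traj.topology)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.frames.astype(np.float32)
    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(stack)
    pdbfile.write(str(path))


# ---------------------------------------------------------------------------
# profile table I/O
# ---------------------------------------------------------------------------

def write_profile(table: ProfileTable, path, allow_nonuniform: bool = False) -> None:
    """Write a ProfileTable as CSV with ``# key = value`` metadata headers.

    Refuses non-uniform z grids unless ``allow_nonuniform`` is set.
    """
    if not table.is_uniform() and not allow_nonuniform:
        raise ValueError("non-uniform z grid; pass allow_nonuniform=True to override")
    if "units" not in table.metadata:
        raise ValueError("profile metadata must declare 'units'")
    path = Path(path)
    with path.open("w") as fh:
        for key, value in table.metadata.items():
            fh.write(f"# {key} = {value}\n")
        df = pd.DataFrame({"z": table.z, **table.columns})
        df.to_csv(fh, index=False, float_format="%.10g")


def read_profile(path) -> ProfileTable:
    """Read a profile CSV written by :func:`write_profile`."""
    path = Path(path)
    metadata: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                metadata[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    if "units" not in metadata:
        raise ParseError(f"{path}: profile header missing 'units' metadata")
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    if "z" not in df.columns:
        raise ParseError(f"{path}: profile table has no 'z' column")
    cols = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "z"}
    return ProfileTable(z=df["z"].to_numpy(dtype=float), columns=cols, metadata=metadata)
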