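"""Pore axis fitting, radius profiling and the residue-orientation metric.

The radius algorithm is the slab-minimum distance to a straight axis: for
each axial bin and frame the pore radius is the smallest (distance-to-axis
minus vdW radius) over atoms in the slab, floored at zero.  This is the
straight-axis approximation appropriate for near-straight, four-fold
symmetric channel pores; it is exactly reproducible, unlike off-axis
sphere maximization.

The orientation metric places a residue-local frame: origin at the Calpha,
x toward the pore axis (so pore-facing sidechains score x > 0), z along the
pore axis, y completing the right-handed frame; the reported point is the
(x, y) projection of the Calpha -> Cgamma vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import WATER_RESNAMES, vdw_radius
from .geometry import unit
from .structure_io import Structure, Trajectory


@dataclass(frozen=True)
class PoreAxis:
    """Pore axis: origin (Angstrom) and unit direction (+z extracellular)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def axial(self, coords: np.ndarray) -> np.ndarray:
        """Signed axial coordinate (z along the pore) of each point."""
        return (np.atleast_2d(coords) - self.origin) @ self.direction

    def radial(self, coords: np.ndarray) -> np.ndarray:
        """Distance of each point from the axis line."""
        rel = np.atleast_2d(coords) - self.origin
        axial = rel @ self.direction
        perp = rel - np.outer(axial, self.direction)
        return np.linalg.norm(perp, axis=1)


@dataclass
class PoreProfile:
    """Pore radius statistics per axial bin (all Angstrom)."""

    z: np.ndarray
    mean_radius: np.ndarray
    sd_radius: np.ndarray
    min_radius: np.ndarray
    max_radius: np.ndarray
    empty_flag: np.ndarray  # True where any frame had an empty slab


@dataclass(frozen=True)
class OrientationPoint:
    """(x, y) components of Calpha->Cgamma in the pore-centered frame."""

    structure_id: int
    chain_id: str
    residue_number: int
    x: float
    y: float


def fit_pore_axis(structure: Structure, subunit_selections) -> PoreAxis:
    """Fit the pore axis of a pseudo-four-fold bundle.

    ``subunit_selections``: four selection strings (or masks) with equal
    atom counts.  Origin is the centroid of all four; the direction is the
    bundle's principal axis, signed so it runs N-terminal to C-terminal
    (low to high residue number), which points toward the selectivity
    filter for a channel built N-in/C-out along the pore.
    """
    if len(subunit_selections) != 4:
        raise ValueError(f"need exactly 4 subunit selections, got {len(subunit_selections)}")
    masks = []
    for sel in subunit_selections:
        mask = structure.select(sel) if isinstance(sel, str) else np.asarray(sel, dtype=bool)
        masks.append(mask)
    counts = [int(m.sum()) for m in masks]
    if len(set(counts)) != 1:
        raise ValueError(f"subunit selections have unequal atom counts: {counts}")
    if counts[0] == 0:
        raise ValueError("empty subunit selection")

    all_mask = np.logical_or.reduce(masks)
    coords = structure.coord[all_mask]
    origin = coords.mean(axis=0)
    centered = coords - origin
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] < 1.5 * evals[1]:
        raise ValueError("degenerate bundle geometry: no dominant principal axis")
    direction = evecs[:, 2]

    # sign: point from low-residue-number half to high (N -> C)
    resnum = structure.residue_number[all_mask]
    med = np.median(resnum)
    lo = coords[resnum <= med].mean(axis=0)
    hi = coords[resnum > med].mean(axis=0) if np.any(resnum > med) else lo
    if np.dot(direction, hi - lo) < 0:
        direction = -direction
    return PoreAxis(origin=origin, direction=unit(direction))


def _protein_mask(structure: Structure) -> np.ndarray:
    return ~np.isin(np.char.upper(structure.residue_name), list(WATER_RESNAMES))


def radius_profile(traj: Trajectory, axis: PoreAxis, z_range: tuple,
                   bin_width: float = 1.0, selection=None,
                   probe_cap: float = 10.0) -> PoreProfile:
    """Pore radius profile with mean, SD and extremes over frames.

    Per frame and bin: radius = min over atoms in the slab of
    (distance-to-axis - vdW radius), floored at 0.  Empty slabs are reported
    at ``probe_cap`` and flagged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = traj.topology
    if selection is None:
        mask = _protein_mask(top)
    elif isinstance(selection, str):
        mask = top.select(selection)
    else:
        mask = np.asarray(selection, dtype=bool)
    if not mask.any():
        raise ValueError("no atoms selected for the radius profile")
    vdw = np.array([vdw_radius(e) for e in top.element[mask]])

    z0, z1 = z_range
    n_bins = int(round((z1 - z0) / bin_width))
    if n_bins < 1:
        raise ValueError("empty z range")
    centers = z0 + (np.arange(n_bins) + 0.5) * bin_width

    per_frame = np.empty((traj.n_frames, n_bins))
    empty = np.zeros(n_bins, dtype=bool)
    for f in range(traj.n_frames):
        coords = traj.frames[f][mask]
        zs = axis.axial(coords)
        rad = axis.radial(coords) - vdw
        bin_idx = np.floor((zs - z0) / bin_width).astype(int)
        inside = (bin_idx >= 0) & (bin_idx < n_bins)
        row = np.full(n_bins, np.inf)
        np.minimum.at(row, bin_idx[inside], rad[inside])
        is_empty = ~np.isfinite(row)
        empty |= is_empty
        row[is_empty] = probe_cap
        per_frame[f] = np.clip(row, 0.0, None)

    return PoreProfile(
        z=centers,
        mean_radius=per_frame.mean(axis=0),
        sd_radius=per_frame.std(axis=0),
        min_radius=per_frame.min(axis=0),
        max_radius=per_frame.max(axis=0),
        empty_flag=empty,
    )


def pore_lining_residues(structure: Structure, axis: PoreAxis, z_window: tuple,
                         cutoff: float = 6.0) -> list[tuple[tuple[str, int], float]]:
    """Residues with any atom within ``cutoff`` of the axis inside z_window.

    Returns ((chain, residue_number), min distance to axis), sorted by
    distance; an empty window yields an empty list.
    """
    z0, z1 = z_window
    zs = axis.axial(structure.coord)
    rad = axis.radial(structure.coord)
    in_window = (zs >= z0) & (zs <= z1) & (rad <= cutoff)
    best: dict[tuple[str, int], float] = {}
    for i in np.nonzero(in_window)[0]:
        key = (str(structure.chain_id[i]), int(structure.residue_number[i]))
        d = float(rad[i])
        if key not in best or d < best[key]:
            best[key] = d
    return sorted(best.items(), key=lambda kv: (kv[1], kv[0]))


def residue_orientation(structure: Structure, axis: PoreAxis,
                        residue: tuple[str, int],
                        structure_id: int = 0) -> OrientationPoint:
    """Orientation of a residue's Calpha->Cgamma vector in the pore frame.

    x > 0 means the sidechain points toward the pore axis.  The frame is
    built per residue: x from Calpha toward its own projection onto the
    axis, z along the axis, y = z cross x.  Invariant under global rigid
    motions and translations along the axis.
    """
    chain, resnum = str(residue[0]), int(residue[1])
    sub = structure.subset((structure.chain_id == chain)
                           & (structure.residue_number == resnum))
    atom_map = {str(n).upper(): c for n, c in zip(sub.name, sub.coord)}
    if "CA" not in atom_map:
        raise ValueError(f"residue {residue} has no CA atom")
    if "CG" not in atom_map:
        raise ValueError(f"residue {residue} has no CG atom")
    ca = atom_map["CA"]
    cg = atom_map["CG"]
    axial = float((ca - axis.origin) @ axis.direction)
    pore_point = axis.origin + axial * axis.direction
    to_axis = pore_point - ca
    if np.linalg.norm(to_axis) < 1e-9:
        raise ValueError(f"Calpha of residue {residue} lies on the pore axis; "
                         "orientation frame undefined")
    x_hat = unit(to_axis)
    z_hat = axis.direction - np.dot(axis.direction, x_hat) * x_hat
    z_hat = unit(z_hat) if np.linalg.norm(z_hat) > 1e-12 else axis.direction
    y_hat = np.cross(z_hat, x_hat)
    v = cg - ca
    return OrientationPoint(structure_id=structure_id, chain_id=chain,
                            residue_number=resnum,
                            x=float(v @ x_hat), y=float(v @ y_hat))
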