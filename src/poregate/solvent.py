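"""Water density along the pore, hydration free energy, wetting states.

The hydration free energy is the Boltzmann inversion of the axial water
number density, dG(z) = -kT ln(n(z)/n_bulk) — the standard channel-
annotation estimator.  Bins with zero density get a finite cap (default
+25 kJ/mol) and a flag rather than +inf, mirroring how published profiles
truncate dewetted gates.  Errors are first-order propagated: kT * sd/mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BULK_WATER_DENSITY, WATER_RESNAMES, kt
from .pore import PoreAxis
from .structure_io import ProfileTable, Trajectory


@dataclass
class DensityProfile:
    """Axial water number density (nm^-3) with per-bin statistics."""

    z: np.ndarray                  # bin centers, Angstrom
    mean_density: np.ndarray       # nm^-3
    sd_density: np.ndarray         # nm^-3, over frames
    bulk_density: float            # nm^-3
    sampling_area: float           # cylinder cross-section, nm^2
    bin_width: float               # Angstrom
    counts: np.ndarray             # (n_frames, n_bins) raw per-frame counts

    @property
    def bin_volume_nm3(self) -> float:
        return self.sampling_area * self.bin_width / 10.0


def water_mask(traj: Trajectory) -> np.ndarray:
    """Water oxygen atoms in the topology (HOH/SOL/TIP3/... residues)."""
    top = traj.topology
    is_water = np.isin(np.char.upper(top.residue_name), list(WATER_RESNAMES))
    is_oxygen = (np.char.upper(top.element) == "O") | np.char.startswith(
        np.char.upper(top.name), "O")
    return is_water & is_oxygen


def water_density_profile(traj: Trajectory, axis: PoreAxis,
                          cylinder_radius: float = 8.0, bin_width: float = 1.0,
                          z_range: tuple | None = None,
                          bulk_density: float | None = None,
                          stride: int = 1) -> DensityProfile:
    """Time-averaged water number density in a cylinder along the pore.

    Per frame, water oxygens within ``cylinder_radius`` of the axis are
    counted in axial bins; density = count / (pi r^2 dz) in nm^-3.  Mean and
    SD are over (strided) frames.  ``bulk_density`` defaults to the mean
    density over the two outermost 5-Angstrom z-bands, the region beyond
    the protein extent in a solvated channel system.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    if cylinder_radius <= 0:
        raise ValueError("cylinder_radius must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = water_mask(traj)
    if not mask.any():
        raise ValueError("no water oxygens in topology")

    frames = traj.frames[::max(int(stride), 1)]
    n_frames = len(frames)
    if z_range is None:
        zs_all = axis.axial(frames.reshape(-1, 3)[np.tile(mask, n_frames)])
        z_range = (float(np.floor(zs_all.min())), float(np.ceil(zs_all.max())))
    z0, z1 = z_range
    n_bins = int(round((z1 - z0) / bin_width))
    if n_bins < 1:
        raise ValueError("empty z range")
    centers = z0 + (np.arange(n_bins) + 0.5) * bin_width

    counts = np.zeros((n_frames, n_bins))
    for f in range(n_frames):
        coords = frames[f][mask]
        rad = axis.radial(coords)
        zs = axis.axial(coords)
        sel = rad <= cylinder_radius
        idx = np.floor((zs[sel] - z0) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(counts[f], idx[ok], 1)

    vol_nm3 = np.pi * (cylinder_radius / 10.0) ** 2 * (bin_width / 10.0)
    dens = counts / vol_nm3
    mean = dens.mean(axis=0)
    sd = dens.std(axis=0)

    if bulk_density is None:
        band = max(int(round(5.0 / bin_width)), 1)
        edge = np.r_[mean[:band], mean[-band:]]
        bulk_density = float(edge.mean())
        if bulk_density <= 0:
            raise ValueError("cannot estimate bulk density from edge bands; "
                             "supply bulk_density explicitly")
    return DensityProfile(z=centers, mean_density=mean, sd_density=sd,
                          bulk_density=float(bulk_density),
                          sampling_area=np.pi * (cylinder_radius / 10.0) ** 2,
                          bin_width=bin_width, counts=counts)


def hydration_free_energy(density: DensityProfile, temperature: float = 300.0,
                          cap: float = 25.0) -> ProfileTable:
    """Boltzmann-invert a density profile into dG(z) = -kT ln(n/n_bulk).

    Returns a ProfileTable with columns ``dg`` (kJ/mol), ``err`` (kJ/mol,
    first-order kT*sd/mean) and ``flag`` (1 where density was zero and the
    cap value was substituted).
    """
    kT = kt(temperature)
    if density.bulk_density <= 0:
        raise ValueError("bulk density must be positive")
    mean = density.mean_density
    dg = np.full_like(mean, float(cap))
    err = np.zeros_like(mean)
    flag = np.zeros_like(mean)
    nonzero = mean > 0
    dg[nonzero] = -kT * np.log(mean[nonzero] / density.bulk_density)
    err[nonzero] = kT * density.sd_density[nonzero] / mean[nonzero]
    flag[~nonzero] = 1.0
    return ProfileTable(
        z=density.z.copy(),
        columns={"dg": dg, "err": err, "flag": flag},
        metadata={"units": "kJ/mol", "reference": "bulk",
                  "temperature_K": temperature, "cap_kJ_mol": cap,
                  "bulk_density_nm3": density.bulk_density},
    )


@dataclass
class WettingSeries:
    """Per-frame hydration state of the gate region."""

    frame: np.ndarray          # frame indices
    count: np.ndarray          # water count in the gate window
    state: np.ndarray          # "wet" / "dry"
    threshold_count: float

    @property
    def n_transitions(self) -> int:
        wet = self.state == "wet"
        return int(np.sum(wet[1:] != wet[:-1]))


def classify_wetting(traj: Trajectory, axis: PoreAxis, gate_z_window: tuple,
                     threshold_fraction: float = 0.1,
                     cylinder_radius: float = 8.0,
                     bulk_density: float = BULK_WATER_DENSITY) -> WettingSeries:
    """Label each frame wet/dry from the gate water count.

    A frame is wet iff its count >= threshold_fraction times the count a
    bulk-density-filled gate cylinder would hold.
    """
    z0, z1 = gate_z_window
    if z1 <= z0:
        raise ValueError("empty gate window")
    mask = water_mask(traj)
    if not mask.any():
        raise ValueError("no water oxygens in topology")
    window_vol_nm3 = np.pi * (cylinder_radius / 10.0) ** 2 * ((z1 - z0) / 10.0)
    threshold = threshold_fraction * bulk_density * window_vol_nm3

    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        coords = traj.frames[f][mask]
        zs = axis.axial(coords)
        rad = axis.radial(coords)
        counts[f] = int(np.sum((zs >= z0) & (zs <= z1) & (rad <= cylinder_radius)))
    state = np.where(counts >= threshold, "wet", "dry")
    return WettingSeries(frame=np.arange(traj.n_frames), count=counts,
                         state=state, threshold_count=float(threshold))
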