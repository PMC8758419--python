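"""PMF post-processing, short-range interaction energies, pose clustering,
and ligand ionization/partition arithmetic.

PMF inputs are external profile tables (output of adaptive-bias sampling);
only the window averaging / error / reference-shift / barrier protocol is
implemented here, not the free-energy estimation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .constants import COULOMB_PREFACTOR, KJ_PER_KCAL, R_J_MOL_K
from .structure_io import ProfileTable, Trajectory


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile along the pore axis (kJ/mol, z in Angstrom)."""

    z: np.ndarray
    dg: np.ndarray
    err: np.ndarray
    reference: str = "raw"  # bulk | bilayer_center | raw

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.dg = np.asarray(self.dg, dtype=float)
        self.err = np.asarray(self.err, dtype=float)
        if not (self.z.shape == self.dg.shape == self.err.shape):
            raise ValueError("z/dg/err shape mismatch")
        if np.any(self.err < 0):
            raise ValueError("errors must be non-negative")

    def to_table(self) -> ProfileTable:
        return ProfileTable(z=self.z.copy(),
                            columns={"dg": self.dg.copy(), "err": self.err.copy()},
                            metadata={"units": "kJ/mol", "reference": self.reference})


def average_pmf(profiles: list[ProfileTable], column: str = "dg") -> FreeEnergyProfile:
    """Average windowed PMF estimates; error bars are the per-bin SD.

    This is the windowed-average protocol used for adaptive-bias output:
    profiles extracted at fixed intervals from the simulation tail are
    averaged per bin, with the standard deviation over the window set as
    the error bar.  All profiles must share the z grid exactly.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    z = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z.shape or not np.allclose(p.z, z, rtol=0, atol=1e-9):
            raise ValueError("profiles have mismatched z grids")
    data = np.stack([p.columns[column] for p in profiles])
    return FreeEnergyProfile(z=z.copy(), dg=data.mean(axis=0),
                             err=data.std(axis=0), reference="raw")


def shift_reference(profile: FreeEnergyProfile, mode: str,
                    anchor_z: float) -> FreeEnergyProfile:
    """Shift dg so the bin at ``anchor_z`` becomes the zero of energy.

    ``mode`` tags the new convention (``bulk`` or ``bilayer_center``);
    errors are unchanged.  Idempotent for a fixed anchor.
    """
    if mode not in ("bulk", "bilayer_center"):
        raise ValueError(f"unknown reference mode {mode!r}")
    half = np.inf if len(profile.z) < 2 else 0.5 * np.diff(profile.z).max() + 1e-9
    i = int(np.argmin(np.abs(profile.z - anchor_z)))
    if abs(profile.z[i] - anchor_z) > half:
        raise ValueError(f"anchor z={anchor_z} outside the profile grid")
    return FreeEnergyProfile(z=profile.z.copy(), dg=profile.dg - profile.dg[i],
                             err=profile.err.copy(), reference=mode)


@dataclass(frozen=True)
class Barrier:
    """Barrier height relative to a reference minimum."""

    height: float        # kJ/mol
    z_at_max: float      # Angstrom
    reference_dg: float  # kJ/mol, the minimum used as baseline

    @property
    def height_kcal(self) -> float:
        return self.height / KJ_PER_KCAL


def barrier_height(profile: FreeEnergyProfile, region_z: tuple,
                   reference_z: tuple | None = None) -> Barrier:
    """Barrier = max dg in the region minus the reference minimum.

    ``reference_z`` bounds the bulk-side window whose minimum serves as
    baseline; by default the minimum over the whole profile is used.  Ties
    at the maximum report the smaller z.  Invariant under shift_reference.
    """
    z0, z1 = region_z
    region = (profile.z >= z0) & (profile.z <= z1)
    if not region.any():
        raise ValueError("empty barrier region")
    if reference_z is None:
        ref_mask = np.ones_like(region)
    else:
        ref_mask = (profile.z >= reference_z[0]) & (profile.z <= reference_z[1])
        if not ref_mask.any():
            raise ValueError("empty reference window")
    ref = float(profile.dg[ref_mask].min())
    dg_region = profile.dg[region]
    i = int(np.argmax(dg_region))  # first max = smaller z on an increasing grid
    return Barrier(height=float(dg_region[i] - ref),
                   z_at_max=float(profile.z[region][i]),
                   reference_dg=ref)


@dataclass
class InteractionEnergyTable:
    """Mean +- SD short-range interaction energy per residue, kJ/mol."""

    energies: dict  # (chain, resnum) -> (mean, sd)
    cutoff: float   # Angstrom


def residue_ion_interaction_energy(traj: Trajectory, residue_selection,
                                   ion_selection, charges, sigma, epsilon,
                                   cutoff: float = 12.0) -> InteractionEnergyTable:
    """Short-range Coulomb + Lennard-Jones energy between residues and ions.

    Per frame, E = sum over pairs within ``cutoff`` (Angstrom) of
    f q_i q_j / r + 4 eps_ij ((sig_ij/r)^12 - (sig_ij/r)^6), r in nm,
    f = 138.935 kJ nm/(mol e^2); Lorentz-Berthelot combination.  Parameters
    are per-atom arrays aligned with the topology: charges (e),
    sigma (Angstrom), epsilon (kJ/mol).  Reported per residue of the
    residue selection as mean +- SD over frames.
    """
    top = traj.topology
    rmask = top.select(residue_selection) if isinstance(residue_selection, str) \
        else np.asarray(residue_selection, dtype=bool)
    imask = top.select(ion_selection) if isinstance(ion_selection, str) \
        else np.asarray(ion_selection, dtype=bool)
    if not rmask.any() or not imask.any():
        raise ValueError("empty residue or ion selection")
    charges = np.asarray(charges, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    for arr, label in ((charges, "charge"), (sigma, "sigma"), (epsilon, "epsilon")):
        if arr.shape != (len(top),):
            raise ValueError(f"{label} array must have one entry per topology atom")
        bad = np.nonzero(~np.isfinite(arr) & (rmask | imask))[0]
        if len(bad):
            i = bad[0]
            raise ValueError(
                f"missing {label} for atom {top.serial[i]} "
                f"({top.chain_id[i]} {top.residue_name[i]}{top.residue_number[i]} "
                f"{top.name[i]})")

    ridx = np.nonzero(rmask)[0]
    iidx = np.nonzero(imask)[0]
    res_keys = [(str(top.chain_id[i]), int(top.residue_number[i])) for i in ridx]
    unique_res = sorted(set(res_keys))
    res_of_atom = np.array([unique_res.index(k) for k in res_keys])

    sig_ij = 0.5 * (sigma[ridx][:, None] + sigma[iidx][None, :]) / 10.0  # nm
    eps_ij = np.sqrt(epsilon[ridx][:, None] * epsilon[iidx][None, :])
    qq = charges[ridx][:, None] * charges[iidx][None, :]

    per_frame = np.zeros((traj.n_frames, len(unique_res)))
    for f in range(traj.n_frames):
        d = np.linalg.norm(traj.frames[f][ridx][:, None, :]
                           - traj.frames[f][iidx][None, :, :], axis=2)
        within = d <= cutoff
        r_nm = d / 10.0
        with np.errstate(divide="ignore", invalid="ignore"):
            coul = COULOMB_PREFACTOR * qq / r_nm
            sr6 = (sig_ij / r_nm) ** 6
            lj = 4.0 * eps_ij * (sr6 ** 2 - sr6)
        e = np.where(within, coul + lj, 0.0)
        np.add.at(per_frame[f], res_of_atom, e.sum(axis=1))
    energies = {key: (float(per_frame[:, k].mean()), float(per_frame[:, k].std()))
                for k, key in enumerate(unique_res)}
    return InteractionEnergyTable(energies=energies, cutoff=cutoff)


@dataclass
class ClusterSet:
    """Single-linkage pose clusters (frame indices), largest first."""

    clusters: list = field(default_factory=list)
    representatives: list = field(default_factory=list)
    cutoff: float = 0.1  # nm


def _kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    u, _, vt = np.linalg.svd(mc.T @ rc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + reference.mean(axis=0)


def pose_rms_matrix(frames: np.ndarray, superpose: bool = False) -> np.ndarray:
    """Pairwise RMS distance between pose frames, in nm.

    By default no re-superposition is applied: the pose position in the
    channel frame is the clustered variable.  With ``superpose`` each frame
    is first least-squares fitted onto the first frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, n_atoms, 3)")
    n, m, _ = frames.shape
    if superpose:
        frames = np.stack([_kabsch_superpose(fr, frames[0]) for fr in frames])
    flat = frames.reshape(n, m * 3)
    # Euclidean distance of flattened coords = RMSD * sqrt(n_atoms)
    return squareform(pdist(flat) / np.sqrt(m) / 10.0)


def cluster_poses(frames, cutoff: float = 0.1, superpose: bool = False) -> ClusterSet:
    """Single-linkage clustering of ligand poses with an RMS cutoff.

    Two poses are linked when their RMS distance is strictly below
    ``cutoff`` (nm); clusters are the connected components, sorted by size
    (descending) then smallest member index.  The representative of each
    cluster is its medoid: the member minimizing the mean RMS distance to
    the rest of the cluster (ties toward the smaller index).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0 or len(frames) == 0:
        raise ValueError("empty frame list")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rms = pose_rms_matrix(frames, superpose=superpose)
    n = len(frames)
    adj = csr_matrix((rms < cutoff).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = [np.nonzero(labels == k)[0].tolist() for k in range(n_comp)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    reps = []
    for members in clusters:
        sub = rms[np.ix_(members, members)]
        mean_rms = sub.mean(axis=1)
        reps.append(members[int(np.argmin(mean_rms))])
    return ClusterSet(clusters=clusters, representatives=reps, cutoff=cutoff)


@dataclass(frozen=True)
class LigandIonization:
    """Henderson-Hasselbalch charged/neutral split of a weak acid or base."""

    pKa: float
    pH: float
    species: str
    charged_fraction: float

    @property
    def neutral_fraction(self) -> float:
        return 1.0 - self.charged_fraction

    @property
    def charged_percent(self) -> float:
        return 100.0 * self.charged_fraction


def ionization_fraction(pKa: float, pH: float, species: str = "base") -> LigandIonization:
    """Charged fraction at a given pH.

    Base: charged (protonated) fraction = 1/(1+10^(pH-pKa)); acid:
    charged (deprotonated) fraction = 1/(1+10^(pKa-pH)).
    """
    if not (np.isfinite(pKa) and np.isfinite(pH)):
        raise ValueError("pKa and pH must be finite")
    if species == "base":
        frac = 1.0 / (1.0 + 10.0 ** (pH - pKa))
    elif species == "acid":
        frac = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    else:
        raise ValueError(f"species must be 'acid' or 'base', got {species!r}")
    return LigandIonization(pKa=pKa, pH=pH, species=species, charged_fraction=float(frac))


def logp_to_dg(logP: float, temperature: float = 298.0) -> float:
    """Partition free energy (kJ/mol) from a partition coefficient.

    dG = -ln(10) R T logP; logP > 0 (prefers the lipid phase) gives a
    negative water->lipid transfer free energy.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(-np.log(10.0) * R_J_MOL_K * temperature * logP / 1000.0)
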