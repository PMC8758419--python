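"""Synthetic fixtures: ideal helices, C4 toy channels, Boltzmann water fields,
noisy PMF windows, and planted ligand-pose ensembles.

Every generator is a pure function of its arguments and seed: identical
inputs give bit-identical outputs.  These fixtures emulate the statistical
structure of channel simulation output (axial water densities following
``density = bulk * exp(-dG(z)/kT)``, C4-symmetric pore bundles, windowed
PMF estimates with independent noise) without any molecular dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BULK_WATER_DENSITY, kt, vdw_radius
from .geometry import place_atom, rotation_about_axis, rotation_aligning, unit
from .structure_io import ProfileTable, Structure, Trajectory

# canonical backbone internal coordinates (Engh-Huber-like ideal values)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_C_N_CA = 121.7
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_CA_C_O = 120.8
_OMEGA = 180.0

#: canonical helix dihedrals (phi, psi), degrees.  The pi values are the
#: ideal repeating conformation that yields i+5->i hydrogen bonds; the
#: average dihedrals reported from (distorted) observed pi-helices,
#: (-76, -41), do not hydrogen-bond at i+5 when repeated exactly.
HELIX_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "pi": (-55.0, -70.0),
    "three_ten": (-49.0, -26.0),
}

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA_1TO3 = {v: k for k, v in _AA_3TO1.items()}


def three_to_one(res_name: str) -> str:
    return _AA_3TO1.get(res_name.upper(), "X")


def one_to_three(code: str) -> str:
    return _AA_1TO3.get(code.upper(), "UNK")


def make_ideal_helix(n_residues: int, kind: str = "alpha",
                     sequence: str | None = None, chain_id: str = "A",
                     first_residue_number: int = 1) -> Structure:
    """Build a poly-residue helix backbone from canonical dihedrals.

    Backbone atoms N, CA, C, O per residue (amide H is reconstructed by the
    hydrogen-bond detector when needed).  alpha: phi=-57, psi=-47;
    pi: phi=-76, psi=-41; three_ten: phi=-49, psi=-26.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if kind not in HELIX_DIHEDRALS:
        raise ValueError(f"unknown helix kind {kind!r}; expected one of {sorted(HELIX_DIHEDRALS)}")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    phi, psi = HELIX_DIHEDRALS[kind]

    n = np.array([0.0, 0.0, 0.0])
    ca = n + np.array([_BOND_N_CA, 0.0, 0.0])
    # seed the first C with an arbitrary reference point; absolute placement
    # of the first residue does not matter (helix is defined up to rigid motion)
    c = place_atom(n + np.array([0.0, 1.0, 0.0]), n, ca, _BOND_CA_C, _ANG_N_CA_C, -60.0)

    backbone = [(n, ca, c)]
    for _ in range(n_residues - 1):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psi)
        ca_next = place_atom(ca_prev, c_prev, n_next, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c_next = place_atom(c_prev, n_next, ca_next, _BOND_CA_C, _ANG_N_CA_C, phi)
        backbone.append((n_next, ca_next, c_next))

    serial, names, elements, res_names, res_ids, chains, coords = [], [], [], [], [], [], []
    s = 1
    for i, (npos, capos, cpos) in enumerate(backbone):
        res_num = first_residue_number + i
        res_name = one_to_three(sequence[i])
        if i + 1 < n_residues:
            n_next = backbone[i + 1][0]
            opos = place_atom(n_next, capos, cpos, _BOND_C_O, _ANG_CA_C_O, 180.0)
        else:
            # last residue: place O with the same psi-locked torsion
            opos = place_atom(npos, capos, cpos, _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
        for atom_name, el, pos in (("N", "N", npos), ("CA", "C", capos),
                                   ("C", "C", cpos), ("O", "O", opos)):
            serial.append(s); names.append(atom_name); elements.append(el)
            res_names.append(res_name); res_ids.append(res_num)
            chains.append(chain_id); coords.append(pos)
            s += 1
    return Structure(serial, names, elements, res_names, res_ids, chains, coords,
                     metadata={"generator": "make_ideal_helix", "kind": kind})


@dataclass
class ToyChannelSpec:
    """Four-fold symmetric helix bundle with a tunable gate ring.

    gate_radius is the pore radius (atom surface to axis, Angstrom) produced
    by the gate-ring pseudo-Cgamma atoms.  gate_ring_position is a 1-based
    residue index along each helix.  inward_residue_toggle points the
    gate-ring sidechains toward (True) or away from (False) the pore.
    """

    helix_length: int = 20
    bundle_radius: float = 10.0
    gate_radius: float = 4.3
    gate_ring_position: int = 10
    inward_residue_toggle: bool = True
    n_subunits: int = 4
    first_residue_number: int = 201
    chain_ids: tuple = ("A", "B", "C", "D")

    def __post_init__(self):
        if self.n_subunits != 4:
            raise ValueError("toy channel is four-fold symmetric: n_subunits must be 4")
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be positive")
        if self.helix_length < 10:
            raise ValueError("helix_length must be >= 10")
        if not 1 <= self.gate_ring_position <= self.helix_length:
            raise ValueError("gate_ring_position outside helix")


def make_toy_channel(spec: ToyChannelSpec) -> Structure:
    """Place four ideal alpha-helices with C4 symmetry about z.

    Each helix runs N-terminus at low z.  The designated gate-ring residue
    (named ASN) carries CB and pseudo-CG atoms pointing toward or away from
    the pore axis; the CG is positioned so that the pore radius at the gate
    equals ``spec.gate_radius`` (atom center at gate_radius + vdW(C)).
    """
    seq = ["A"] * spec.helix_length
    seq[spec.gate_ring_position - 1] = "N"
    helix = make_ideal_helix(spec.helix_length, "alpha", sequence="".join(seq),
                             chain_id="A", first_residue_number=spec.first_residue_number)
    coords = helix.coord.copy()
    ca = coords[np.char.equal(helix.name, "CA")]
    centroid = ca.mean(axis=0)
    # principal axis of the helix, oriented N->C
    u, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    rot = rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
    coords = (coords - centroid) @ rot.T
    coords[:, 0] += spec.bundle_radius

    chains_atoms = []
    gate_resnum = spec.first_residue_number + spec.gate_ring_position - 1
    for k, chain_id in enumerate(spec.chain_ids[: spec.n_subunits]):
        r = rotation_about_axis([0, 0, 1], 90.0 * k)
        c = coords @ r.T
        st = Structure(helix.serial, helix.name, helix.element, helix.residue_name,
                       helix.residue_number, [chain_id] * len(helix), c)
        chains_atoms.append(_add_gate_sidechain(st, gate_resnum, spec))
    return _concat_structures(chains_atoms,
                              metadata={"generator": "make_toy_channel",
                                        "gate_residue_number": gate_resnum,
                                        "gate_radius": spec.gate_radius})


def _add_gate_sidechain(chain: Structure, gate_resnum: int, spec: ToyChannelSpec) -> Structure:
    mask = chain.residue_number == gate_resnum
    ca = chain.coord[mask & np.char.equal(chain.name, "CA")][0]
    radial = unit(np.array([ca[0], ca[1], 0.0]))
    if spec.inward_residue_toggle:
        # CG surface defines the gate: center at gate_radius + vdW(C) from axis
        cg_xy = radial * (spec.gate_radius + vdw_radius("C"))
    else:
        cg_xy = radial * (np.hypot(ca[0], ca[1]) + 2.5)
    cg = np.array([cg_xy[0], cg_xy[1], ca[2]])
    cb = ca + (cg - ca) * 0.45
    n = len(chain)
    extra = Structure(
        serial=[n + 1, n + 2], name=["CB", "CG"], element=["C", "C"],
        residue_name=["ASN", "ASN"], residue_number=[gate_resnum, gate_resnum],
        chain_id=[chain.chain_id[0], chain.chain_id[0]], coord=[cb, cg])
    return _concat_structures([chain, extra])


def _concat_structures(parts: list[Structure], metadata: dict | None = None) -> Structure:
    serial = np.arange(1, sum(len(p) for p in parts) + 1)
    cat = lambda attr: np.concatenate([getattr(p, attr) for p in parts])
    st = Structure(serial, cat("name"), cat("element"), cat("residue_name"),
                   cat("residue_number"), cat("chain_id"),
                   np.concatenate([p.coord for p in parts], axis=0),
                   metadata=metadata)
    # overlap guard: atoms from different chains must not clash
    chain_ids = np.unique(st.chain_id)
    if len(chain_ids) > 1 and metadata and metadata.get("generator") == "make_toy_channel":
        from scipy.spatial import cKDTree
        for i, ci in enumerate(chain_ids):
            for cj in chain_ids[i + 1:]:
                a = st.coord[st.chain_id == ci]
                b = st.coord[st.chain_id == cj]
                if cKDTree(a).query(b, k=1)[0].min() < 1.5:
                    raise ValueError("helices overlap: bundle_radius too small")
    return st


@dataclass
class SolventFieldSpec:
    """Water field Boltzmann-distributed against an imposed axial dG*(z).

    dg_profile: list of Gaussians (height kJ/mol, center Angstrom,
    width Angstrom); the imposed free energy is their sum.  Densities are
    nm^-3; geometry is a cylinder of ``cylinder_radius`` Angstrom spanning
    ``z_range`` Angstrom in bins of ``bin_width``.
    """

    dg_profile: list = field(default_factory=list)
    bulk_density: float = BULK_WATER_DENSITY
    cylinder_radius: float = 8.0
    z_range: tuple = (-30.0, 30.0)
    bin_width: float = 1.0
    n_frames: int = 100
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be positive")
        for h, c, w in self.dg_profile:
            if w <= 0:
                raise ValueError("Gaussian widths must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def imposed_dg(self, z: np.ndarray) -> np.ndarray:
        """Evaluate the imposed free-energy profile dG*(z) in kJ/mol."""
        z = np.asarray(z, dtype=float)
        dg = np.zeros_like(z)
        for height, center, width in self.dg_profile:
            dg += height * np.exp(-((z - center) ** 2) / (2.0 * width ** 2))
        return dg

    def bin_centers(self) -> np.ndarray:
        z0, z1 = self.z_range
        n_bins = int(round((z1 - z0) / self.bin_width))
        return z0 + (np.arange(n_bins) + 0.5) * self.bin_width


def sample_waters(spec: SolventFieldSpec) -> Trajectory:
    """Sample water oxygens against the imposed profile, frame by frame.

    Per frame and axial bin the water count is Poisson with mean
    ``bulk * exp(-dG*(z)/kT) * pi r^2 dz`` (volume converted to nm^3), and
    positions are uniform within the bin cylinder.  Frames are padded to a
    common atom count with inactive waters parked far beyond the sampled
    z-range (z_max + 100 Angstrom) so the Trajectory congruence invariant
    holds; parked waters fall outside every analysis bin.
    """
    rng = np.random.default_rng(spec.seed)
    z = spec.bin_centers()
    n_bins = len(z)
    kT = kt(spec.temperature)
    vol_nm3 = np.pi * (spec.cylinder_radius / 10.0) ** 2 * (spec.bin_width / 10.0)
    mean_counts = spec.bulk_density * np.exp(-spec.imposed_dg(z) / kT) * vol_nm3
    counts = rng.poisson(mean_counts, size=(spec.n_frames, n_bins))
    n_max = int(counts.sum(axis=1).max())
    park_z = spec.z_range[1] + 100.0

    # parked coordinates stay within PDB's fixed-column range
    frames = np.full((spec.n_frames, max(n_max, 1), 3), [500.0, 500.0, park_z], dtype=float)
    for f in range(spec.n_frames):
        total = int(counts[f].sum())
        if total == 0:
            continue
        zs = np.repeat(z, counts[f]) + rng.uniform(-0.5, 0.5, total) * spec.bin_width
        # uniform in the disk
        r = spec.cylinder_radius * np.sqrt(rng.uniform(0.0, 1.0, total))
        theta = rng.uniform(0.0, 2.0 * np.pi, total)
        frames[f, :total, 0] = r * np.cos(theta)
        frames[f, :total, 1] = r * np.sin(theta)
        frames[f, :total, 2] = zs

    n_atoms = frames.shape[1]
    topo = Structure(
        serial=np.arange(1, n_atoms + 1),
        name=["O"] * n_atoms, element=["O"] * n_atoms,
        residue_name=["HOH"] * n_atoms,
        residue_number=np.arange(1, n_atoms + 1),
        chain_id=["W"] * n_atoms,
        coord=frames[0],
        metadata={"generator": "sample_waters", "seed": spec.seed,
                  "bulk_density": spec.bulk_density,
                  "cylinder_radius": spec.cylinder_radius,
                  "park_z": park_z},
    )
    return Trajectory(topology=topo, frames=frames)


def make_pmf_windows(base_profile: ProfileTable, n_windows: int,
                     noise_sd: float, seed: int = 0) -> list[ProfileTable]:
    """Windowed PMF estimates: base plus i.i.d. per-bin Gaussian noise.

    Emulates profiles extracted at fixed intervals from the tail of an
    adaptive-bias run, whose spread yields the reported error bars.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    base = base_profile.columns["dg"]
    out = []
    for i in range(n_windows):
        noisy = base + rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else base.copy()
        out.append(ProfileTable(
            z=base_profile.z.copy(), columns={"dg": noisy},
            metadata={**base_profile.metadata, "window": i, "seed": seed,
                      "units": base_profile.metadata.get("units", "kJ/mol")}))
    return out


@dataclass
class PoseEnsemble:
    """Ligand pose frames (Angstrom) with the planted cluster labels."""

    frames: np.ndarray
    labels: np.ndarray
    centroids_nm: np.ndarray


# rigid 5-atom dummy ligand, Angstrom
_LIGAND_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [1.4, 0.0, 0.0],
    [2.1, 1.2, 0.0],
    [1.4, 2.4, 0.0],
    [0.0, 2.4, 0.6],
])


def make_pose_ensemble(cluster_centroids, members_per_cluster, spread_nm: float,
                       seed: int = 0) -> PoseEnsemble:
    """Rigid ligand copies jittered uniformly within ``spread_nm`` of each
    centroid (centroids in nm).  Requires spread < half the minimum centroid
    separation so the planted partition is recoverable."""
    centroids = np.atleast_2d(np.asarray(cluster_centroids, dtype=float))
    if np.isscalar(members_per_cluster):
        members = [int(members_per_cluster)] * len(centroids)
    else:
        members = [int(m) for m in members_per_cluster]
    if len(members) != len(centroids):
        raise ValueError("members_per_cluster length mismatch")
    if len(centroids) > 1:
        from scipy.spatial.distance import pdist
        min_sep = pdist(centroids).min()
        if spread_nm >= 0.5 * min_sep:
            raise ValueError(
                f"spread {spread_nm} nm >= half the minimum centroid separation "
                f"({0.5 * min_sep:.3g} nm); planted clusters would merge")
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for ci, (centroid, m) in enumerate(zip(centroids, members)):
        for _ in range(m):
            # uniform in a ball of radius spread_nm
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * spread_nm * rng.uniform() ** (1.0 / 3.0)
            offset_angstrom = (centroid + v) * 10.0
            frames.append(_LIGAND_TEMPLATE + offset_angstrom)
            labels.append(ci)
    return PoseEnsemble(frames=np.array(frames), labels=np.array(labels),
                        centroids_nm=centroids)
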