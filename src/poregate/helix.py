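"""Backbone hydrogen-bond detection and helical-pattern classification.

The default hydrogen-bond criterion is the DSSP electrostatic energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol

with a bond accepted when E < -0.5 kcal/mol.  A purely geometric fallback
(donor-acceptor distance <= 3.5 Angstrom, D-H...A angle >= 120 deg) is
selectable.  Amide hydrogens are reconstructed when the input lacks them
(X-ray structures usually do), along the direction opposing the bisector of
the N-C(prev) and N-CA bonds, N-H = 1.01 Angstrom.

Classification follows the helical hydrogen-bond registers: a residue
participating in an i+5->i bond is labelled ``pi``, i+4->i ``alpha``,
i+3->i ``three_ten``.  A residue that could form an i+4 bond within the
segment but participates in no helical bond at all is a ``defect``; maximal
runs of defects are reported as defect segments, the signature of a helix
kink or an alpha->pi transition boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import reconstruct_amide_hydrogens, unit
from .structure_io import Structure

DSSP_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom
DSSP_ENERGY_CUTOFF = -0.5  # kcal/mol

ResidueId = tuple[str, int]


@dataclass(frozen=True)
class BackboneHBond:
    """A donor(N-H) -> acceptor(C=O) backbone hydrogen bond."""

    donor_residue: ResidueId
    acceptor_residue: ResidueId
    offset: int  # donor residue number - acceptor residue number
    energy: float  # kcal/mol (DSSP) or geometric score (negative = stronger)


@dataclass
class HelixAnnotation:
    """Per-residue helical labels over an analyzed segment."""

    labels: dict[ResidueId, str]
    unpaired_carbonyls: list[ResidueId] = field(default_factory=list)
    defect_segments: list[tuple[ResidueId, ResidueId]] = field(default_factory=list)


def _backbone_index(structure: Structure, mask: np.ndarray | None):
    """Map residue id -> {atom name -> coordinate} for backbone atoms."""
    idx: dict[ResidueId, dict[str, np.ndarray]] = {}
    sel = np.ones(len(structure), dtype=bool) if mask is None else np.asarray(mask)
    for i in np.nonzero(sel)[0]:
        name = str(structure.name[i]).upper()
        if name in ("N", "CA", "C", "O", "H", "HN"):
            key = (str(structure.chain_id[i]), int(structure.residue_number[i]))
            idx.setdefault(key, {})["H" if name == "HN" else name] = structure.coord[i]
    return idx


def _resolve_selection(structure: Structure, selection) -> np.ndarray | None:
    if selection is None:
        return None
    if isinstance(selection, str):
        return structure.select(selection)
    return np.asarray(selection, dtype=bool)


def _residue_names(structure: Structure) -> dict[ResidueId, str]:
    return {(str(c), int(r)): str(n) for c, r, n in
            zip(structure.chain_id, structure.residue_number, structure.residue_name)}


def dssp_energy(n, h, c, o) -> float:
    """DSSP electrostatic hydrogen-bond energy, kcal/mol."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing atoms, not a bond
        return np.inf
    return DSSP_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _geometric_score(n, h, o, max_dist: float, min_angle: float) -> float:
    """Negative donor-acceptor distance if the geometric criterion passes."""
    d = np.linalg.norm(o - n)
    if d > max_dist:
        return np.inf
    # D-H...A angle: angle at H between H->D and H->A
    hd = unit(n - h)
    ha = unit(o - h)
    angle = np.degrees(np.arccos(np.clip(np.dot(hd, ha), -1.0, 1.0)))
    if angle < min_angle:
        return np.inf
    return -(max_dist - d)


def detect_backbone_hbonds(structure: Structure, selection=None,
                           criterion: str = "dssp",
                           energy_cutoff: float = DSSP_ENERGY_CUTOFF,
                           max_distance: float = 3.5, min_angle: float = 120.0,
                           min_offset: int = 2) -> list[BackboneHBond]:
    """Detect backbone N-H -> O=C hydrogen bonds within a selection.

    Each donor keeps at most its best-scoring acceptor (lowest energy; ties
    broken toward the smaller sequence offset).  Residues missing backbone
    atoms are skipped with a warning.  Only intra-chain bonds with
    donor - acceptor >= ``min_offset`` are considered.
    """
    if criterion not in ("dssp", "geom"):
        raise ValueError(f"unknown criterion {criterion!r}")
    mask = _resolve_selection(structure, selection)
    residues = _backbone_index(structure, mask)
    names = _residue_names(structure)

    # reconstruct amide H where needed
    hydrogens: dict[ResidueId, np.ndarray] = {}
    for (chain, resnum), atoms in residues.items():
        if names.get((chain, resnum), "").upper() == "PRO":
            continue  # proline has no amide hydrogen
        if "H" in atoms:
            hydrogens[(chain, resnum)] = atoms["H"]
            continue
        prev = residues.get((chain, resnum - 1))
        if "N" in atoms and "CA" in atoms and prev is not None and "C" in prev:
            hydrogens[(chain, resnum)] = reconstruct_amide_hydrogens(
                atoms["N"], atoms["CA"], prev["C"])

    bonds: list[BackboneHBond] = []
    for donor, datoms in sorted(residues.items()):
        if "N" not in datoms or "CA" not in datoms:
            if set(datoms) - {"O", "C"}:
                warnings.warn(f"residue {donor} missing backbone N/CA; skipped as donor")
            continue
        h = hydrogens.get(donor)
        if h is None:
            continue
        best: tuple[float, int, ResidueId] | None = None
        for acceptor, aatoms in residues.items():
            if acceptor[0] != donor[0]:
                continue
            offset = donor[1] - acceptor[1]
            if offset < min_offset:
                continue
            if "C" not in aatoms or "O" not in aatoms:
                warnings.warn(f"residue {acceptor} missing backbone C/O; skipped as acceptor")
                continue
            if criterion == "dssp":
                e = dssp_energy(datoms["N"], h, aatoms["C"], aatoms["O"])
                accept = e < energy_cutoff
            else:
                e = _geometric_score(datoms["N"], h, aatoms["O"], max_distance, min_angle)
                accept = np.isfinite(e)
            if accept:
                cand = (float(e), offset, acceptor)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is not None:
            e, offset, acceptor = best
            bonds.append(BackboneHBond(donor, acceptor, offset, e))
    return bonds


def classify_helix_pattern(hbonds: list[BackboneHBond], segment) -> HelixAnnotation:
    """Label each segment residue alpha / pi / three_ten / defect / none.

    ``segment`` is an iterable of residue ids (chain, residue_number),
    assumed contiguous per chain.  pi takes precedence over alpha over
    three_ten (an i+5 bond is the pi-helix signature even where i+4 bonds
    survive).  ``defect`` marks residues that could form an i+4 bond within
    the segment but participate in no helical bond; maximal defect runs
    become defect_segments, and carbonyls accepting no bond despite an
    available in-segment donor are reported as unpaired.
    """
    segment = sorted(set(tuple(r) for r in segment))
    if not segment:
        raise ValueError("empty segment")
    seg_set = set(segment)

    offsets: dict[ResidueId, set[int]] = {r: set() for r in segment}
    accepted: set[ResidueId] = set()
    for b in hbonds:
        if b.donor_residue in offsets:
            offsets[b.donor_residue].add(b.offset)
        if b.acceptor_residue in offsets:
            offsets[b.acceptor_residue].add(b.offset)
            accepted.add(b.acceptor_residue)

    labels: dict[ResidueId, str] = {}
    for chain, num in segment:
        offs = offsets[(chain, num)]
        if 5 in offs:
            labels[(chain, num)] = "pi"
        elif 4 in offs:
            labels[(chain, num)] = "alpha"
        elif 3 in offs:
            labels[(chain, num)] = "three_ten"
        else:
            could_donate = (chain, num - 4) in seg_set
            could_accept = (chain, num + 4) in seg_set
            labels[(chain, num)] = "defect" if (could_donate or could_accept) else "none"

    defect_segments: list[tuple[ResidueId, ResidueId]] = []
    run_start = None
    prev = None
    for rid in segment:
        is_defect = labels[rid] == "defect"
        contiguous = prev is not None and rid[0] == prev[0] and rid[1] == prev[1] + 1
        if is_defect and run_start is not None and contiguous:
            pass
        elif is_defect:
            if run_start is not None:
                defect_segments.append((run_start, prev))
            run_start = rid
        else:
            if run_start is not None:
                defect_segments.append((run_start, prev))
                run_start = None
        prev = rid
    if run_start is not None:
        defect_segments.append((run_start, prev))

    unpaired = [rid for rid in segment
                if rid not in accepted
                and ((rid[0], rid[1] + 4) in seg_set or (rid[0], rid[1] + 5) in seg_set)]
    return HelixAnnotation(labels=labels, unpaired_carbonyls=unpaired,
                           defect_segments=defect_segments)


def annotate_helix(structure: Structure, selection=None, criterion: str = "dssp",
                   **kwargs) -> tuple[HelixAnnotation, list[BackboneHBond]]:
    """Convenience: detect bonds then classify, over one selection."""
    mask = _resolve_selection(structure, selection)
    bonds = detect_backbone_hbonds(structure, mask, criterion=criterion, **kwargs)
    residues = _backbone_index(structure, mask)
    annotation = classify_helix_pattern(bonds, sorted(residues))
    return annotation, bonds


_SIDECHAIN_AMIDE = {"ASN": ("ND2", "OD1", "CG"), "GLN": ("NE2", "OE1", "CD")}


def detect_asn_sidechain_hbond(structure: Structure, residue: ResidueId,
                               max_distance: float = 3.5,
                               min_angle: float = 120.0) -> list[tuple[ResidueId, int]]:
    """Hydrogen bonds between an Asn/Gln sidechain amide and backbone atoms.

    Looks for the sidechain N-H donating to a backbone carbonyl O, and the
    sidechain O accepting from a backbone amide N-H.  Returns
    (partner_residue, offset) with offset = partner - residue, e.g. -4 for
    the one-helical-turn-below contact conserved in channel pore helices.
    """
    chain, resnum = str(residue[0]), int(residue[1])
    names = _residue_names(structure)
    res_name = names.get((chain, resnum))
    if res_name is None:
        raise ValueError(f"residue {residue} not found")
    if res_name.upper() not in _SIDECHAIN_AMIDE:
        raise ValueError(f"residue {residue} ({res_name}) has no sidechain amide")
    nd_name, od_name, cg_name = _SIDECHAIN_AMIDE[res_name.upper()]

    own = structure.subset((structure.chain_id == chain)
                           & (structure.residue_number == resnum))
    atom_map = {str(n).upper(): c for n, c in zip(own.name, own.coord)}
    if nd_name not in atom_map or od_name not in atom_map:
        raise ValueError(f"residue {residue} lacks sidechain amide atoms "
                         f"{nd_name}/{od_name}")
    nd = atom_map[nd_name]
    od = atom_map[od_name]
    side_h = [c for n, c in atom_map.items() if n.startswith("HD2") or n.startswith("HE2")]

    residues = _backbone_index(structure, None)
    hits: list[tuple[ResidueId, int]] = []
    for partner, atoms in sorted(residues.items()):
        if partner == (chain, resnum):
            continue
        offset = partner[1] - resnum if partner[0] == chain else None
        if offset is None:
            continue
        # sidechain N-H -> backbone O
        if "O" in atoms and np.linalg.norm(atoms["O"] - nd) <= max_distance:
            ok = True
            if side_h:
                angles = []
                for h in side_h:
                    hd = unit(nd - h)
                    ha = unit(atoms["O"] - h)
                    angles.append(np.degrees(np.arccos(np.clip(np.dot(hd, ha), -1, 1))))
                ok = max(angles) >= min_angle
            if ok:
                hits.append((partner, offset))
                continue
        # backbone N-H -> sidechain O
        if "N" in atoms and np.linalg.norm(atoms["N"] - od) <= max_distance:
            hits.append((partner, offset))
    return hits
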