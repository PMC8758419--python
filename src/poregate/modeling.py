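"""Register-shift (pi-helix) model construction.

A pi-helix inserts one extra residue per turn, which re-registers the
sequence on the downstream backbone by one position.  The recipe is a
gapped template/target self-alignment: one gap in the template row
immediately before the first shifted residue and one gap in the target row
immediately after the last, so every target residue k inside the region
pairs with template residue k-1 ("one position upstream").  Threading then
copies the template partner's backbone coordinates onto each target
residue; the gap-bridged residue receives linearly interpolated backbone
positions and is flagged low-confidence.  No restraint-based refinement or
sidechain rebuilding is attempted: the construction is deterministic and
exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Structure
from .synthetic import one_to_three, three_to_one

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class RegisterShift:
    """One-position-upstream register shift over [shift_start, shift_end]."""

    chain_id: str
    shift_start: int
    shift_end: int
    direction: str = "one position upstream"

    def __post_init__(self):
        if self.shift_start > self.shift_end:
            raise ValueError(f"shift_start {self.shift_start} > shift_end {self.shift_end}")


@dataclass
class PairwiseAlignment:
    """Gapped template/target rows with an explicit column map.

    column_map: list of (template residue_number or None, target
    residue_number or None) per alignment column.
    """

    template_row: str
    target_row: str
    column_map: list

    def __post_init__(self):
        if len(self.template_row) != len(self.target_row):
            raise ValueError("alignment rows differ in length")
        if len(self.column_map) != len(self.template_row):
            raise ValueError("column_map length mismatch")

    def ungapped(self, row: str) -> str:
        return row.replace("-", "")


def build_shift_alignment(sequence: str, shift: RegisterShift,
                          numbers=None) -> PairwiseAlignment:
    """Build the gapped self-alignment implementing the register shift.

    ``sequence`` is the one-letter chain sequence; ``numbers`` its residue
    numbering (default 1..n).  The template row receives one gap
    immediately before ``shift_start`` and the target row one gap
    immediately after ``shift_end``; flanks are identity-aligned, and every
    target residue k with shift_start < k <= shift_end pairs with template
    residue k-1.
    """
    seq = str(sequence)
    if numbers is None:
        numbers = list(range(1, len(seq) + 1))
    numbers = [int(x) for x in numbers]
    if len(numbers) != len(seq):
        raise ValueError("numbering length must match sequence length")
    if shift.shift_start not in numbers or shift.shift_end not in numbers:
        raise ValueError("shift residues not present in the sequence numbering")
    si = numbers.index(shift.shift_start)
    ei = numbers.index(shift.shift_end)
    if si == 0:
        raise ValueError("shift_start at chain start: no upstream position to shift into")

    template_row = seq[:si] + "-" + seq[si:]
    target_row = seq[: ei + 1] + "-" + seq[ei + 1:]
    column_map = []
    for col in range(len(seq) + 1):
        t_num = None if col == si else numbers[col - 1] if col > si else numbers[col]
        g_num = None if col == ei + 1 else numbers[col] if col <= ei else numbers[col - 1]
        column_map.append((t_num, g_num))
    aln = PairwiseAlignment(template_row=template_row, target_row=target_row,
                            column_map=column_map)
    assert aln.ungapped(aln.template_row) == seq
    assert aln.ungapped(aln.target_row) == seq
    return aln


def _chain_backbone(template: Structure, chain_id: str):
    """residue_number -> {backbone atom name -> coordinate} for one chain."""
    out: dict[int, dict[str, np.ndarray]] = {}
    names: dict[int, str] = {}
    mask = template.chain_id == chain_id
    for i in np.nonzero(mask)[0]:
        name = str(template.name[i]).upper()
        num = int(template.residue_number[i])
        names[num] = str(template.residue_name[i])
        if name in BACKBONE_ATOMS:
            out.setdefault(num, {})[name] = template.coord[i]
    return out, names


def thread_backbone(template: Structure, alignment: PairwiseAlignment,
                    chain_id: str | None = None) -> Structure:
    """Thread target backbone coordinates onto the template.

    Each paired target residue receives its template partner's N/CA/C/O
    coordinates exactly; gap-bridged target residues get linearly
    interpolated backbone positions between the flanking threaded residues
    and are flagged in ``metadata['interpolated_residues']``.  Residues
    outside the alignment receive no coordinates.
    """
    if chain_id is None:
        chain_id = str(template.chain_id[0])
    backbone, res_names = _chain_backbone(template, chain_id)

    threaded: dict[int, dict[str, np.ndarray]] = {}
    bridged: list[int] = []
    for t_num, g_num in alignment.column_map:
        if g_num is None:
            continue
        if t_num is None:
            bridged.append(g_num)
            continue
        if t_num not in backbone or any(a not in backbone[t_num] for a in BACKBONE_ATOMS):
            missing = [a for a in BACKBONE_ATOMS if a not in backbone.get(t_num, {})]
            raise ValueError(f"template residue {chain_id}:{t_num} missing "
                             f"backbone atoms {missing}")
        threaded[g_num] = {a: backbone[t_num][a].copy() for a in BACKBONE_ATOMS}

    for num in bridged:
        lo = max((k for k in threaded if k < num), default=None)
        hi = min((k for k in threaded if k > num), default=None)
        if lo is None or hi is None:
            raise ValueError(f"gap-bridged residue {num} has no flanking threaded "
                             "residues to interpolate between")
        frac = (num - lo) / (hi - lo)
        threaded[num] = {a: (1 - frac) * threaded[lo][a] + frac * threaded[hi][a]
                         for a in BACKBONE_ATOMS}

    serial, names, elements, rnames, rnums, chains, coords = [], [], [], [], [], [], []
    s = 1
    for num in sorted(threaded):
        rname = res_names.get(num, "ALA")
        for a in BACKBONE_ATOMS:
            serial.append(s); names.append(a); elements.append(a[0])
            rnames.append(rname); rnums.append(num); chains.append(chain_id)
            coords.append(threaded[num][a])
            s += 1
    return Structure(serial, names, elements, rnames, rnums, chains, coords,
                     metadata={"register_shift": True,
                               "interpolated_residues": sorted(bridged)})


def symmetrize_tetramer(model: Structure, chain_ids, shift: RegisterShift) -> Structure:
    """Apply the register shift identically to all four chains.

    Requires identical sequences over the shift region in every chain;
    refuses to re-shift an already shifted model.  Unshifted residues are
    exact backbone copies, so any C4 relationship of the input is preserved.
    """
    chain_ids = list(chain_ids)
    if len(chain_ids) != 4:
        raise ValueError(f"need exactly 4 chain ids, got {len(chain_ids)}")
    if model.metadata.get("register_shift"):
        raise ValueError("model already carries a register shift; re-shifting is refused")

    region_seqs = []
    per_chain = []
    for cid in chain_ids:
        _, names = _chain_backbone(model, cid)
        if not names:
            raise ValueError(f"chain {cid!r} not found in model")
        nums = sorted(names)
        seq = "".join(three_to_one(names[n]) for n in nums)
        per_chain.append((cid, seq, nums))
        region = "".join(three_to_one(names[n]) for n in nums
                         if shift.shift_start <= n <= shift.shift_end)
        region_seqs.append(region)
    if len(set(region_seqs)) != 1:
        raise ValueError("chains disagree in sequence over the shift region")

    parts = []
    interpolated = []
    for cid, seq, nums in per_chain:
        aln = build_shift_alignment(seq, RegisterShift(cid, shift.shift_start,
                                                       shift.shift_end), numbers=nums)
        threaded = thread_backbone(model, aln, chain_id=cid)
        interpolated += [(cid, n) for n in threaded.metadata["interpolated_residues"]]
        parts.append(threaded)

    serial = np.arange(1, sum(len(p) for p in parts) + 1)
    cat = lambda attr: np.concatenate([getattr(p, attr) for p in parts])
    return Structure(serial, cat("name"), cat("element"), cat("residue_name"),
                     cat("residue_number"), cat("chain_id"),
                     np.concatenate([p.coord for p in parts], axis=0),
                     metadata={"register_shift": True,
                               "shift": (shift.shift_start, shift.shift_end),
                               "interpolated_residues": interpolated})
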