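"""Detect backbone hydrogen bonds and classify helical register.

Builds ideal alpha- and pi-helices from canonical dihedrals and runs the
DSSP-energy hydrogen-bond detector.  An alpha-helix hydrogen-bonds at
i+4->i, a pi-helix at i+5->i; the offset histogram is the fingerprint that
separates the two registers in channel pore helices.
"""

from collections import Counter

import poregate as pg

for kind in ("alpha", "pi"):
    helix = pg.make_ideal_helix(15, kind)
    annotation, bonds = pg.annotate_helix(helix)
    offsets = Counter(b.offset for b in bonds)
    labels = Counter(annotation.labels.values())
    print(f"{kind:9s} helix: {len(bonds)} H-bonds, offsets {dict(offsets)}, "
          f"labels {dict(labels)}")

# A lone i+5 bond inserted into an alpha-helical pattern marks a defect:
# the signature of the kink seen when a pore helix transitions alpha -> pi.
from poregate.helix import BackboneHBond

segment = [("A", i) for i in range(200, 215)]
bonds = [BackboneHBond(("A", i), ("A", i - 4), 4, -2.0)
         for i in range(204, 215) if i not in range(210, 215)]
bonds.append(BackboneHBond(("A", 212), ("A", 207), 5, -2.0))
annotation = pg.classify_helix_pattern(bonds, segment)
print("transition labels:",
      {r[1]: lab for r, lab in annotation.labels.items() if lab != "alpha"})
print("defect segments:", annotation.defect_segments)
# Residues 207/212 label pi (they share the i+5 bond); the residues that
# lost their i+4 partners without replacement form the defect runs.
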