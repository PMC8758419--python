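"""Drug ionization, membrane partitioning, pose clustering, ion interactions.

The open-pore blockers lidocaine (pKa 7.56) and flecainide (pKa 9.3) are
weak bases: their charged fraction at physiological pH follows
Henderson-Hasselbalch and determines which species blocks the pore.
"""

import numpy as np

import poregate as pg

for name, pka in (("lidocaine", 7.56), ("flecainide", 9.3)):
    ion = pg.ionization_fraction(pka, pH := 7.4, "base")
    print(f"{name}: pKa {pka} -> {ion.charged_percent:.0f}% charged / "
          f"{100 * ion.neutral_fraction:.0f}% neutral at pH {pH}")

dg = pg.logp_to_dg(1.49, 298.0)
print(f"charged lidocaine logP 1.49 -> membrane partition dG = {dg:.1f} kJ/mol")

# Cluster a planted two-site pose ensemble with the 0.1 nm RMS cutoff
ens = pg.make_pose_ensemble([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
                            members_per_cluster=[6, 4], spread_nm=0.02, seed=7)
clusters = pg.cluster_poses(ens.frames, cutoff=0.1)
print("cluster sizes:", [len(c) for c in clusters.clusters],
      "| representatives (medoids):", clusters.representatives)

# Short-range Coulomb + LJ energy of a sodium ion 3 A from a -1e site
coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
top = pg.Structure([1, 2], ["OD1", "NA"], ["O", "NA"], ["ASN", "NA"],
                   [212, 1], ["A", "I"], coords)
traj = pg.Trajectory(topology=top, frames=coords[None])
table = pg.residue_ion_interaction_energy(
    traj, "chain A", "chain I",
    charges=[-1.0, 1.0], sigma=[2.9, 2.4], epsilon=[0.4, 0.2], cutoff=12.0)
mean, sd = table.energies[("A", 212)]
print(f"Asn212 - Na+ interaction: {mean:.1f} +- {sd:.1f} kJ/mol "
      f"(12 A short-range cutoff)")
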