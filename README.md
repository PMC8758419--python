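# poregate

Structural analysis of **hydrophobic gating** in ion-channel pores — tools to
decide whether a pore model is open (hydrated, conductive) or non-conductive
(dewetted), and to build and test π-helix open-state models.

Voltage-gated channel pores can close without steric occlusion: a ring of
hydrophobic sidechains at the activation gate dewets, and the resulting
vacuum/vapor plug makes ion passage energetically prohibitive even through a
geometrically "open" radius. Deciding conductivity therefore needs more than
a radius profile: it needs the water density along the pore, the hydration
free energy derived from it, the hydrogen-bond register of the pore-lining
helices (an α→π transition rotates gate sidechains by ~50°), and the
orientation of the conserved pore-facing asparagine. `poregate` implements
that analysis set for pseudo-tetrameric channel pores, plus the
post-processing of ion/drug permeation free-energy profiles and the
construction of register-shifted (π-helix) models.

Intended users: computational structural biologists analyzing channel
models and MD output (multi-model PDB natively; binary trajectories via any
converter that writes PDB frames).

## The core quantities

- **Hydration free energy** (Boltzmann inversion of the axial water number
  density, the CHAP-style estimator):

      ΔG(z) = −kT · ln( n(z) / n_bulk )

  A dewetted gate appears as a barrier of a few kcal/mol; an open pore is
  effectively flat.

- **Helical register** from backbone hydrogen bonds, scored with the DSSP
  electrostatic energy E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332
  kcal/mol (bond if E < −0.5): offset i+4 → α, i+5 → π, an expected-but-
  absent i+4 bond → helical defect.

- **Pore radius profile** (slab-minimum distance to the fitted pore axis,
  minus vdW radii) with mean, SD and extreme values over frames.

- **Residue orientation**: the (x, y) projection of Cα→Cγ in a pore-centered
  frame where +x points at the pore axis — pore-facing sidechains have x > 0.

- **PMF post-processing**: window averaging with SD error bars, reference
  shift to the bilayer center, barrier extraction (kJ/mol and kcal/mol).

- **Ligand analytics**: Henderson–Hasselbalch charged fractions,
  ΔG = −ln(10)·R·T·logP partitioning, single-linkage RMS-cutoff pose
  clustering with medoid representatives, and short-range Coulomb +
  Lennard-Jones residue–ion interaction energies.

A first-class synthetic-data module generates every fixture needed to test
the pipeline end to end — ideal α/π/3₁₀ helices, C4 toy channel bundles with
a tunable gate, water fields Boltzmann-distributed against an imposed ΔG*(z),
noisy PMF windows, and planted ligand-pose clusters — so nothing requires
downloads or MD runs.

## Worked example

```python
import numpy as np
import poregate as pg

# water field against an imposed 3 kcal/mol gate barrier at z = -10 A
spec = pg.SolventFieldSpec(dg_profile=[(12.55, -10.0, 4.0)],
                           n_frames=2000, seed=2021)
traj = pg.sample_waters(spec)
axis = pg.PoreAxis(origin=np.zeros(3), direction=np.array([0., 0., 1.]))
dens = pg.water_density_profile(traj, axis, 8.0, 1.0, z_range=spec.z_range)
dg = pg.hydration_free_energy(dens, 300.0)
print(round(dens.bulk_density, 1), round(dg.columns["dg"].max(), 2))
```

prints `33.5 12.69`: the estimated bulk water density (33.5 nm⁻³ against the
planted 33.4) and the recovered gate barrier (12.69 kJ/mol against the
imposed 12.55) — the density→ΔG estimator inverts the generator to within
sampling error. `examples/` contains one narrative script per capability
(helix annotation, pore geometry, hydration, PMF post-processing,
register-shift modeling, ligand analytics); each prints the numbers it
computes and says what they mean.

## Command line

A thin CLI wraps the library:

```bash
poregate ligand --pka 9.3 --ph 7.4            # flecainide: 99% charged
poregate hydration --traj traj.pdb --gate=-14:-6 --out hyd
poregate annotate-helix --pdb model.pdb --chain A --out labels.tsv
poregate pi-shift --pdb model.pdb --start 207 --end 234 \
    --out-alignment shift.fasta --out-model pi_model.pdb
```

Exit codes: 0 ok, 1 runtime error, 2 usage. Every output file carries a
`# key = value` metadata header sufficient to re-run the command.

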