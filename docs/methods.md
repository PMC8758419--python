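# Methods

This note documents the models, estimators and design choices behind
`poregate`, in the spirit of the methods documentation of analysis packages
for molecular simulation.

## Units and conventions

Coordinates are Angstrom throughout; densities are nm⁻³; energies are stored
in kJ/mol with kcal/mol available as a conversion (1 kcal = 4.184 kJ; kT at
300 K = 2.4943 kJ/mol). Residue numbering is taken verbatim from the input —
nothing is renumbered. The pore axis z increases toward the extracellular
side; the activation-gate region of a bacterial-channel pore domain then
falls near z ≈ −10 Å when z = 0 sits at the pore-domain centroid (the "−1 nm"
convention used in hydration figures). Multi-model PDB is the native
trajectory format; binary formats are expected to be converted externally.

## Backbone hydrogen bonds and helical register

The default bond criterion is the DSSP electrostatic model,
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, accepted when
E < −0.5 kcal/mol; a geometric fallback (N···O ≤ 3.5 Å, D–H···A ≥ 120°) is
selectable. Each N–H donor keeps at most its best-scoring acceptor; ties
break toward the smaller sequence offset, making the assignment
deterministic. Amide hydrogens absent from the input (X-ray structures) are
rebuilt along the direction opposing the bisector of the N–C(prev) and N–Cα
bonds at N–H = 1.01 Å; the first residue of a chain and prolines are never
donors.

Classification: a residue participating in any i+5 bond is labelled `pi`
(the i+5 bond is the π signature even when neighboring i+4 bonds survive);
otherwise i+4 → `alpha`, i+3 → `three_ten`. A residue that could form an
i+4 bond within the analyzed segment but participates in no helical bond is
a `defect`; maximal defect runs are reported as defect segments — the
boundary pattern of an α→π transition. Residues whose partners simply lie
outside the segment are `none`.

Ideal helices are generated from repeating canonical dihedrals by
internal-coordinate chain extension (Engh–Huber-like bond lengths/angles,
ω = 180°): α (−57°, −47°), 3₁₀ (−49°, −26°), π (−55°, −70°). The π values
are the ideal repeating conformation that actually hydrogen-bonds at i+5;
the frequently quoted (−76°, −41°) are averages over distorted observed
π-helices and, repeated exactly, produce i+4 bonding — they are therefore
not used as the generator default.

## Pore geometry

The pore axis of a pseudo-four-fold bundle is the principal axis of the
pooled subunit selections, origin at their centroid. The sign is chosen so
the axis runs from the low-residue-number halves toward the high ones
(N→C), which is rotation-equivariant and points extracellular for channels
built N-in/C-out. A bundle whose largest covariance eigenvalue is not at
least 1.5× the second is rejected as degenerate.

The radius profile uses the slab-minimum algorithm: per frame and axial bin,
radius = min over atoms in the slab of (distance to axis − vdW radius),
floored at 0. This straight-axis approximation suits near-straight,
symmetric channel pores and is exactly reproducible, unlike off-axis sphere
maximization (HOLE-style); it slightly underestimates the radius where the
true pore center wanders off-axis. vdW radii come from a fixed element
table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, default 1.70). Empty slabs
are reported at a probe cap (default 10 Å) and flagged rather than omitted.

The orientation metric builds a per-residue frame: origin at Cα, x̂ from Cα
toward the projection of that same Cα onto the axis (so x > 0 means
pore-facing), ẑ along the axis, ŷ = ẑ × x̂; the reported point is the (x, y)
projection of Cα→Cγ. Using the residue's own axial projection as "pore
center" is the closest literal reading of a pore-centered frame and makes
the metric invariant under translation along the axis; one point is emitted
per chain, aggregation across subunits is the caller's choice.

## Water density and hydration free energy

Water oxygens (residue names HOH/SOL/TIP3/TIP4/WAT) within a cylinder
(default radius 8 Å — wide enough to cover the pore without collecting
membrane-level water) are binned along the axis; density = count/(π r² Δz),
mean and SD over frames. Bulk density defaults to the mean over the two
outermost 5 Å z-bands, the region beyond the protein extent in a solvated
system; it can be overridden (33.4 nm⁻³ is ambient-water-like).

Hydration free energy is the Boltzmann inversion ΔG(z) = −kT ln(n(z)/n_bulk).
Zero-density bins receive a finite cap (default +25 kJ/mol) and an explicit
flag instead of +∞ — published profiles truncate dewetted gates similarly,
and a cap keeps downstream arithmetic finite; the cap is a parameter, not a
physical estimate. The error bar is first-order propagation, kT·σ_n/n̄,
with σ_n the over-frames SD — the convention of reporting frame-to-frame
spread, not the standard error of the mean.

Wetting classification counts gate-window waters per frame; a frame is wet
iff the count reaches `threshold_fraction` (default 0.1) of what a
bulk-density-filled gate cylinder would hold. The threshold is deliberately
coarse: it separates vapor plugs (near-zero counts) from hydrated gates.

## Synthetic water fields

`sample_waters` draws, per frame and bin, a Poisson count with mean
n_bulk·exp(−ΔG*(z)/kT)·V_bin and scatters the waters uniformly in the bin
cylinder — the exact statistical inverse of the density→ΔG estimator, with
ΔG*(z) a sum of Gaussians. Because frames then differ in count while a
trajectory requires congruent frames, frames are padded to the maximum
count with inactive waters parked far outside the sampled z-range (z_max +
100 Å, xy = 500 Å); parked waters can never enter an analysis bin. What the
generator emulates is only the equilibrium axial statistics of pore water:
it has no water–water correlations, no protein, no dynamics or residence
times, and frames are i.i.d. Passing the inverse-consistency tests
therefore validates the estimator's statistics, not any force-field or
sampling question about real trajectories. At the default test scale
(2000 frames, r = 8 Å, 1 Å bins, 3 kcal/mol barrier) the expected count in
the peak bin is ≈ 90, giving a 1-SE inversion error of ≈ 0.27 kJ/mol —
the origin of the 0.3 kJ/mol recovery tolerance.

## PMF post-processing

`average_pmf` implements the windowed-average protocol for adaptive-bias
output: profiles extracted at fixed intervals from the tail of a run are
averaged per bin and the per-bin population SD becomes the error bar. The
z-grids must match exactly; no interpolation is attempted. `shift_reference`
subtracts the value at an anchor bin (bulk or bilayer center) and is
idempotent. `barrier_height` reports max(region) minus the minimum of a
reference window (default: the whole profile); ties at the maximum report
the smaller z. Barrier height is invariant under reference shifts.

## Interaction energies and pose clustering

Residue–ion energies are the sum over pairs within a 12 Å cutoff of
f·q_iq_j/r + 4ε_ij((σ_ij/r)¹² − (σ_ij/r)⁶), f = 138.935 kJ·nm/(mol·e²),
Lorentz–Berthelot combination, with per-atom parameters supplied by the
caller — no force-field inference is performed. Means and SDs are over
frames. The plain cutoff (no shifting/switching or mesh electrostatics)
matches the "short-range" convention of simulation energy groups.

Pose clustering is single-linkage: frames are linked when their RMS distance
(computed in nm, by default without re-superposition, since the pose
position in the channel frame is the variable of interest) is strictly below
the cutoff (default 0.1 nm); clusters are connected components sorted by
size then smallest member. The representative is the medoid — the member
minimizing mean RMS distance to its cluster — a concrete reading of "the
center of the most populated cluster".

Ionization uses Henderson–Hasselbalch: charged fraction 1/(1+10^(pH−pKa))
for a base, mirrored for an acid. Note that a pKa of 7.56 gives 59% charged
at pH 7.4 (not the 70% sometimes quoted for lidocaine at "physiological pH",
which corresponds to a lower pH); the operation takes pH explicitly and
reports the arithmetic. logP converts as ΔG = −ln(10)·R·T·logP.

## Register-shift model building

The π-model recipe is a gapped self-alignment: one gap in the template row
immediately before the first shifted residue, one in the target row
immediately after the last, so every target residue k in the region pairs
with template residue k−1 (one position upstream). Threading copies the
template partner's N/Cα/C/O exactly; the single gap-bridged residue gets
linearly interpolated backbone positions, flagged low-confidence in the
output metadata. There is no restraint-based refinement, loop modeling or
sidechain rebuilding: the deterministic construction keeps every coordinate
exactly testable, at the cost of locally strained geometry around the
bridged residue. `symmetrize_tetramer` applies the shift identically to all
four chains (requiring identical region sequences), preserves any C4
relationship of the input, and refuses to re-shift an already shifted model.

## Degenerate inputs and numerical choices

Structures with non-finite coordinates, duplicate (chain, residue, atom)
keys, or incongruent trajectory frames are rejected at construction. Profile
tables require strictly increasing z and refuse to write non-uniform grids
without an explicit override. Selections use a small grammar (`chain`,
`resid` ranges/lists, `name`, `resname`, joined by `and`). All generators
are pure functions of their spec and seed (numpy `default_rng`), giving
bit-identical outputs for identical inputs.

## Problem sizes used in tests

The shipped tests and the acceptance script run entirely on synthetic
fixtures: 15–20-residue helices, a 328-atom toy channel, 2000-frame water
fields (~400 waters per frame), 10-window PMF ensembles over ≤ 120 bins, and
200-frame pose sets. These sizes were chosen so each statistical check has
the power its tolerance implies (see the SE analysis above) while the whole
suite completes in seconds.

## Known limitations

Straight-axis radius profiling (no spline/curved pathway); no cavity
detection off the main pore; hydration analysis uses oxygen positions only;
the wetting threshold is a coarse binary; threading does not rebuild
sidechains (the orientation metric therefore applies to experimental or
refined inputs, not raw threaded toys); MD itself, enhanced-sampling bias
estimation (the package only post-processes its profile output), and
force-field parameter assignment are out of scope.
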