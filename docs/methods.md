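# Methods

## Coarse-grained representation

Every standard amino acid is mapped to six beads: the backbone N, amide H,
Cα, C′ and carbonyl O at their atomic positions, plus one side-chain (SC)
bead at the mass-weighted centroid of the side-chain heavy atoms (standard
atomic masses; hydrogens excluded).  Glycine has five beads and proline
keeps each heavy side-chain atom as an explicit, geometry-only bead and has
no amide H.  Each residue carries exactly one *interaction centre* — the SC
bead, or Cα for glycine and proline — at which all side-chain–side-chain
and salt-bridge energies are evaluated.

X-ray inputs carry no hydrogens, so the amide H is reconstructed
deterministically: 1.0 Å from N along the direction opposite the bisector
of the N–Cα and N–C′(prev) bonds (chain-initial residues: opposite N–Cα).
Alternate locations are resolved by occupancy; insertion codes count as
sequential residues; HETATM records and waters are dropped; non-standard
residues are rejected rather than approximated.

Polypeptides with missing residues are split into segments at numbering
discontinuities, and each gap is bridged by a harmonic restraint between
the flanking C′ and N beads with the current gap length as equilibrium and
k = 100 kcal/(mol·Å²).  Throughout the package harmonic energies are
E = k (d − d₀)² *without* the ½ factor, so printed force constants apply
literally.

Both binding partners may span several chains; all chains of one partner
are treated as a single protein, and partner assignment is always explicit
(receptor/ligand chain lists), never inferred from size.

## Nonbonded energy terms

Four terms act between beads; only inter-partner pairs enter the score.

**E_SS** (side chain–side chain, interaction centres).  Parameterized per
residue-type pair by a magnitude ε_ij ≥ 0, an attractive/repulsive flag,
and an optimal distance r⁰_ij, with the well position
σ_ij = 1.0729 r⁰_ij − 0.3992.  The attractive branch is a 12-6 well with
minimum exactly −ε at σ, multiplied beyond σ by a smooth long-range damper
S(r) = 1/(1 + ((r − σ)/λ)⁶), where λ is the sixth root of the damping
function G(r⁰) = [−0.7 e^{2(r⁰−0.5)/5}(r⁰ − 0.5)]⁶.  S leaves both the
minimum position and depth untouched (S(σ) = 1, S′(σ) = 0) while limiting
the attraction at longer distances.  The repulsive branch is ε (σ/r)⁶:
non-negative, monotone, vanishing at long range.  The exact algebra of the
published attractive/repulsive branches is not available in this form;
these branches are this package's own constructions satisfying the same
contracts (minimum location and depth, long-range limiting via G, repulsive
monotonicity).

**E_VDW** (backbone-involving pairs).  A standard 12-6 form with per-role
radii and depths; combined radius = sum, combined depth = geometric mean.
Amide H beads take part only in E_HB, and proline heavy-atom beads are
geometry-only.  A pair of two interaction centres is never double-counted:
it belongs to E_SS/E_SB exclusively.

**E_HB** (backbone N–H···O=C′).  well_depth × radial × alignment, with a
radial factor that equals 1 exactly at the equilibrium H···O distance and
is clamped at short range so the term is never positive, and an alignment
factor cos²θ of the N–H···O angle that vanishes at and beyond 90°
misalignment.  Intra-chain pairs closer than five residues use a shorter
equilibrium distance; inter-partner pairs have no defined sequence
separation and always use the long one.  The four-body helix term and the
(i,i+3)/(i,i+4) enhanced side-chain pairs of the parent force field are
intra-chain constructs and are excluded: the scoring function uses
inter-partner terms only.

**E_SB** (salt bridges).  The four pairs Arg/Asp, Arg/Glu, Lys/Asp,
Lys/Glu are scored from tabulated free-energy profiles interpolated with a
monotone cubic (PCHIP): one interior minimum for the Arg pairs, two
(contact and solvent-separated) for the Lys pairs, zero beyond the grid,
clamped to the first tabulated value (a repulsive wall) below it.

**Parameters.**  All numbers live in a versioned text file with sections
`[pairs]`, `[saltbridge:*]`, `[hbond]`, `[vdw]`; a checksum of the loaded
configuration is reported alongside scores.  The shipped 20×20 table is a
documented stand-in: attraction magnitudes 0.8·s_i·s_j + 0.05 from a
residue "stickiness" scale s ∈ [0,1], pair distances r⁰ = R_i + R_j from
side-chain radii, like-charged pairs repulsive.  The original OPEPv5 values
are not publicly tabulated; users with access can substitute them in the
parameter file without touching code.  The default salt-bridge profiles
are Gaussian wells plus an exponential wall sampled on a 2.5–10 Å grid.
A global nonbonded cutoff (default 16 Å) truncates and shifts each radial
term to zero; pair-level unit operations are unshifted, and the cutoff can
be disabled (`cutoff = none`) for exact pairwise work.

## The softened scoring function E86

Rescoring replaces both E_SS's attractive branch and E_VDW with 8-6
Lennard-Jones curves E(r) = ε′[(σ′/r)⁸ − (σ′/r)⁶].  This family has its
minimum at r_min = σ′·√(4/3), i.e. σ′/r_min = √3/2 = 0.8660, with minimum
energy −ε′(0.75³ − 0.75⁴) = −ε′/9.4815; requiring the softened curve to
reproduce the unsoftened minimum (position σ, energy E_SS(σ)) therefore
fixes σ′ = 0.866 σ and |ε′| = 9.481 |E_SS(σ)|.  The package uses the exact
values √3/2 and 1/(0.75³ − 0.75⁴) internally so the matching construction
holds to numerical precision; the three-decimal constants are the rounded
forms of these.  The repulsive-only branch, E_HB and E_SB are not
modified.  The total is

E86 = E_VDW86 + E_SS86 + E_HB + E_SB,

summed over bead pairs with one bead in each partner.

## Restrained minimization

Decoys arriving from a grid search carry bead clashes after
coarse-graining and are relaxed with at most 140 limited-memory BFGS
iterations in full Cartesian space (both partners mobile).  140 steps is a
protocol default, not a convergence criterion.  The parent force field's
bonded terms are not published; they are replaced by a *self-consistent
harmonic scaffold* whose equilibria are read off the input conformation:
intra-residue bonds (N–H, N–Cα, Cα–C′, C′=O), the peptide C′–N bond within
contiguous segments, 1-3 distances standing in for the backbone angles,
1-4 Cα(i)–Cα(i+2) distances standing in for the backbone dihedral
stiffness, side-chain tethers, and every gap restraint at k = 100.
Defaults: bonds 100, angles 40, tethers and 1-4 terms 20 kcal/(mol·Å²).
The restraint energy of the input pose is exactly zero, so only the
unsoftened nonbonded terms (E_VDW, E_SS, E_SB — the orientational E_HB
term is scoring-only and kept out of the relaxation gradient) drive the
relaxation.  Without the 1-4 terms the harmonic scaffold lets toy chains
bend slowly under interface attraction and near-native poses drift ~0.5–1 Å
in interface RMSD over 140 steps; with them the drift is ~0.15–0.2 Å,
consistent with the intent that minimization relieves clashes without
moving the pose.  Gradients are analytic and checked against central
differences; the interaction list is fixed from the input pose for the
duration of one minimization; runs are bit-deterministic.

## Evaluation

The interface of the reference complex is the set of residues with any
bead strictly within 10 Å of any bead of the other partner; decoys inherit
this selection.  IRMSD is the RMSD over interface Cα beads after optimal
least-squares superposition with an enforced proper rotation
(det = +1), fitted on the interface Cα set itself.  A hit has IRMSD
strictly below 4 Å; accuracy tiers are high ≤ 1 Å, medium ≤ 2 Å,
acceptable < 4 Å (boundaries inclusive, inclusive, strict).  Decoys are
ranked by ascending score with ties broken by ascending decoy id (ranking
feeds training, so the tie-break must be reproducible).  Per-class mean
best-hit ranks support two no-hit policies: substitute the rank cap
(2000), or exclude no-hit targets; published per-class averages for the
test benchmark are consistent with the exclusion policy even where the
accompanying footnote describes substitution, so both are provided and the
discrepancy is surfaced here rather than resolved.  Means are rounded
half-up to one decimal, the precision of the published tables.

## Contact-potential training

After scoring, each decoy of a target is labelled by crossing hit status
(IRMSD < 4 Å) with ranking status (rank ≤ 20): TP, FN, FP, TN.  All TPs
are kept (at most 20 by construction); the best-ranked 20 − N FNs and FPs
are kept (N = number of TPs); all TNs are kept; targets with ≥ 20 hits in
total keep no FNs or FPs.  A residue-residue contact exists when any two
beads of an inter-partner residue pair are closer than 8 Å (strict); per
label, the per-decoy-mean 20×20 residue-type contact maps are averaged
over all targets of one complex class.

A type pair is *strengthened* when its frequency is strictly higher in
both near-native maps (TP, FN) than in both misdocked maps (FP, TN), and
*weakened* in the strictly reversed case; ties deselect (which keeps the
k = 0 fixed point exact).  Selected pairs move by

E_new(i,j) = E_old(i,j) − k ln(FN_ij / FP_ij),  k = 0.2,

applied to the E_SS86 well depth (σ′ untouched; the whole curve scales so
the minimum energy equals the trained value) or to the salt-bridge profile
depth for the four salt-bridge pairs.  Zero frequencies are guarded by an
additive pseudocount of 1/(total kept decoys); a class with zero kept
decoys contributes no inequality, and the update is skipped entirely when
FN or FP is empty, since the ratio then carries no information (this also
freezes training once every hit of every target ranks in the top 20).
Decoy geometries are fixed between iterations — re-scoring and re-ranking
only, no re-minimization — and the default 30 iterations are validated by
seeded k-fold cross-validation of the log-rank quality Σ ln(best-hit
rank), whose rise past its minimum flags overfitting.  Because the
SS86/SB part of the score is linear in the per-type-pair well depths, each
target caches per-decoy 20×20 energy features once, and one training
iteration is a matrix contraction plus a re-ranking.

The delta matrix reported after training is trained − original, so
negative entries mean the interaction became more attractive.

## Synthetic benchmarks: what they emulate and what they do not

`make_toy_complex` builds two idealized chains (extended, helical or
compact-random φ/ψ templates; pseudo side chains as compact atom clusters
sized per residue type) and rigidly poses the ligand so designated
interface side-chain pairs sit within 4–7 Å while no inter-partner heavy
atoms come closer than 2.5 Å, preferring the most tightly packed feasible
pose.  `generate_rigid_decoys` emulates the retained-decoy regime of an
FFT search at desk scale: the receptor is fixed; near-native decoys are
small rigid perturbations (defaults 6° / 1.2 Å, the angular and
translational bin widths of the emulated grid search) accepted below the
4 Å hit threshold, additionally filtered by a type-aware soft core
(interaction centres ≥ 0.75 (R_i + R_j)) that stands in for the clash
relief a full relaxation stage would provide; misdocked decoys are
uniformly oriented and translated along a random direction until the
minimum inter-partner bead distance falls in a 3–6 Å graze window, and are
re-sampled if they accidentally qualify as hits.  True IRMSDs are computed
with the package's own evaluator and stored.

`make_recovery_benchmark` is the packaged study condition for trainer
validation: 20 targets × 500 decoys, near-native fraction 0.03 (15 hits
per target — below 20, so the FN/FP machinery engages), one His/His
interface contact enriched at least 3× among near-native poses.  Its design
isolates the planted signal deliberately: the background alternates
alanine and serine only, whose near-identical side-chain heights make the
contact composition of a grazing pose statistically close to that of the
native face (a glycine background, with no side-chain bead, registers
contacts only in backbone-close poses and systematically biases the
frequency maps), and the planted type is histidine because its default
interaction magnitude sits inside the background range, so the initial
ranking of misdocked decoys is blind to its presence.  Scattered His
residues along both chains give the planted pair a non-zero baseline
frequency among misdocked poses, making the enrichment ratio well-defined.

These toys share the decoy-regime *statistics* of a real benchmark —
minority hits, surface-grazing misdocks, contact-composition signals — but
not the physics of real interfaces: no packing refinement, no side-chain
rotamers, idealized secondary structure, stand-in parameters.  Passing the
recovery test demonstrates that the training machinery finds and amplifies
a genuine contact signal without disturbing uninformative pairs; it does
not certify ranking performance on crystallographic complexes.

## Numerical choices and limitations

* Exact soft constants √3/2 and 1/(0.75³−0.75⁴) rather than the rounded
  0.866/9.481 (the rounded values displace the matched minimum by ~10⁻⁴
  relative).
* Superposition via a proper-rotation Kabsch solve; degenerate interfaces
  (< 3 Cα) are an error, never silently padded.
* The L-BFGS history size is 10 with tight function/gradient tolerances so
  the iteration cap, not the tolerance, ends a 140-step run on unrelaxed
  decoys.
* The trained potential scales whole pair curves; a weakened attractive
  well whose depth crosses zero would flip the curve sign — iteration
  counts and k keep shifts far from that regime, and the delta matrix makes
  any such excursion visible.
* The published per-target benchmark rank table ships with the package for
  the mean-rank arithmetic check; no structural data are bundled.
* The 9999-bead limit of the original fixed-width parameter files is not
  reproduced; this implementation has no such constraint.
* f_nat and ligand-RMSD quality criteria are out of scope (IRMSD-only
  evaluation), as are desolvation/electrostatic grid terms, secondary-
  structure analysis, Monte Carlo refinement and side-chain repacking.
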