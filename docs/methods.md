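# Methods

This note records the models and conventions the package implements, the
defaults and why they were chosen, the design decisions that were genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and numbering conventions

All coordinates are stored in Å; XTC files (nm) are converted on read and
write. Residue numbering follows the input PDB numbering with no
renumbering, so literature labels such as G182 or F214 address residues
directly. Distance-based statistics use heavy atoms only (element ≠ H):
hydrogen placement is force-field dependent, while the contact analyses are
defined on residue proximity. Multi-model PDB files load the first model
with a warning.

## Ligand-residue occupancy

Occupancy of a residue is the fraction of frames in which the
ligand-residue distance is ≤ the cutoff (default 7.0 Å, boundary
inclusive). The source definition — "ligand within 7 Å of the given
residue" — does not fix the distance convention, so the default is the
minimum heavy-atom/heavy-atom distance (the common contact convention and
the conservative choice); a ligand-centroid mode is available in the
config and the mode used is recorded per run. Frames are weighted equally
with no stride resampling.

A bound-conditioned variant restricts the denominator to frames where the
ligand centroid lies within the cutoff of the binding-site centroid. Both
conventions exist because statements of the form "the ligand remained near
residue X for >94% of the time it occupied the site" imply conditioning,
while a plain per-residue occupancy table does not; when conditioning is
requested, zero bound frames is an error, never a silent NaN.

**Escape detection.** The first escape is the first frame at which the
ligand centroid exceeds the cutoff from the site centroid and remains
outside for at least a persistence window (default 10 consecutive stored
frames). The window suppresses single-frame recrossings, for which no
published criterion exists; 10 frames was chosen as comfortably longer
than any single-frame noise event while short against the residence times
of interest. A trajectory with no qualifying excursion returns a distinct
"no escape" sentinel (falsy, with `frame=None`), never frame 0.

## Pi-stacking

Two rings are stacked in a frame iff their centroid separation is
≤ 4.4 Å (inclusive, "or less") and the angle between their ring planes is
< 30° (exclusive, "less than"). Ring atoms for Phe/Tyr are
CG/CD1/CD2/CE1/CE2/CZ. The plane normal is the least-squares fit over all
ring atoms (smallest right singular vector of the centered coordinates)
rather than a single cross product, which is robust to thermal pucker;
normals are sign-ambiguous, so the interplanar angle is folded to
[0°, 90°]. Distances are snapped to 1e-9 Å and angles to 1e-6° before the
threshold comparison so that geometries constructed exactly on a boundary
receive the verdict the boundary semantics dictate; both snaps are far
below thermal motion.

The rolling stacking fraction uses a left-aligned window (default 10
stored snapshots, indexed by window start) computed from integer window
counts, so fractions like 10/10 are exact. The overall fraction is the
plain mean of the per-frame booleans.

## Superposition, per-residue RMSD, χ1

Superposition solves the least-squares rigid transform over the alignment
selection only (Kabsch/SVD with determinant correction) and applies it to
all atoms. The default alignment selection is all heavy atoms of the
selectivity-filter residues 143/145/147 — the source does not state
Cα-only vs all-atom for the alignment set, and using all heavy atoms is
the better-conditioned choice on a three-residue anchor. Collinear or
< 3-atom alignment sets are rejected.

Per-residue RMSD is computed against a configurable reference frame after
superposition, in all-atom or Cα-only mode; the Cα profile equals the
all-atom profile restricted to Cα by construction. Both the per-frame
series and the time average are retained; the time average is the default
summary (with a final-frame option), since whether published per-residue
profiles are time-averaged or final-frame is not always stated.

χ1 is the signed N–Cα–Cβ–γ torsion (IUPAC convention, degrees in
(−180, 180]); the γ atom is table-driven per residue type (CG for
Phe/Tyr/Leu/…, CG1 for Ile/Val, OG1/OG/SG for Thr/Ser/Cys). Glycine and
alanine are rejected by name. Rotamer residence uses half-open thirds of
the dihedral circle centered at −60/180/+60 (gauche−/trans/gauche+); the
trans bin wraps through ±180° so angles near the seam fall in one bin.

## Flat-well restraint

The restraint potential is zero for r ≤ R and k·(r−R)² beyond
(continuous and C¹ at the wall). The wall functional form and stiffness
behind the published trajectories are not stated; only the flat-region
behavior and the entropic cost are reproducible, so k is a plain config
parameter (default 10 kcal mol⁻¹ Å⁻²) with no claim of fidelity, and the
half-harmonic is the standard engine form. The restraint coordinate is the
ligand center-of-geometry distance from the well center.

The standard-state cost of confining the ligand to the sphere is
ΔG = −R_gas·T·ln(V*/V°), V* = (4/3)πR³, V° = 10²⁷/N_A ≈ 1660.54 Å³
(volume per molecule at 1 M), R_gas = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, default
T = 303.15 K (the simulation thermostat temperature). ΔG decreases
monotonically with R and crosses zero at R ≈ 7.34 Å where V* = V°. For
R = 7 Å at 303.15 K, ΔG ≈ 0.087 ≈ 0.09 kcal/mol. Wall-contact statistics
report (n_outside, n_total, percentage) with the percentage exactly
100·n_outside/n_total.

## Density grids

The grid records, per voxel, the fraction of frames in which the ligand
visited the voxel — its centroid (exactly one voxel per frame, so voxel
fractions sum to 1) or any heavy atom (a voxel counts at most once per
frame). Default mode is heavy-atoms, which matches the volumetric
appearance of published occupancy isosurfaces; centroid mode provides
exact counts for testing. Default spacing 1.0 Å; the published grid
spacing and atom convention are unstated, so both are logged config
values. The origin is snapped down to spacing multiples of the ligand
bounding box minus a one-voxel margin, making grids reproducible for a
given alignment and spacing. Frames must be pre-aligned; the accumulator
warns if not flagged as aligned. Isolevel sets at decreasing levels are
nested by construction. Output is OpenDX (z-fastest) plus a CSV voxel dump.

## Electrophysiology

Fold effect is the ratio of the 0 mV current after vs before drug; Q10 is
I(30 °C)/I(20 °C), already a 10-degree span. Time courses normalize to the
first sample, and the effect size is the normalized value at the final
time point. Currents at 0 mV can be interpolated from −150..+50 mV ramp
records.

Activation dose-response uses the standard Hill form
I = I_min + (I_max−I_min)·cᴴ/(EC50ᴴ+cᴴ) with EC50 > 0 and H ∈ (0, 10]
(the published activation functional form is not printed; this is the
field default, and the H bound makes the fitted curve monotone).

The external-pH inhibition equation is implemented exactly as printed in
its source, with the *ratio* midpoint/pH in the exponent:
I = I_min + (I_max−I_min)/(1 + 10^((pH_mid/pH)·H)). Two consequences of
that form are worth recording: the exponent depends on the parameters only
through the product pH_mid·H, so midpoint and Hill slope are not jointly
identifiable (fits report both, but only their product and the fitted
curve are meaningful); and because the exponent never changes sign, the
form cannot reach I_max at high pH. The conventional difference form
(pH_mid − pH)·H — fully identifiable, midpoint at the half-effect — is
available via `form="difference"`, and every fit records which form it
used. Published midpoints (e.g. pH ≈ 7.9 for wild-type TREK1) are treated
as format illustrations through the difference form.

Fitting uses trust-region reflective least squares (scipy, ftol/xtol/gtol
1e-12) from a deterministic grid of initializations (quantiles of the x
values for the midpoint; several H magnitudes for the ratio form, whose
surface has distant local minima), keeping the lowest-cost converged
solution. Parameter standard errors come from the Gauss–Newton
approximation, cov = (JᵀJ)⁻¹·RSS/dof, via pseudo-inverse so that singular
directions (the ratio form's midpoint/H trade-off) yield large, honest
errors rather than a crash. Non-convergence is flagged and parameters are
withheld.

## Sequence conservation

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
PairwiseAligner, scored with BLOSUM62, gap open 10, gap extend 0.5 in
EMBOSS semantics (a gap of length L costs open + L·extend), end gaps free
— needle-style defaults, since the alignment tool and parameters behind
published identity figures are usually unstated; all parameters are logged
per run and a sweep over gap open {8, 10, 12} × extend {0.5, 1.0} is
provided for sensitivity analysis. Percent identity counts identical
columns and percent similarity counts positive-substitution-score columns,
both over the full alignment length including gap columns by default (a
shorter-sequence denominator is configurable). Site mapping pairs a named
reference residue (label checked against the sequence, with an optional
numbering offset) with the residue in the same alignment column of the
second sequence, reporting deletions as an explicit gap token.

## Synthetic data: what it emulates and what it does not

The generator builds chemically plausible toy geometry — standard backbone
and side-chain atom names, Phe rings as exact 1.39 Å hexagons, χ1 torsions
constructed to target via internal coordinates (NeRF), a small rigid
three-atom ligand — so that selections, dihedrals, ring fits, and
occupancy run unmodified on it. There is no force field and no dynamics:
poses are placed, not simulated.

Contact walks realize per-residue contact draws as one categorical draw
per frame (at most one residue contacted per frame), because a single
ligand cannot simultaneously contact residues spaced far apart; planted
probabilities must sum to ≤ 1 and geometric conflicts are rejected with
the offending residues named. Contact poses are placed inside the cutoff
shell with a 0.3 Å margin (and non-contact poses far outside it), so
verdicts are robust to the threshold. Stacked poses use 3.5 Å/0° and
unstacked poses 6.0 Å/60°, both ≥ 0.2 Å/5° from the thresholds. Each
generator takes a mandatory seed (single `numpy` Generator stream, no
wall-clock seeding) and emits its ground truth as JSON beside the data.

Passing the synthetic battery demonstrates that the *operations* are
correct — count-exact occupancy, boundary-exact stacking verdicts,
superposition to numerical precision, unbiased fit recovery — under
conditions where the answer is known. It does not demonstrate anything
about force-field accuracy, sampling convergence, or biological binding
behavior, and published trajectory-scale numbers (per-residue occupancy
tables, stacking percentages of specific simulations, escape times)
cannot be regenerated without the original trajectories, which are not
deposited.

## Problem sizes

The default benchmark sizes are chosen as the smallest that exercise each
property convincingly: 5-residue toy systems (25 Å spacing for contact
walks, so cutoff shells cannot overlap), 100–1000-frame trajectories
(1000 frames puts three binomial standard errors at ±4.6% for a planted
p = 0.6), 1000 random ring placements for the stacking oracle, and a
200-repetition Monte Carlo at 10% noise, 6 doses × 6 replicates for EC50
recovery (median bias resolvable well below the 5% tolerance).

## Known limitations

- No periodic-boundary handling: trajectories are assumed imaged/whole.
- The selection language covers the expressions the analyses need, not a
  general grammar.
- The pH ratio-form identifiability issue above is inherent to that
  parameterization, not a fitting defect.
- Density grids assume cubic voxels and pre-aligned frames.
- Pairwise alignment only; no MSA or structure-based alignment.
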