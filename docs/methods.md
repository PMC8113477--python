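# Methods

`icepept` reimplements, as a tested library, the computational analyses used
to characterize a 14-residue cyclic ice-binding peptide: how one decides,
from a molecular trajectory, that a dissolved molecule has bound a growing
ice front and slowed it; how one reads a disulfide bridge off cysteine Cβ
chemical shifts; how one selects a representative conformer from a
chemical-shift-guided ensemble; and how ice-recrystallization-inhibition
(IRI) activity is quantified from grain images.  Because no trajectories,
structures or micrographs from the original study are publicly deposited,
every analysis here runs on synthetic systems whose ground truth is known by
construction; passing tests therefore demonstrate that the *analyses*
recover planted truth, not that the original simulations are reproduced.

## The peptide scaffold

The scaffold is a cyclic 14-mer with cysteines at positions 2, 3, 7, 13
(bridge between 3 and 13 in the oxidized form), threonines at 4, 10, 14 and
aspartate at 8.  The identities of the remaining six positions are not
recoverable from public text, so they are filled with glycine and flagged
as `placeholder_positions`; any analysis touching them operates on a
stand-in and says so (mutating one raises a warning).  A residue is
*essential* when some single-point variant at that position is inactive
while the parent is active at the same concentration; multi-substitution
variants never contribute, since their loss of activity cannot be assigned
to one site.  On the packaged variant table the essential set is
{8, 10, 14}.

Activity is a thresholded call on the mean-grain-area (MGA) ratio to a
buffer control: `active ⇔ mga_ratio < 0.8` at the headline concentration of
1 mg/mL by default.  The threshold is configurable because the underlying
assay is reported qualitatively; 0.8 is a conservative reading of "clearly
smaller grains than control".

## Water-phase classification

Each water oxygen gets an l=3 Steinhardt vector `q3` from the directions to
its four nearest oxygen neighbours within 3.5 Å, and each neighbour pair a
normalized correlation `c_ij ∈ [−1, 1]`.  In perfect hexagonal ice the
three off-axis bonds are *staggered* (`c = −1.00` exactly, for the ideal
lattice built here) and the c-axis bond *eclipsed* (`c = −0.11`); clathrate
cages are all-eclipsed.  The label rules (4 staggered → cubic; 3+1 → 
hexagonal; 4 eclipsed → clathrate; exactly 3 eclipsed → interfacial
clathrate; ≥2 staggered otherwise → interfacial ice; else liquid) with
thresholds staggered ≤ −0.8 and eclipsed ∈ [−0.35, 0.25] follow the CHILL+
family of algorithms; all cutoffs are configurable (`PhaseCutoffs`).
Molecules with fewer than four neighbours inside the cutoff are liquid by
fiat.  "Ice-like" means {hexagonal, cubic, interfacial ice} by default and
is likewise a config choice.

A known property of this rule family, reproduced here: orientationally
disordered (liquid) configurations park a substantial minority (~25%) of
molecules in the two clathrate labels, because the eclipsed window captures
about half of random bond orientations (the binomial `4p³(1−p)+p⁴` is ≈0.25
at `p≈0.5`).  The classifier's *false-ice* rate on disordered boxes is what
the downstream analyses depend on, and it is <1%; tests assert that
control.  Clathrate fractions should therefore always be read against a
liquid baseline, which is how the clathrate-layer analysis is framed.

## Synthetic systems

**Ice Ih.**  Oxygens sit on the ideal lonsdaleite lattice (orthorhombic
8-molecule cell `a × √3a × c`, a = 4.50 Å, c = 7.34 Å; the fractional
parameter 1/16 makes all four bonds exactly equal at c/a = √(8/3)).  Bonds
are image-aware (in a one-cell box a pair can be bonded through two distinct
periodic images).  Protons are assigned by random bond orientation repaired
by defect random walks until every oxygen owns exactly two hydrogens and
every bond carries exactly one (Bernal–Fowler rules); an independent
geometric audit (`bernal_fowler_violations`) re-derives ownership and bond
occupancy from coordinates alone.

**Liquid boxes.**  Random sequential insertion of rigid waters at
0.0334 molecules/Å³ (1 g/cm³) with a 2.6 Å minimum O–O separation and
random orientations.

**Scripted trajectories.**  These are kinematic, not physical: the point is
exact ground truth.  A slab of ice Ih (c axis in-plane, so the face exposed
along the growth axis z is a primary prismatic face) grows at a scripted
rate v until the binding time, then at `0.1·v` — the signature of a bound
growth inhibitor.  The interface is kinetically rough: each lattice site
freezes when the mean front passes its height plus a per-site offset
uniform in ±2.25 Å, applied to the initial surface too, so the measured
front advances continuously rather than in discrete crystal layers (layer
quantization otherwise biases slow-growth rate estimates by tens of
percent).  Liquid molecules overtaken by the front are snapped onto the
engulfed lattice sites in height order, and the remaining liquid column is
affinely rescaled to track the front — ice is ~7% less dense than the
liquid, and without this expansion the surplus forms a double-density band
that destroys interface classification.  Ice sites get Gaussian jitter σ/3,
liquid σ (default σ = 0.2 Å, up to 0.3 Å in recovery tests).

The probe (a methyl carbon with a C–S–S–C chain realizing a scripted
torsion schedule, plus an optional hydroxyl donor) drifts toward the front,
holds a 6.5 Å standoff, and at the binding time adsorbs with its center
2.5 Å *below* the mean front plane — the desolvated-methyl-in-a-surface-
cavity picture.  The embedding depth matters: a probe hovering above the
rough interfacial band sees too few confidently classified ice waters for
robust detection.

**Conformer ensembles.**  Pseudo-peptide models (Cα ring + Cβ for non-Gly
residues) with strictly increasing energies.  In `"dominant"` mode the
per-model deformation from the shared base geometry grows steeply
(0.05 + 0.15·i Å, capped at 2 Å), so model 0 is the planted representative:
lowest energy *and* smallest mean RMSD in any low-energy shortlist.  A
`"two_cluster"` mode plants two conformer families with within-family
spread ≪ between-family distance.

**Grain maps.**  Voronoi tessellations of uniformly random seeds; the mean
grain area is `W·H/n` exactly when border grains are kept.

## Trajectory analyses

- **Front tracking** bins the ice-like fraction along z (1 Å bins), fits a
  non-increasing isotonic profile (which leaves an already monotone profile
  unchanged and suppresses single-bin noise), and interpolates the 0.5
  crossing scanning from the ice side.  All-ice and all-liquid profiles
  return the box boundary with a diagnostic.
- **Growth rate** is the centered finite difference of the moving-average-
  smoothed front (window 5 frames by default).  A constant classification
  lag at the interface cancels in the derivative; recovery across
  v ∈ {0.1, 0.5, 1.0} Å/ns is within 5% of truth (typically <1% averaged
  over 10 seeds).
- **Solvation census** counts water oxygens within r_shell = 5.4 Å of the
  probe (first minimum of a methane–water pair correlation; the radius
  behind any particular published shell count is not stated, so absolute
  counts are not comparable across choices), split into ice-like vs liquid;
  the two always sum to the shell total.
- **Binding detection** reports the earliest time from which the shell
  holds ≥ k_ice = 4 ice-like waters continuously for ≥ 5 ns.  The defaults
  are justified by recovery: over 30 scripted trajectories (3 rates × 10
  seeds, σ = 0.3 Å) detection lands within ±2 frame intervals of the
  scripted binding time.
- **Torsion series** uses the IUPAC signed dihedral (cis = 0°; sign checked
  against an independent implementation), smoothed by a moving average
  whose unsupported edges are omitted rather than padded (default window
  5000 points, matching long-trajectory practice; tests use shorter
  windows).
- **The φ–hydration map** is a 2D histogram of (torsion, shell count)
  normalized to unit mass, with presets for the full pre-binding span and
  the last 5 ns before binding.
- **Hydrogen bonds**: donor–acceptor ≤ 3.5 Å and H–donor–acceptor ≤ 30°,
  counts split by the partner water's phase.
- **Distance PDFs** are unit-integral histogram densities (0.2 Å bins).
- **RMSD** uses proper-rotation Kabsch superposition (mirror images are not
  matched); a rotated+translated copy superposes to < 1e−6 Å.

## NMR layer

Cysteine Cβ shifts below 32 ppm classify as reduced (free thiol), above
35 ppm as oxidized (disulfide), between as indeterminate — literature-style
cutoffs, configurable.  If exactly two cysteines are oxidized they are
reported as the inferred bridge; on the packaged shift table (42.07 and
38.84 ppm vs 28.13 and 28.12 ppm) that is (Cys3, Cys13).

Ensemble ranking shortlists the k = 10 lowest-energy models, superposes all
pairs, and scores each by mean RMSD to the rest.  "Lowest energy and RMSD"
is operationalized as the minimal sum of the two ranks, ties broken by
lower energy; both component ranks are emitted so alternative readings
(e.g. RMSD to the lowest-energy model) can be audited from the same matrix.
The result is order-invariant and deterministic.

## IRI quantification

Grain statistics are per-label pixel counts on a pre-segmented integer map
(segmentation of raw micrographs is out of scope).  Border-touching grains
are partial and bias the mean down, so they are excluded by default
(configurable; kept in the Voronoi recovery tests, where the exact-count
identity holds).  The MGA ratio is (mean of sample replicate MGAs)/(mean of
control replicate MGAs), with an SD from per-replicate ratios.  The
statistic is the mean over *all* grains — a largest-grain variant exists as
an option but is not the default.

## Problem sizes and determinism

The default desk-scale profile is 3 trajectories × 160 frames (0.5 ns
interval, 80 ns) in a ~14.7 × 15.6 × 81 Å box (~1900 atoms), against 20 ×
200 ns production-scale runs in the original setting; recovery accuracy,
not realism, is the design target at this scale.  Every stochastic
operation takes an explicit seed and is bit-reproducible; pipeline outputs
carry the hash of the resolved configuration, and reruns are byte-identical.

## Known limitations

- Scripted kinematics: no forces, no thermostat, no thermodynamic realism;
  the trajectories validate analyses, not mechanisms.
- The six placeholder residues make any sequence-level conclusion about
  those positions a property of the stand-in.
- Absolute solvation-shell counts depend on r_shell; only within-package
  comparisons are meaningful.
- The clathrate labels carry a large liquid baseline (see above); the
  packaged defaults record, not resolve, the underlying threshold choice.
- Orthorhombic boxes only; minimum-image convention throughout.
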