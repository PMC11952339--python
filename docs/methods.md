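# Methods

This note documents the models, conventions and numerical choices behind
`enseval`, and what the synthetic fixtures do and do not establish about
real data.

## Representation and units

Proteins are single-chain, heavy-atom only (no hydrogens, no hetero groups,
no altlocs beyond blank/'A').  Coordinates are Angstrom internally
(trajectory formats in nm are converted on read), angles are degrees wrapped
to (−180°, 180°], temperatures Kelvin.  Residues are indexed from 0
internally and from 1 in every report and CLI output, following PDB
convention for users and array convention in code.

Torsions follow the IUPAC definitions: φ(i) = C(i−1)–N–Cα–C,
ψ(i) = N–Cα–C–N(i+1), ω(i) = Cα–C–N(i+1)–Cα(i+1), and the standard χ
quadruples per residue type, capped at χ4 (arginine's χ5 is ignored).  χ
counts: ARG/LYS 4; MET/GLU/GLN 3; ASP/ASN/HIS/ILE/LEU/PHE/PRO/TRP/TYR 2;
SER/THR/VAL/CYS 1; ALA/GLY 0.  Two-fold-degenerate terminal torsions
(ASP/PHE/TYR χ2, GLU χ3) are *not* symmetry-folded; the raw dihedral is
kept, preserving information at the cost of treating ring flips as distinct.
All angular differences are computed on the circle.

## Side-chain torsion divergence (chiJSD)

For each residue and each existing consecutive χ pair — (1,2), (2,3), (3,4)
— the joint distribution of the two angles is discretized into a 3×3
histogram per ensemble, with bin edges at −120°, 0°, 120° per axis; values
outside [−120°, 240°) wrap around the torus, so −180°..−120° joins the
[120°, 240°) bin.  These 120° bins track the three staggered rotamer wells
(gauche−, gauche+, trans), which is why small in-well jitter scores zero
while population shifts between wells register.  The score is the mean over
all residue/pair combinations of the Jensen–Shannon divergence (natural
log, M = (p+q)/2, 0·ln 0 = 0) between the two normalized histograms —
bounded in [0, ln 2], symmetric, zero iff all histograms agree.  No
pseudocounts are added; the JSD handles empty bins natively.  Pairs with
zero valid observations in either ensemble are excluded from the mean and
reported as a warning; a chain with no evaluable pair at all (e.g.
poly-glycine) raises rather than returning a default.

## Foldedness: native contacts, Q, FSF

Native contacts are all residue pairs at least 3 apart in sequence
(|i−j| ≥ 3, the literal reading of "at least 3 residues apart") whose
shortest heavy-atom distance in the native structure is ≤ 10 Å (inclusive).
Per frame, each contact contributes a logistic switch
1/(1+exp(β(d − λd⁰))) with β = 5 Å⁻¹ and λ = 1.2, where d is recomputed as
the same shortest heavy-atom distance; Q is the mean contribution.  A frame
is folded when Q > 0.6 (strict), and the folded-state fraction (FSF) of an
ensemble is the fraction of folded frames.  The 0.6 threshold is a global
pragmatic choice: on the two-state fixtures, folded (native-jittered) frames
score Q ≈ 0.9–1 and unfolded rebuilds Q ≪ 0.6, so FSF reproduces the
generator's realized folded count essentially exactly.

## Secondary structure and SSEP

`assign_sse` is an in-package implementation of the Kabsch–Sander
hydrogen-bond algorithm.  Because the model is hydrogen-free, the amide H is
placed ideally: 1 Å from N, anti-parallel to the preceding carbonyl — the
standard construction used by trajectory-analysis DSSP implementations.
Bond energy E = 0.084·332·(1/dON + 1/dCH − 1/dOH − 1/dCN) kcal/mol with the
−0.5 kcal/mol cutoff; proline and the N-terminal residue cannot donate.
From the bond pattern, 4-turn helices, 3/5-turns and parallel/antiparallel
bridges are derived and reduced to 3 states ({H,G,I}→H, {E,B}→E, else C);
chains shorter than 4 residues are all-coil.  The test suite cross-checks
the assignment against an independent reference implementation on ideal and
jittered fixtures.

SSEP takes the native assignment, keeps the residues in H or E, and scores
each frame by the fraction of those residues whose 3-state assignment equals
the native state; the ensemble value is the frame mean.  It is undefined
(error) for natives with no H/E residue.

## Fluctuation and landscape metrics

RMSF superposes every frame onto the initial structure over Cα atoms
(Kabsch, proper rotations only) and measures fluctuations about the
*ensemble-mean* Cα positions after alignment — the common
trajectory-analysis semantics; the alternative (deviation from the reference
itself) is what initRMSD reports per frame.  Rg is mass-unweighted over
heavy atoms, consistent with the hydrogen-free model.  Contact maps count
Cα pairs with |i−j| ≥ 2 within 9 Å (inclusive ≤).  The landscape model is
PCA on centered, unscaled non-adjacent Cα–Cα distances (all pairs
|i−j| ≥ 2) fitted on the reference ensemble only; query ensembles are
centered by the reference mean and projected on the stored axes.  Free
energy grids bin a 2D projection into 50×50 uniform cells spanning the data
range, set G = −RT ln P (R = 8.314462618×10⁻³ kJ/(mol·K)) from raw
frequencies, mask empty bins as +∞ and shift the occupied minimum to zero;
Boltzmann inversion of the unmasked cells recovers P exactly.

## Melting curves

An observable series f(T) (FSF or SSEP per temperature-labelled ensemble,
≥ 4 unique temperatures) is fitted with
f(T) = y_min + (y_max − y_min)/(1 + exp(−(T − Tm)/k)).  y_min/y_max are
fixed to the series extremes; only (Tm, k) are optimized, by trust-region
least squares with tolerances 10⁻¹².  As printed the curve increases with
T, so decreasing observables fit with negative k rather than a flipped
series — keeping the functional form intact.  Initialization: Tm₀ at the
first linear-interpolated crossing of the half-height, k₀ = ±20 K by series
orientation; Tm is bounded to [min T − 100, max T + 100] K.  Fixing the
y-range to noisy extremes mildly biases Tm (a few K on the two-state
fixtures at 200 frames/temperature); the bias is inherent to that fit
definition and left as-is.  The exposure is statsmodels-style:
`MeltCurveModel(series).fit()` returns a results object with estimates,
residuals and `summary()`.

## Integrity counters

Heavy clashes: pairs of heavy atoms from residues |i−j| ≥ 2 with
d < ½(r_i + r_j), strict inequality, Bondi radii (C 1.70, N 1.55, O 1.52,
S 1.80 Å; configurable).  Candidate pairs come from a KD-tree; the test
suite proves exact agreement with an O(N²) double loop.  Peptide-bond
violations: C(i)–N(i+1) bonds with |b − 1.348 Å|/0.029 Å ≥ 3.0, two-sided
(a 0.09 Å-short bond is as unphysical as a long one) and inclusive at the
boundary.

## Restrained relaxation

Each frame minimizes
E = Σ bonds + Σ angles + planarity terms + restraints + repulsion, where

* bonds/angles are harmonic with idealized equilibria: backbone values
  N–Cα 1.458, Cα–C 1.525, C–O 1.231, C–N 1.348 Å and the standard backbone
  angles; side-chain equilibria are measured from the ideal residue
  templates.  The peptide-bond equilibrium equals the violation counter's
  reference mean so that ideal-geometry chains are fixed points of the
  bonded terms.
* planarity: harmonic circular restraints on ω (to 0° or 180°, whichever
  the input is closer to, preserving cis prolines) and on the carbonyl
  improper keeping O in the Cα–C–N(i+1) plane.
* restraints: harmonic circular tethers on φ/ψ/χ1–4 to their input values
  (default 0.02 energy/deg²) and harmonic tethers on adjacent Cα–Cα
  distances (20 energy/Å²) — the features whose distributions the
  relaxation must not distort.
* repulsion: half-quadratic floor max(0, s(r_i+r_j) − d)² over heavy pairs
  |i−j| ≥ 2 with s = 0.8 (on by default).  Purely bonded terms cannot
  resolve nonbonded overlaps, so a soft repulsive term is part of the
  protocol.

Gradients are analytic throughout (including the torsion terms, whose force
is zeroed for near-collinear quadruples where the dihedral is ill-defined);
minimization is scipy L-BFGS-B, max 200 iterations, gradient tolerance
10⁻³.  Grossly stretched bonds (> 20 % deviation) are healed first in a
pre-stage that moves only the distal atom of each bad bond with the
repulsion off — otherwise the very large bond force drags whole
well-formed groups out of their restrained torsions before the geometry is
sane.  Frames whose energy turns non-finite are returned unmodified with a
diagnostic.  On clash-injected ideal chains the protocol removes all
clashes with Cα shifts of ~0.01–0.1 Å and restrained-torsion drift below
2°; both bounds are asserted by the test suite at 0.6 Å and 5°.

## Synthetic fixtures

All generators are seeded (`numpy.random.default_rng`) and byte-reproducible.
Chains are grown by sequential torsion placement (NeRF) with the idealized
backbone geometry above; peptide bonds are built at 1.348 Å so fresh chains
score zero violations.  Side chains are grafted from the ideal-geometry
residue templates of the chemical component dictionary (bundled with
biotite) by superposing the N/Cα/C frame, then rotated about their bond
axes to exact target χ values (proline keeps its template ring; its χ is
not adjustable).  Named backbone presets: helix (−57°, −47°), extended
(180°, 180°).

* **Two-state ensembles** draw each frame folded with probability
  p(T) = 1/(1+exp((T − Tm)/k)) — defaults Tm = 400 K, k = 20 K, chosen as a
  realistic domain-melting transition width.  Folded frames are the native
  rebuilt with 5° torsion jitter; unfolded frames are uniform-random
  φ/ψ/χ rebuilds accepted when they have ≤ 5 clashes (100 retries,
  best-effort otherwise).  The realized folded count is recorded as ground
  truth.
* **Rotamer ensembles** sample χ pairs from prescribed 9-bin torus tables
  (uniform within a bin).  Consecutive pairs share an angle, so later pairs
  are sampled conditionally on the shared bin; tables must have consistent
  shared marginals for empirical frequencies to converge to them.
* **Defect injection** creates exact, countable defects: a clash spec moves
  a named atom onto a sphere around a target atom along the direction of
  maximal clearance from all other atoms (64 Fibonacci directions), so
  exactly the intended pair clashes; a stretch spec rigidly translates all
  downstream residues along the peptide-bond axis, changing exactly one
  bond.  The manifest of expected counter increments is computed from the
  specs alone, independently of the counters.

What passing on these fixtures shows: the formulas, conventions and
boundary behavior of every score are implemented correctly, end to end.
What it does not show: behavior on real MD ensembles — the fixtures have
idealized geometry (no bond/angle thermal noise), unfolded states with no
physically realistic polymer statistics, no solvent, single chains only,
and sequence lengths of 14–40 residues.  Scores on real data inherit the
definitions, not the fixture magnitudes.

## Problem sizes

The test suite and the acceptance script use 14–40-residue chains,
ensembles of 10–200 frames (2000 for the Gaussian RMSF limit), 8-point
temperature sweeps and 20–50 seeded replicates — sizes at which every
ground-truth recovery (Tm within ±10 K, manifest exactness, σ√3
convergence within 5 %) is statistically comfortable on a single CPU.
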