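# Methods

This note documents the models, conventions, parameters and design
choices behind `nucpack`, and what its synthetic fixtures do and do not
establish about real data.

## Conformational descriptors

Internal dihedrals follow the IUPAC right-hand convention and live in
(−180°, 180°]; χ and the pseudorotation phase *P* are reported on
[0°, 360°), the domain on which the χ mixtures are fitted (nucleotide χ
distributions have no mass near the 0/360 seam, so ordinary rather than
circular statistics apply).

The five endocyclic torsions use the standard furanose quadruples
(ν₀: C4′-O4′-C1′-C2′ … ν₄: C3′-C4′-O4′-C1′).  *P* is obtained from
the inverse formula tan *P* = ((ν₄+ν₁) − (ν₃+ν₀)) / (2ν₂(sin 36° +
sin 72°)) implemented with `atan2`, which realises the +180°
correction for ν₂ < 0 and resolves ν₂ = 0 to 90°/270° by the numerator
sign.  A perfectly planar ring has no phase and raises an error.

The amplitude is τ<sub>M</sub> = ν₂ / cos *P* when |cos *P*| > 0.1;
near *P* = 90°/270° this division is ill-conditioned and τ<sub>M</sub>
is instead fitted by least squares over all five torsions against the
cosine model ν<sub>j</sub> = τ<sub>M</sub> cos(*P* + 144°(j − 2)).

Pucker classes: 2′-endo-like for 80° ≤ *P* < 260°, 3′-endo-like
elsewhere.  The class boundaries are half-open (80° is 2′-endo-like,
260° is 3′-endo-like) so that classification is total; the exact
assignment of the two boundary points is an arbitrary but documented
convention.

Residues with alternate conformers are reduced to the
highest-occupancy altloc on reading (logged).  Non-standard or modified
nucleotides are not coerced into the eight canonical types; analysis
code skips them with a warning.

## Library derivation

Per (nucleoside, pucker-class) group, univariate Gaussian mixtures with
k = 1…20 components are fitted by EM (scikit-learn, full covariance,
tolerance 1e−4, five k-means++ restarts per k, seeded).  The BIC uses
k<sub>free</sub> = 3k − 1 free parameters (means, variances, weights
minus the simplex constraint).  The selected model is the first local
BIC minimum (BIC[k] < BIC[k−1] and BIC[k] ≤ BIC[k+1]); the scan stops
once that index is confirmed, since later fits cannot change it.  If
the BIC decreases monotonically the largest k is kept with a warning.

Curation automates, deterministically, what would otherwise be manual
model inspection: a model with two adjacent means closer than 10° is
rejected and the scan falls back to the next-smaller component count
that passes; components with weight < 1% or SD > 50° are removed and
the remaining weights renormalised to sum to one.  "Adjacent" means
adjacent after sorting by mean on the linear (non-circular) domain.
Curation is idempotent.  χ means are rounded to integers at library
assembly; probabilities are not re-estimated after rounding.

The basic (pucker-independent) library fits one Gaussian by moments to
the samples inside each user-specified χ window; the rotamer
probability is the area under the full fitted curve (in-window count
corrected for the truncated tails) divided by the sum of all areas.

Library files are TSV (`nucleoside class chi sd probability`) with
`repr`-precision floats, so write→read→write round-trips are
byte-identical.

## Idealized geometry

Base geometry is constructed from regular polygons: hexagon side
1.37 Å, fused pentagon matched to the shared edge, exocyclic O/N/C
placed radially at 1.23/1.34/1.50 Å.  This is an intentional
idealization — real bases deviate by a few hundredths of an Ångström —
chosen because every consumer of the geometry (building, detection,
packing, duplex fixtures) uses the same tables, making all round-trip
and recovery tests exact by construction.

Sugar templates are generated by closing a five-membered ring whose
torsions best-fit the cosine pucker model at the requested
(*P*, τ<sub>M</sub>): a least-squares problem over the five atom
positions with strong bond-length weights (O4′-C1′ 1.414 Å …
C4′-O4′ 1.446 Å), soft angle weights, and dominant torsion weights.
Closed five-rings cannot satisfy ideal torsions and ideal angles
simultaneously; the torsions carry the pucker, so they win.  The
measured phase of every generated sugar is within 2° of the request
(typically < 0.5°).  Exocyclic substituents are placed on tetrahedral
directions: C5′ and the base on the β face, O3′/O2′ on the α face,
matching the face assignment of natural β-D-nucleosides.

The seven sugar templates sit on the 18°-spaced pseudorotation wheel:
3′-endo-like positions offer P = 0°, 18°, 36° (³₂T, ³E, ³₄T);
2′-endo-like positions offer P = 180°, 162°, 144°, 126° (²₃T, ²E, ²₁T,
₁E) — four rather than three because the observed 2′-endo phase
distribution is broader.  Template amplitudes default to the observed
distribution maxima: 37° for deoxyribose, 40° for ribose.

Base attachment places the glycosidic nitrogen 1.48 Å along the free
tetrahedral direction at C1′, aligns the base so the external bisector
at the nitrogen points back along the bond, and fixes the remaining
rotation so the measured χ equals the request exactly (the dihedral
responds linearly to rotation about its central bond, so one probe
rotation calibrates the sign).

## Candidate expansion

δχ increments rotate the base rigidly about the glycosidic bond
(sugar untouched); backrub rotates the entire nucleotide about the
C3′-C4′ axis (or the P(i)-P(i+1) axis, which requires the next
residue's phosphate).  χ expansion is applied before backrub.  The
candidate count obeys n<sub>rot</sub> × n<sub>sugar</sub> ×
n<sub>H</sub> × |δχ| × |backrub| per allowed nucleoside; the
identity value 0 must be present in any enabled expansion list.
Hydrogen-placement multiplicity is bookkeeping except for the ribose
2′-OH, where three staggered hydroxyl positions are generated when
requested.

## Packing energies and search

The energy function is deliberately simple and isolated behind
`EnergyModel` so alternatives can be plugged in:

* capped 6-12 Lennard-Jones over heavy atoms (per-element r/ε:
  C 1.70/0.10, N 1.55/0.16, O 1.52/0.20, P 1.80/0.20; pair cap
  10 kcal/mol; 8 Å cutoff).  r<sub>min</sub> of N/O–N/O pairs is
  scaled by 0.85: hydrogen-bonded heavy atoms legitimately sit at
  2.7–3.0 Å, inside the sum of their van der Waals radii, and must not
  be scored as clashes.
* a hydrogen-bond bonus of −3.0 kcal/mol per donor–acceptor pair at
  2.6–3.4 Å with a donor angle ≥ 120°.  Ring N-H donors (G N1, U/T N3)
  measure the donor angle against the ring centroid (the amide H points
  along the external ring-bond bisector); exocyclic amines use their
  ring carbon.  The 3.0 kcal/mol weight was chosen during energy-model
  design so that a lost Watson–Crick hydrogen bond outweighs the extra
  dispersion a larger base earns from stacking; with weaker H-bonds the
  packer substitutes G at A·T positions in wobble-like arrangements.
* a rotamer prior of 0.5 · (−ln p) from the library probability.

Candidates contribute their rebuilt (non-main-chain) atoms to the
energy; main-chain atoms are shared with the fixed frame.  Self
energies include the fixed environment (excluding the candidate's own
residue); pair energies couple candidates at different positions and
are omitted (treated as exactly zero) beyond the cutoff.

Search: iterated Goldstein singles dead-end elimination (provably
never removes a GMEC member), then exhaustive enumeration if the
residual space is ≤ 10⁶ combinations, otherwise Metropolis Monte Carlo
with geometric cooling (default 10 → 0.05 over 20 000 steps, three
restarts, seeded).  Ties break lexicographically by (position,
candidate) index, so outputs are deterministic.  No final gradient
minimisation is applied — the method selects among discrete
candidates only.

## Comparison metrics

* **Pooled side-chain RMSD**: all included atom deviations in a single
  RMSD, no superposition (model and reference share the backbone
  frame).  Excluded: P, OP1, OP2, O5′, C5′, C4′, C3′, O3′ for
  nucleotides; N, CA, C, O, CB for amino acids.  Residues whose
  included atom sets differ (identity redesign) are excluded and
  counted separately; pooled RMSD is reported, not the per-residue
  average (which runs systematically lower on heterogeneous errors).
* **χ recovery**: percentage of positions with absolute circular
  Δχ strictly below 15°; 15.0° exactly is not a match.  Mean Δχ uses
  the same circular-difference primitive.  Identity-redesigned
  positions have no defined Δχ and are excluded.
* **INF** = √(precision · recall) over base-pair and base-stack edges.
  Edge detection is geometric: a pair needs ≥ 2 donor–acceptor
  contacts ≤ 3.4 Å with donor angles ≥ 120° and base planes within
  30°; a stack needs ring centroids < 4.5 Å, planes within 30°, rise
  > 2 Å and lateral offset < 2.5 Å.  These thresholds are documented
  defaults; absolute INF values from other tool chains may differ
  slightly, but model and reference are always processed by the same
  detector.
* **lDDT**: per-residue fraction of inter-residue reference distances
  < 15 Å preserved within 0.5/1/2/4 Å, averaged over thresholds, then
  over residues (the published standard's parameters).
* **F<sub>nat</sub>**: fraction of native protein-residue /
  nucleotide contact pairs (any heavy-atom distance < 5 Å) preserved.

## Synthetic fixtures

The fixture generator exists so that every pipeline stage is testable
without downloads.  `ideal_sugar`/`ideal_nucleotide` realise the
cosine pucker model geometrically and round-trip through the
descriptor code.  `toy_duplex` builds idealized Watson–Crick duplexes
pair-first: a planar pair template per base combination (H-bond
distances 2.9 Å, C1′–C1′ 10.4 Å restraint for two-bond pairs, parity
chosen so no cross-base contact is tighter than the H-bonds), stacked
by rise/twist (B: 3.38 Å/36°, 2′-endo sugars, χ = 250°; A:
2.81 Å/32.7°, 3′-endo sugars, χ = 200°), sugars then attached to match
χ and per-residue phosphates placed from each residue's own
C4′-C5′-O5′ frame.

Known idealizations, and hence limits on what passing tests show about
real data: base pairs are exactly coplanar (no propeller/buckle), the
backbone is not covalently threaded between residues, helical
parameters are single-valued rather than sequence-dependent, and bases
are regular polygons.  Self-recovery on these fixtures demonstrates
internal consistency of building, packing and scoring — the rebuild
path regenerates the fixture geometry exactly when the library
contains the generating χ — not accuracy against experimental
structures, which additionally face measurement noise, modified
residues, and non-ideal puckers between template phases.  Sequence
recovery on the duplex shows the energy model ranks Watson–Crick
complements correctly in ideal geometry; it does not calibrate
absolute energies.

Problem sizes used by the test and acceptance suites — χ samples of
5 000 per group for library recovery, 10-bp duplexes for rebuild and
design, 50 random 4-position instances for the GMEC oracle — were
chosen as the smallest sizes at which the corresponding statistical
tolerances (2° on means, 0.03 on probabilities) are comfortably
non-marginal.

## Numerical notes

* Ring closure and pair-template placement use `scipy.optimize.
  least_squares` from deterministic informed starts; sugar rings fall
  back to a coarse phase grid if the informed start misconverges.
* All stochastic components (sampling, EM restarts, MC/SA) take
  explicit seeds; fixtures are bit-reproducible.
* Superposition uses the SVD (Kabsch) construction with the
  determinant correction, returning proper rotations only; collinear
  point sets raise.
* `curate` guarantees group probabilities re-sum to 1 within 1e−9
  after any removal.
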