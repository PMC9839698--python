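# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `statemap`. It describes what the code computes; every
number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## State-unique interaction maps

**Statistic.** For two residues a, b the contact statistic is the minimum
Euclidean distance over all heavy-atom pairs, backbone atoms included.
Hydrogens are stripped on input: experimental receptor models rarely carry
them, and including them in some structures but not others would bias the
minimum. A residue absent from a model (disordered region) makes every pair
containing it *unresolved* rather than dropped: disordered helix ends are
often exactly the biology under discussion, so their absence is reported.

**Classification.** With thresholds `contact_max` (default 4.6 Å) and
`separated_min` (default 6.0 Å), a cross-helix pair is active-unique iff
d_active < 4.6 and d_inactive > 6.0, inactive-unique for the mirror. Both
inequalities are strict; a distance of exactly 4.6 or 6.0 Å classifies as
neither. `contact_max < separated_min` is enforced at construction, which
makes the two labels mutually exclusive by arithmetic, not by precedence.
The dead band between the thresholds is the rule's robustness margin: a
pair must move by at least 1.4 Å between states to be called.

**Scope of "helix".** Any residue carrying a generic number participates;
helix 8 counts as a helix by default and can be excluded
(`include_h8=False`), since the field's usage varies. Residues without a
generic number (loops) are not analysed. No sequence-separation filter is
applied beyond the different-helix requirement.

**Cross-receptor correspondence.** Residues correspond iff their generic
numbers agree after applying the difference of the two receptors' per-helix
offsets. The offset mechanism exists because some receptor families register
a one-residue slide on a helix (TM5 in the GPR21/GPR52 family) relative to
canonical class-A numbering; the slide's direction is configuration, not a
hard-coded constant, because published descriptions state its existence but
not its sign. Correspondence uses generic numbers only — amino-acid identity
is never required, matching how conservation of an *interaction* (not of a
residue type) is defined.

**Conservation check.** Reference pairs (state-unique in some reference
receptor) are located in a query receptor through the query's offsets and
flagged `interacting` iff the closest-atom distance is strictly below
`contact_max`. Missing residues give status `unresolved`.

## Superposition and r.m.s.d.

Rigid superposition uses the SVD (Kabsch) solution with the reflection
branch suppressed (determinant forced to +1). Degenerate inputs — fewer than
3 points, or all points collinear (second singular value below 1e-10 of the
first) — raise instead of returning an arbitrary rotation. `ca_rmsd`
superposes Cα atoms of generic-number-matched residues only and reports
`n_atoms`, because an r.m.s.d. without its matched-residue set is not
reproducible; published receptor-comparison values depend on exactly that
choice, which is rarely stated. The test suite cross-checks the SVD route
against an independent quaternion-eigenvalue (Kearsley) implementation to
1e-6 Å.

## Radius of gyration

Rg = sqrt(Σ wᵢ |rᵢ − r̄|² / Σ wᵢ) with r̄ the weighted centroid. Default
weights are atomic masses over heavy atoms (the MD-analysis convention);
`mass_weighted=False` and a Cα-only atom scope are available for
sensitivity checks. Ensembles are consumed from a plain whitespace
xyz-per-frame text format; Rg is rotation/translation-invariant and scales
linearly with coordinates, both asserted as properties.

## Orientation-consistency particle filter

Rationale: a particle whose image genuinely determines its orientation
re-converges to (nearly) the same Euler assignment when refinement is
continued past convergence; ambiguous particles wander. The filter measures,
for each particle, the geodesic angle between each post-convergence cycle's
rotation and the *converged reference* assignment (an alternative
consecutive-cycle mode is selectable), and eliminates the particle when the
deviation exceeds `angle_threshold` (default 9°) in strictly more than
`fraction_threshold` (default 50%) of `n_cycles` (default 7) cycles — i.e.
≥ 4 of 7 under the defaults.

Conventions and numerics: Euler triplets are ZYZ intrinsic
(R = Rz(rot)·Ry(tilt)·Rz(psi)), the RELION STAR convention. The geodesic
angle clips the trace argument to [−1, 1] before arccos and requires inputs
orthonormal to 1e-6. In-plane shifts are ignored (the criterion is angular)
and no point-group symmetry is applied — the intended targets are
asymmetric receptor–G-protein complexes; for symmetric particles the angle
would need minimisation over the symmetry group, which is out of scope.
Decisions are invariant to cycle order and to any global rotation applied to
all orientations, and the angle agrees with the quaternion formula
2·arccos|q₁·q₂| to better than 1e-8 degrees (both verified in tests).

STAR I/O is a deliberately small reader/writer for the RELION 3.1 particles
dialect (loop blocks, `_rln` tags, optional optics block); surviving
particles are written in input order with all original columns.

## HDX percent deuteration

The envelope centroid is the intensity-weighted mean m/z. Percent
deuteration is 100·(c(t) − c_undeut)/(c_fullD − c_undeut): anchoring the
100% point at the fully deuterated control corrects back-exchange because
the control loses deuterium through the same digestion/chromatography path.
Values outside [0, 100] are flagged (`out_of_range`) but never clamped —
clamping would hide control or noise problems. Centroids are compared on
m/z within one charge state; no deconvolution to neutral mass is performed.
A crude bimodality check (an intensity dip between two local maxima) logs a
warning as a cooperative-unfolding (EX1) tell-tale; actual bimodal fitting
is upstream software's job and out of scope.

## Assay normalisations

BRET ratio = acceptor/donor emission (510/400 nm);
ΔBRET = ratio(receptor + sensor) − ratio(sensor only), negative values
permitted (dissociation sensors decrease on activation). HTRF response(%)
maps the untransfected-cell mean ratio to 0% and the wild-type receptor
mean to 100%; it is invariant under common affine transforms of all ratios.
Replicate summaries are arithmetic mean ± s.e.m. (sample sd, ddof = 1).
Significance testing is out of scope: it is routine statistics run in
standard packages.

## Synthetic data: what it emulates, and what it does not

* **Two-state bundles** are ideal poly-alanine helices (rise 1.5 Å/residue,
  twist 100°, Cα radius 2.3 Å; N, CA, C, O, CB per residue with CB pointing
  outward) placed on configurable axes; the "inactive" copy applies a rigid
  per-helix shift. Generic numbers run along each helix with position 50 at
  the midpoint, so offset logic is exercised. The planted truth enumerates
  all cross-helix pairs meeting the state-unique rule by an independent
  brute-force double loop inside the generator — never by calling the
  interaction-map module. Not emulated: side-chain rotamers, loop regions,
  and helix bending; the threshold rule does not depend on them, so passing
  tests validate the classification logic and distance computation, not
  atomic-detail realism.
* **Orientation sets** give well-behaved particles a per-cycle deviation
  uniform in [0, noise°] about a random axis, and planted deviants an exact
  `offset°` excursion in ⌊n_cycles/2⌋ + 1 cycles — the minimum count whose
  fraction strictly exceeds 50% — so elimination is guaranteed whenever the
  offset clears the angular threshold. Defaults used throughout testing are
  100 particles, 20 deviants, 0.5° noise, 20° offset, 7 cycles. Not
  emulated: refinement physics, defocus/CTF, or correlated drift.
* **Isotope envelopes** are discrete Gaussians at isotope spacing 1/charge
  with 1% multiplicative intensity noise; the centroid follows first-order
  kinetics c(t) = c₀ + U·(1 − e^(−kt)), so truth %D = 100·(1 − e^(−kt)).
  Test settings (σ = 0.35 Th, 5 time points of 0–900 s, 10 peptides) recover
  %D to within 0.5 percentage points. Not emulated: natural isotope
  abundance fine structure, overlapping peptides, EX1 bimodality.
* **Unfolding ensembles** interpolate a Cα segment from ideal helix to an
  extended 3.8 Å/residue chain about a common centroid; squared Rg is then a
  convex quadratic in the mixing weight with positive initial slope for
  segments of ≥ 4 residues, so the profile is strictly increasing by
  construction — a clean monotone ground truth for `rg_profile`.

All generators are pure functions of parameters + seed; STAR outputs are
byte-reproducible for a fixed seed.

## Problem sizes and determinism

The verification suite uses bundles of ≤ 32 residues (50 random geometries
for map/oracle equivalence, 20 for conservation), 100-particle orientation
sets over 20 seeds, 1000 rotation pairs for the quaternion cross-check, and
10 × 5 HDX recovery points — sizes at which the brute-force oracles are
exact and the full suite runs in seconds. Property tests run hypothesis
with fixed example budgets; all other randomness flows through explicit
`numpy.random.default_rng` seeds.

## Known limitations

* Generic-number assignment is an input; the package does not derive
  numbering from sequence or structure.
* Closest-atom distances take deposited coordinates at face value — no
  occupancy weighting beyond altloc selection, no B-factor screening.
* The particle filter assumes C1 symmetry and one particles table per STAR
  file.
* Comparisons of published receptor-pair r.m.s.d. values require the
  deposited coordinate files and knowledge of the matched-residue set the
  original analysis used; `ca_rmsd` reports `n_atoms` precisely so such
  comparisons can be made explicit when those files are available.
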