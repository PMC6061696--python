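# Methods

## Scope and data model

The package analyses *processed* coordinate ensembles: NMR-style
multi-model PDB files or plain frame-series text with a fixed atom
table. Frames are assumed imaged/whole — periodic boundary conditions
are not modelled, because the inputs are deposition- or export-stage
ensembles, not raw trajectories. Author residue numbering is kept
verbatim (1–27 for the neomycin-sensing riboswitch construct) and never
re-indexed, so atom references match the literature labels (U14, A17,
…). Ribose prime dialects (`O2'`, `O2′`, `O2*`) are normalized to one
internal spelling. Waters are recognized by residue names HOH/WAT and
cations by K/K+/NA/NA+/MG. Units are fixed: Å, ps, mM, Hz, ppm.

## Hydrogen bonds and water bridges

A candidate donor–hydrogen–acceptor triple is counted as an H-bond when
the heavy-atom distance is **strictly** below `d_max` (default 3.5 Å)
and the D–H–A angle **strictly** above `angle_min` (default 120°).
Strict inequalities make counts at threshold values reproducible.
Hydrogens are required — structures without them are rejected rather
than approximated with heavy-atom-only surrogates, which would silently
change the criterion. A water bridge between a donor group and an
acceptor exists when some water oxygen accepts from the donor under the
same criteria and donates to the acceptor via either of its hydrogens;
ties between qualifying waters are broken by the smallest water residue
number.

## Base planes and oxygen-π contacts

Base planes are least-squares planes through the ring atoms (pyrimidine
N1–C6; purine N1–C6 + N7/C8/N9), computed from the SVD of the centered
coordinates; the normal's sign is fixed along the glycosidic N→C1′
direction for reproducibility. Whether exocyclic atoms belong in the
plane is genuinely open; ring-only is the default and
`include_exocyclic=True` adds the carbonyl/amino substituents.
Atom–plane distances (anion-π, lone-pair-π contacts) are unsigned
perpendicular distances per frame, summarized as **median ± standard
deviation** (population sd; midpoint convention for even counts). The
median/sd pair is a declared convention — published tables print
"median ± x" without defining the spread, and one testable choice had
to be fixed.

## Conformer classification of cWW U/U pairs

The two built-in schemes encode the riboswitch's U/U pairs. For
U10/U21: *2a* = U10(N3)→U21(O4) + U21(N3)→U10(O2); *2b* mirrors the
roles (U10(N3)→U21(O2) + U21(N3)→U10(O4)); in the single-bond variants
*1a*/*1b* the H-bond **involving O2** is water-mediated. The
loop-closing U13/U18 pair is sterically restricted to *2a*
(U13(N3)→U18(O4) + U18(N3)→U13(O2)) and its water-mediated variant
*1a*. Because the mediated contact is pinned to O2 by definition,
relabelling O2↔O4 maps 2a↔2b but carries 1a/1b outside the scheme —
the classifier then reports `unassigned`, which the test suite asserts.

Priority when several states' requirements hold simultaneously: more
direct H-bonds wins (a frame satisfying both 2a bonds is 2a even if a
bridging water is also present), then scheme list order. Populations
are reported both over all frames (with the unassigned fraction
explicit) and renormalized over assigned frames; ensembles without
explicit waters cannot exhibit mediated states, which is flagged
(`water_states_available`) rather than reported as population zero.

## NOE ensemble averaging

The effective distance of a restraint is the r⁻⁶-weighted average
`d = [⟨Σ_A Σ_B r_ab⁻⁶⟩_frames]^(−1/6)`, with multi-proton groups
combined by the r⁻⁶ sum before frame averaging (no pseudoatoms, no
bound corrections; r⁻³ is available as a configuration alternative and
recorded in report metadata). A restraint is violated when the
ensemble distance exceeds its upper bound by strictly more than 0.3 Å.
Restraints whose atoms do not resolve are listed separately and
excluded from the applicable denominator, giving "V of N" totals.

## Cation atmosphere

RDFs are normalized by the uniform expectation at the ensemble's mean
ion count over the analysis sphere, so an ideal-gas ion cloud converges
to g(r) = 1 (verified at two frame counts with the expected ~1/√frames
error decay). Site occupancy is keyed to the **primary** coordinating
atom only — a frame is occupied when any ion of the species is within
the inner cutoff (default 3.4 Å, the first RDF minimum for K⁺/Na⁺–O
contacts on the fixtures; configurable, and re-derivable from the RDF
operator, which is the documented workflow). Auxiliary atoms receive
descriptive per-frame labels: inner (< inner cutoff), outer (inner to
outer cutoff, default 6.0 Å — a distance-shell proxy for
water-separated coordination; water-verified assignment would be an
extension), or none. Residence episodes are maximal runs of occupied
frames; a gap tolerance (default 0, i.e. strict) can absorb short
interruptions and is reported in output metadata. Density maxima are
computed on a 0.5 Å grid over pre-aligned ensembles, with greedy
merging of cells whose peaks lie within 2 Å and occupancy-weighted
centroids.

## Superposition and per-residue RMSD

Frames are aligned by Kabsch rotation onto frame 1, averaged, re-aligned
onto the average and re-averaged until the average moves < 1e-4 Å
(max per-atom displacement). Per-residue heavy-atom RMSD is computed
against the final average. The rotation solver is cross-checked in the
tests against an independent quaternion-based implementation.

## NMR model fits

**Constant-time coupling.** `I_cross/I_ref = cos(π J τ_m)` is fitted
with one global J pooled over replicates with equal weight per point
(duplicating a replicate therefore leaves the optimum unchanged, which
is asserted). Initialization is a grid search over J ∈ [0, 20] Hz in
0.05 Hz steps — generous for the few-Hz couplings transmitted across
N–H···O–P bridges — refined by bounded least squares; when sparse delay
sets make several J values fit equally, the smallest is returned (the
first cosine zero). Uncertainty is a seeded residual bootstrap (200
resamples by default).

**Titration isotherms.** Single-site `Δδ_max·c/(K_D + c)` and a
cooperative two-ion form `Δδ_max·c²/(K_D² + c²)`; the latter is a Hill
form with coefficient fixed at 2, the simplest surrogate for
two-ion cooperative binding when the underlying sequential constants
are not identifiable from a single shift curve (flagged in all
outputs). Free ligand is approximated by total ligand — valid for
mM-scale titrant against µM-scale RNA, the regime these experiments
occupy. K_D is initialized at the concentration nearest half the
maximum observed shift and bounded positive; series that decrease with
concentration are rejected with a hint to negate the shifts (fitted
amplitudes are therefore positive by construction). `compare_models`
reports both fits and the ratio of residual mean squares; since both
models have two parameters the extra-sum-of-squares test degenerates,
so no automatic verdict is rendered.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (spec, seed) — bit-reproducible —
and their defaults are chosen so the declared round-trip guarantees
hold with margin:

- **Conformer ensembles.** Two planar pyrimidine-like residues (regular
  hexagon, radius 1.40 Å, with radially attached O2/O4/H3/C1′). For
  each state, residue B is placed rigidly by scanning its in-plane
  orientation (including the 180° in-plane flip that relates the two
  faces) and solving the two contact-distance constraints as a
  circle-intersection problem; candidates are scored by the worst donor
  angle subject to exclusivity (non-required imino–oxygen contacts
  > 4.2 Å) and clash floors. Required bonds are realized at 2.9 Å with
  donor angles ≈ 136–175°; water-mediated contacts place the oxygen
  2.9 Å from the donor, swung off-axis to balance the donor-angle and
  the 3.5 Å donating-distance margins, with one O–H aimed at the
  acceptor. Each template is verified to classify as its own label at
  zero noise before any frames are emitted. States switch via a
  user-supplied row-stochastic per-frame Markov matrix; coordinate
  noise is isotropic Gaussian (default σ = 0.05 Å, at which the worst
  per-state misclassification rate is ~0.2%). These are toy
  coordinates: they guarantee the *logical truth of each state's
  geometric predicate*, not RNA chemistry — passing tests demonstrate
  correct classification logic, not force-field realism.
- **Ion tracks.** A two-state chain with geometric (discrete-time
  memoryless) dwells: bound dwells have the prescribed mean residence,
  unbound dwells follow from the bound fraction. Bound frames place the
  ion at 2.8 Å mean contact distance with 0.15 Å Gaussian scatter —
  kept > 3σ inside the 3.4 Å inner shell so detection noise does not
  fragment episodes; bulk frames are uniform in a 40 Å box outside the
  6 Å exclusion radius.
- **NMR observables.** Exact model curves plus Gaussian noise. The
  titration-recovery property fixes noise σ = 0.01 ppm and 8 points;
  the saturation amplitude is set to 0.3 ppm, a mid-range imino-proton
  response to mM-scale cation binding (≈ 3% relative noise), under
  which the median K_D error over 100 replicates is ~7%.

## Problem sizes and determinism

The recovery checks use 10⁵-frame chains for populations and ion
kinetics, 2×10⁴-frame fixtures for RDF flatness, and 100 seeded
replicates for fit-recovery statistics — sizes at which binomial /
√N tolerances are meaningful while whole-suite runs stay interactive.
All stochastic outputs carry their seed; identical configs reproduce
byte-identical reports (timestamps are kept out of report files).

## Known limitations

- The deposited-ensemble checks need `data/2n0j.pdb`; the package does
  not ship third-party coordinates.
- Distance-shell outer-sphere assignment does not verify an intervening
  water.
- The cooperative isotherm is a fixed-coefficient Hill surrogate, not a
  sequential two-site model.
- Classification covers user-defined and built-in U/U schemes, not a
  general Leontis–Westhof classifier.
- No electronic-structure treatment of the oxygen-π contacts — they are
  measured as geometry only.
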