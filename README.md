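# uturn

Ensemble analysis for the RNA **U-turn** motif, built around the
neomycin-sensing riboswitch (NSR) — a 27-nucleotide hairpin whose apical
loop folds into the classic 5′-UNR-3′ U-turn. The package takes
coordinate ensembles (solution-NMR multi-model PDB files or frame series
exported from simulations) plus tabulated NMR observables, and answers
the questions a structural study of such a motif asks:

- **Hydrogen bonds and water bridges** — the strict geometric criterion
  (donor–acceptor heavy-atom distance < 3.5 Å *and*
  donor–hydrogen–acceptor angle > 120°), applied per frame, including
  water-mediated contacts.
- **cWW U/U base-pair conformers** — a U/U cis Watson–Crick pair can form
  two isosteric double-H-bond arrangements (*2a*, *2b*; they differ in
  which carbonyl, O4 or O2, each imino group contacts) and single-bond
  variants (*1a*, *1b*) in which the O2 contact is water-mediated.
  Frames are classified and state populations / transitions tabulated.
- **NOE validation** — r⁻⁶ ensemble-averaged distances,
  d = [⟨Σ r⁻⁶⟩]^(−1/6), compared with upper bounds; violations counted
  when the excess exceeds 0.3 Å ("V of N" reporting).
- **Cation atmosphere** — normalized radial distribution functions g(r),
  binding-site occupancy keyed to a primary coordinating atom (e.g. the
  O4 carbonyl of the conserved uridine) with inner/outer-shell labels,
  residence-time episodes, and density maxima on aligned ensembles.
- **Base-plane contacts** — least-squares base planes and perpendicular
  atom–plane distances (anion-π and lone-pair-π contacts), summarized as
  median ± sd.
- **NMR model fits** — the constant-time trans-H-bond scalar coupling
  I_cross/I_ref = cos(π·²ʰJ_H,P·τ_m), and chemical-shift titration
  isotherms Δδ(c) = Δδ_max·c/(K_D + c) (1:1) or
  Δδ_max·c²/(K_D² + c²) (cooperative two-ion, Hill coefficient 2).
- **Synthetic data** — seeded generators for every input above
  (Markov-switching conformer ensembles with bridging waters, two-state
  ion tracks with geometric dwell times, noisy titration and cosine-decay
  tables), so the full pipeline is testable without downloads.

## Worked example

Simulate a conformer ensemble of the U10/U21 pair hopping among its four
arrangements, classify every frame, then fit synthetic NMR observables:

```sh
$ uturn simulate conformers --out pair.frames --scheme U10U21 \
      --n-frames 2000 --stay 0.9 --seed 11
$ uturn states pair.frames --scheme U10U21 --csv labels.csv
{
  "fractions_all_frames": {
    "1a": 0.2345, "1b": 0.199, "2a": 0.2735, "2b": 0.293,
    "unassigned": 0.0
  },
  ...
}
```

With a symmetric transition matrix the four states are equally likely;
the observed fractions scatter around 0.25 with zero unassigned frames
(every generated frame satisfies exactly one state's H-bond pattern).

```sh
$ uturn simulate ct --out ct.tsv --j 2.7 --seed 11
$ uturn fit-j ct.tsv
{ "J_Hz": 2.6978, "J_se_Hz": 0.0054, ... }

$ uturn simulate titration --out titr.tsv --kd 11 --seed 11
$ uturn fit-kd titr.tsv
{ "model": "single-site", "kd_mM": 10.65, "kd_ci_mM": [6.18, 15.86], ... }
```

The coupling fit recovers the 2.7 Hz used to generate the decay to
within its bootstrap uncertainty; the titration fit recovers an
apparent K_D of ~11 mM — the magnitude reported for monovalent-cation
binding at a U-turn — with a residual-bootstrap confidence interval.

Whole-run configs are supported too: `uturn run config.toml` executes
all configured sections (states, planes, NOE, ions, RMSD) and writes a
deterministic `report.json` plus CSV tables.

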