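# Methods

`crossbeta` re-implements, as a tested pipeline on synthetic data, the
aggregate-stability analysis of single-sheet parallel oligomers of GNNQQNY
sequence variants (N2D = GDNQQNY, N2S = GSNQQNY, N6D = GNNQQDY). The
pipeline has four layers: an aggregate **builder**, a **synthetic
trajectory generator**, an **observables** layer, and an **event/verdict
classifier**, tied together by the study-design metadata in `plan`.
Nothing here integrates equations of motion: the generator produces
trajectories with the *statistical structure* the analysis assumes, so
every analysis stage can be validated against known ground truth.

## Aggregate construction

A strand is built heavy-atoms-only from internal coordinates with
idealized extended-β dihedrals (φ = −120°, ψ = +120°, ω = 180°), standard
backbone bond lengths/angles, and one fixed rotamer per side-chain type
(χ₁ anti; terminal amide/carboxylate groups oriented so their donor and
acceptor atoms spread along the sheet stacking axis, which is where the
Asn/Gln "polar zipper" ladders run in a parallel in-register sheet; the
Tyr ring plane is oriented perpendicular to the stacking axis so stacked
rings sit face to face). L-chirality of the Cα centres was verified against
an independently embedded reference amino acid. Hydrogens are not
modelled; hydrogen-bond chemistry lives on donor/acceptor heavy atoms,
each donor carrying one antecedent atom standing in for the covalent
direction of the missing proton.

Strands are stacked by pure translation along +z at an inter-strand
spacing of 0.48 nm (the canonical cross-β value; configurable). Before
stacking, the strand is put in a canonical orientation: the Cα2→Cα6 vector
lies exactly along +x — so an imposed twist about z is recovered exactly
by the twist observable — and the roll about x is chosen once,
deterministically (1° grid), to maximise the number of inter-strand
backbone H-bonds at the canonical spacing, the orientation real sheets
adopt. The resulting planar in-register build has 6–7 backbone H-bonds and
~4 side-chain H-bonds per adjacent pair, 0.48 nm registry at every
residue, and Tyr ring-plane distances of ≈0.43 nm.

Per-pair twist is applied cumulatively about the common stacking axis;
antiparallel pairs rotate the strand 180° about the stacking axis through
its own centroid (a rotation about the *strand* axis would flip faces
without reversing direction). Builds abort with a named pair when any
inter-peptide heavy-atom distance falls below 0.15 nm; with the fixed
rotamers this limits static twisted builds to ≲5°/pair at 0.48 nm spacing,
so twist-recovery experiments build at 0.6 nm, where the measurement —
which is what those experiments probe — is unaffected.

## Synthetic trajectories

A `ScenarioScript` is a list of scheduled events plus a noise level and a
seed. Each event realises one entry of the molecular-event taxonomy
(disorder, dissociation, rearrangement, disintegration, collapse, plus the
stable-system phenomena progressive twist and end fraying) as a kinematic
transform interpolated linearly over its frame window and held afterwards:

- **progressive twist** — strand k rotates k·θ about the stacking axis
  (default θ reaches 10°/pair, inside the range sheet ladders survive);
- **end fraying** — the named terminal residues swing laterally about the
  stacking axis through the boundary Cα, with alternating direction per
  strand so fraying is incoherent across the sheet and genuinely breaks
  the terminal ladder rungs;
- **disorder** — per-residue φ/ψ perturbations of the named peptide,
  applied by bond rotation with the centre of mass restored, so the
  peptide melts without translating. Perturbations use a random sign and a
  magnitude uniform in [σ/2, 3σ/2] (σ = 25° by default, larger in the
  demonstrative preset): the magnitude floor makes the scripted event
  deliver its nominal severity for every draw, where a plain Gaussian
  occasionally samples a near-identity perturbation;
- **dissociation** — rigid translation of one peptide along a given
  direction (default 2.0 nm, far beyond the 0.45 nm contact cutoff);
- **rearrangement** — 180° rotation of one peptide of the named pair about
  the stacking axis through its own centroid (parallel → antiparallel);
- **disintegration** — rigid translation of the blocks of a partition
  away from each other;
- **collapse** — radial contraction of peptide centres of mass toward the
  aggregate centre (default factor 0.7; 0.55 in the preset) combined with
  random rigid reorientation and internal φ/ψ melting of each peptide,
  yielding a compact amorphous mass rather than a shrunken sheet.

Noise is isotropic Gaussian per atom per frame about the scripted
geometry (not a random walk), with the mass-weighted mean displacement
subtracted per peptide ("rigid-body filtered"): scripted positions are the
exact mean of every peptide's centre of mass, making parameter recovery
well-posed. Defaults: 100 frames at 0.5 ns/frame — a desk-scale analogue
of a 50 ns production run — and σ = 0.01 nm. All randomness derives from
the script seed; trajectories are bitwise reproducible.

What the generator does **not** emulate: forces, solvent, sterics during
event interpolation (peptides may transiently interpenetrate), thermal
kinetics, or temperature (which enters only as metadata). Passing tests
therefore demonstrate that the *analysis* recovers scripted phenomenology
under positional noise — not that the physical conclusions about real
trajectories would be reproduced.

## Observables

- **Rg / ΔRg** — mass-weighted radius of gyration; ΔRg is the mean over
  the final 5 % of frames minus the mean over the initial 5 % (window
  fraction configurable; 0 gives strict single-frame differences).
- **Pair twist** — unsigned angle in [0°, 180°] between the Cα2→Cα6
  vectors of two peptides. The trajectory-level estimator averages the
  vectors over frames before taking the angle, removing the positive
  fold-over bias near 0°.
- **Registry** — per-residue Cα–Cα distances between equivalent residues,
  plus an integer register-offset estimate (arg-min over shifts).
- **Tyr stacking** — symmetrised centroid-to-plane projection onto the
  best-fit (SVD) ring normals; stacked means < 0.5 nm, with the boundary
  value itself not stacked. A centroid–centroid variant is available.
- **Hydrogen bonds** — donor–acceptor heavy-atom distance ≤ 0.35 nm and
  antecedent–donor–acceptor angle ≥ 90°, classified backbone/side-chain/
  mixed and intra/inter-peptide; same-residue pairs are excluded. The
  criterion and both cutoffs are configuration fields.
- **Sheet assignment** — a residue is E when it belongs to a
  registry-consistent ladder: ≥ 2 backbone–backbone bridges to the same
  partner peptide, at most two residues apart (extended strands bond every
  other residue on one face), whose partner residues advance by the same
  (parallel) or negated (antiparallel) amount. Registry consistency is
  what separates a genuine sheet from incidental backbone contacts in
  compact disordered geometry; it is the extended-strand ladder of DSSP
  without the remaining 7 states.
- **Edge classification** — without explicit solvent, "H-bonds with the
  solvent" is operationalised structurally: for a peptide with exactly one
  neighbour, side-chain donors whose proton direction points away from
  that neighbour are unsatisfied; if the unsatisfied weight concentrates on
  the even-position (2/4/6) face the peptide is the N-edge, on the odd
  face the C-edge. Peptides with two neighbours are interior; with none,
  detached.
- **Residue profiles** — time-averaged per-residue backbone/side-chain
  H-bond counts and sheet frequency, with the two edge peptides excluded
  by default (they have a single partner and systematically fewer
  contacts).

## Events and verdicts

Two peptides are connected when they share ≥ 2 backbone H-bonds or
approach within 0.45 nm; clusters are the connected components, computed
per frame. Every trigger below must hold for a persistence window of 5
consecutive frames (noise-flicker suppression; the original methodology
used visual inspection, which these rules replace with documented
criteria):

- **dissociation** — a singleton leaves the tracked main cluster;
- **disintegration** — the main cluster splits into ≥ 2 blocks of ≥ 2;
- **disorder** — a peptide's sheet content falls below 2 residues while it
  stays in a cluster *and* its internally superposed RMSD from the start
  exceeds 0.1 nm. The deformation term distinguishes a genuinely melted
  strand from an intact strand that merely lost its ladder partner (e.g.
  while a neighbour flips);
- **rearrangement** — an adjacent, in-cluster pair of internally intact
  strands changes orientation class (parallel < 50°, antiparallel > 130°,
  crossed between — thresholds symmetric about 90° and configurable) or
  slides by ≥ 1 residue of register;
- **collapse** — compaction (Rg-to-date ≤ −0.1 nm versus the initial
  window) together with loss of sheet structure (running *minimum* of the
  mean sheet content below 50 % of initial). Both terms are cumulative
  because accidental contacts in the compacted mass can masquerade as
  sheet bridges later in the trajectory.

The verdict is **stable** when the initial organisation is retained:
|ΔRg| < 0.1 nm, no detected event of the five-class taxonomy, and no
peptide detached in the final frame. Any detected event makes the system
unstable — disorder and rearrangement included, since they break the
initial organisation even when Rg is unchanged. The **key event** is the
first record, except that a terminal event (disintegration, dissociation,
collapse) within two persistence windows of the earliest onset takes
precedence: one physical process usually trips secondary triggers first
(a collapse reorients pairs before the compaction gate is crossed).
Within one window, ties resolve by class priority
(disintegration > dissociation > collapse > rearrangement > disorder).

The oligomer census tracks every cluster of ≥ 2 peptides as long as its
membership is unchanged; lifetime is (death − birth) × frame spacing, and
records are flagged *ordered* when their members average at least half
their residues in sheet state.

Known limitation: a heavily melted peptide lying on the sheet edge can
re-form short registry-consistent ladders with its neighbour by chance, in
which case the disorder call is conservative (the run is still reported
unstable through the ΔRg or detachment gates when those trip). This
affects a few percent of disorder-scenario draws and none of the other
scenario classes.

## Configuration

All cutoffs live in one frozen `AnalysisConfig` (YAML round-trip, content
hash recorded in every report): stacking 0.5 nm and ΔRg gate 0.1 nm (the
printed criteria), H-bond 0.35 nm / 90°, contact 0.45 nm, orientation
50°/130°, persistence 5 frames, ΔRg window 5 %, collapse sheet fraction
50 %, internal-RMSD threshold 0.1 nm, spacing 0.48 nm, noise 0.01 nm.
Neither the Rg weighting (mass-weighted, the common MD convention) nor the
H-bond and ring-plane constructions are printed in the study this design
follows; they are documented choices exposed as configuration, not facts
about the original analysis.

## Problem sizes

Validation experiments run on 4–8-peptide sheets with 100-frame
trajectories: the scenario-recovery experiment uses the six canonical
presets × 10 seeds at noise 0.01 nm (and the same grid noise-free), twist
recovery uses 4-mers at four twist angles with 100 noisy frames, and the
oracle equivalence checks use 50 perturbed frames (Rg) and all four sheet
sizes × two termini states (H-bonds). These sizes match the systems of the
study design (5–8 peptides) and give stable statistics for the recovery
rates reported.
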