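# crossbeta

Stability analysis of single-sheet parallel amyloid oligomers of GNNQQNY
sequence variants — the amyloidogenic heptapeptide of the yeast prion
protein Sup35 — rebuilt as a tested, synthetic-data pipeline.

The peptide GNNQQNY stacks into parallel in-register cross-β sheets whose
stability depends on sequence, aggregate size (5–8 peptides per sheet) and
the protonation state of the termini (charged NH₃⁺/COO⁻ vs neutral
NH₂/COOH). Single point mutations — N2D (GDNQQNY), N2S (GSNQQNY), N6D
(GNNQQDY) — perturb the Asn/Gln side-chain hydrogen-bond ladders (the
"polar zipper") and shift the balance between stable twisted sheets and
aggregates that fall apart by **disorder**, **dissociation**,
**rearrangement**, **disintegration** or **collapse**.

`crossbeta` provides the full analysis layer for such systems, plus a
synthetic trajectory generator so every stage is testable without
molecular dynamics:

- `crossbeta.plan` — the 50-run study design (3 mutants × 4 sizes ×
  2 temperatures × 2 termini states, plus two re-seeded replicates) and
  the packaged per-system reference verdicts;
- `crossbeta.builder` — idealized heavy-atom parallel in-register sheets
  (extended-β strands, one rotamer per side chain, 0.48 nm stacking);
- `crossbeta.synthgen` — scripted trajectories: thermal positional noise
  about kinematic events drawn from the taxonomy above;
- `crossbeta.observables` — radius of gyration and ΔRg = Rg(final) −
  Rg(initial), the inter-peptide twist order parameter (angle between the
  Cα2→Cα6 vectors, stability gate |ΔRg| < 0.1 nm), per-residue registry
  distances, Tyr ring-plane stacking (< 0.5 nm), a geometric hydrogen-bond
  census, DSSP-style sheet ladders, N-edge/C-edge classification;
- `crossbeta.events` — connectivity clusters, event records with onset
  times, an ordered-oligomer census with lifetimes, and the
  stable/unstable verdict with its key event.

## Worked example

Build a neutral-termini N2S 6-mer, simulate an edge-peptide dissociation
and classify it:

```sh
crossbeta simulate --scenario edge_dissociation --n 6 --mutant N2S \
    --termini neutral --seed 7 --out traj.pdb
crossbeta analyze --traj traj.pdb --out report/
```

which prints

```
verdict: unstable (key event: dissociation, ΔRg +0.501 nm)
```

The scripted event translates the top edge peptide 2 nm away between
frames 40 and 60; the classifier detects the dissociation at frame 44
(when the peptide crosses the 0.45 nm contact cutoff), the radius of
gyration of the aggregate grows by 0.50 nm — far past the 0.1 nm
stability gate — and the verdict matches the script. `report/` contains
tidy per-pair observables (`observables.csv`), the event records
(`events.json`), the verdict with the configuration hash
(`verdict.json`) and the oligomer census (`census.json`).

The same from Python:

```python
from crossbeta import (PeptideSpec, AggregateSpec, build_sheet,
                       preset_scenarios, generate_trajectory,
                       detect_events, stability_verdict)

sheet = build_sheet(PeptideSpec("GSNQQNY", "neutral"), AggregateSpec(6))
script = preset_scenarios(6, seed=7)["edge_dissociation"]
traj = generate_trajectory(sheet, script)
print(stability_verdict(traj))
# StabilityVerdict(verdict='unstable', key_event='dissociation',
#                  delta_rg=0.500..., n_events=1)
```

The numbered scripts under `analysis/` walk the study end to end —
design matrix, built aggregates, one trajectory per scenario, stable-system
observables (twist plateau ≈10°/pair, Tyr rings stacked at ≈0.4 nm),
per-residue H-bond effects of the three mutations, and the
scenario-recovery confusion matrix — writing their tables to `results/`.

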