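"""Per-residue hydrogen-bond profiles across the sequence variants.

Compares the built aggregates of the wild type and the three mutants:
replacing Asn2 by Ser abolishes the position-2 side-chain ladder, and the
Asp6 carboxylate (no donor) loses the position-6 ladder, while the N6D
backbone network is untouched — the directions reported for the real
trajectories.
"""

from pathlib import Path

import pandas as pd

from crossbeta.builder import AggregateSpec, PeptideSpec, build_sheet
from crossbeta.observables import residue_profiles
from crossbeta.synthgen import ScenarioScript, generate_trajectory

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SYSTEMS = {"WT": "GNNQQNY", "N2D": "GDNQQNY", "N2S": "GSNQQNY", "N6D": "GNNQQDY"}

rows = []
for label, seq in SYSTEMS.items():
    sheet = build_sheet(PeptideSpec(seq, "neutral"), AggregateSpec(6))
    traj = generate_trajectory(sheet, ScenarioScript(n_frames=20, noise_sigma=0.01, seed=0))
    prof = residue_profiles(traj, exclude_edges=True)
    for r in range(7):
        rows.append({
            "system": label, "residue": r + 1, "aa": seq[r],
            "bb_hbonds": round(prof.bb_hbonds[r], 2),
            "sc_hbonds": round(prof.sc_hbonds[r], 2),
            "sheet_frequency": round(prof.sheet_frequency[r], 2),
        })

df = pd.DataFrame(rows)
df.to_csv(OUT / "residue_hbond_profiles.csv", index=False)
wide = df.pivot(index="residue", columns="system", values="sc_hbonds")
print("side-chain H-bonds per residue (interior peptides, time-averaged):")
print(wide.to_string())

wt2, s2 = wide.loc[2, "WT"], wide.loc[2, "N2S"]
wt6, d6 = wide.loc[6, "WT"], wide.loc[6, "N6D"]
print(f"\nposition 2: Ser {s2} vs Asn {wt2} side-chain H-bonds (mutation removes the polar zipper)")
print(f"position 6: Asp {d6} vs Asn {wt6} (carboxylate has no donor)")
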