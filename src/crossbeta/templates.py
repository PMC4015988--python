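"""Residue templates: heavy-atom internal coordinates and H-bond chemistry.

Only the residue types occurring in GNNQQNY and its N2D/N2S/N6D variants are
provided (Gly, Asn, Gln, Tyr, Asp, Ser). Hydrogens are not modelled; the
hydrogen-bond criterion operates on donor/acceptor heavy atoms, with each
donor carrying one named antecedent atom that stands in for the covalent
direction of the missing proton.

Side chains use a single rotamer per residue type (chi1 anti; terminal polar
groups oriented so that their donor/acceptor atoms spread along the sheet
stacking axis, which is where amide ladders — the "polar zipper" — form in
parallel in-register sheets).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# sequence bookkeeping

ONE_TO_THREE = {
    "G": "GLY",
    "N": "ASN",
    "Q": "GLN",
    "Y": "TYR",
    "D": "ASP",
    "S": "SER",
    "A": "ALA",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

WILD_TYPE = "GNNQQNY"

MASSES = {"C": 12.011, "N": 14.007, "O": 15.999}

# ---------------------------------------------------------------------------
# backbone internal coordinates (nm / degrees)

BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_C_OXT = 0.1249

ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_CA_C_OXT = 117.0

# idealised extended-strand dihedrals
PHI_BETA = -120.0
PSI_BETA = 120.0
OMEGA_TRANS = 180.0

# improper torsion N-C-CA-CB fixing L-chirality
CB_TORSION = 122.6
BOND_CA_CB = 0.1530
ANGLE_C_CA_CB = 110.5

# ---------------------------------------------------------------------------
# side-chain internal coordinates
#
# Each entry: (atom, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
# meaning: place atom with NeRF from the three already-placed reference atoms
# of the same residue; angle is ref_b-ref_c-atom, torsion ref_a-ref_b-ref_c-atom.

SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [
        ("OG", "O", ("N", "CA", "CB"), 0.1417, 110.8, 180.0),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 0.1516, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 0.1231, 120.8, -90.0),
        ("ND2", "N", ("CA", "CB", "CG"), 0.1328, 116.4, 90.0),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 0.1516, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 0.1249, 118.4, -90.0),
        ("OD2", "O", ("CA", "CB", "CG"), 0.1249, 118.4, 90.0),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 0.1516, 112.6, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 0.1231, 120.8, -90.0),
        ("NE2", "N", ("CB", "CG", "CD"), 0.1328, 116.4, 90.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 0.1512, 113.9, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 0.1389, 120.8, 0.0),
        ("CD2", "C", ("CA", "CB", "CG"), 0.1389, 120.8, 180.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 0.1382, 121.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 0.1382, 121.2, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 0.1378, 119.6, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 0.1376, 119.9, 180.0),
    ],
}

TYR_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

# ---------------------------------------------------------------------------
# hydrogen-bond chemistry
#
# Side-chain donors map atom -> antecedent; acceptors are plain sets.
# Backbone chemistry (amide N donor with CA antecedent, carbonyl O acceptor)
# and the termini (which depend on protonation state) are handled by the
# builder when it annotates the topology.

SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "GLY": {},
    "ALA": {},
    "SER": {"OG": "CB"},
    "ASN": {"ND2": "CG"},
    "ASP": {},  # carboxylate: acceptors only
    "GLN": {"NE2": "CD"},
    "TYR": {"OH": "CZ"},
}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "GLY": set(),
    "ALA": set(),
    "SER": {"OG"},
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "TYR": {"OH"},
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def sidechain_atom_names(resname: str) -> list[str]:
    """CB plus the template side-chain atoms, in build order."""
    if resname in ("GLY",):
        return []
    return ["CB"] + [entry[0] for entry in SIDE_CHAINS[resname]]
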