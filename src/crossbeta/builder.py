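"""Construction of idealized parallel in-register single β-sheets.

A strand is built heavy-atoms-only from internal coordinates with idealized
extended-β dihedrals (φ = −120°, ψ = +120°, ω = 180°) and a single rotamer
per side chain. Strands are stacked by pure translation along the sheet
axis, optionally with a cumulative inter-strand twist, register stagger, or
antiparallel flips.

The strand is put into a canonical orientation before stacking: the
Cα2→Cα6 vector lies exactly along +x (so an imposed twist about the
stacking axis z is recovered exactly by the twist observable), and the roll
about x is chosen — once, deterministically — to maximise the number of
backbone hydrogen bonds to a translated copy at the canonical 0.48 nm
spacing, which is how strands orient in real cross-β sheets.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import templates as T
from .core import Frame, Topology, PEPTIDE_LETTERS
from .geometry import place_atom, rotation_matrix, unit

__all__ = [
    "PeptideSpec",
    "AggregateSpec",
    "InvalidSpecError",
    "BuildClashError",
    "mutate_sequence",
    "build_strand",
    "build_sheet",
    "apply_rigid_transform",
]

# criterion used only for the one-off canonical roll scan; the configurable
# analysis criterion lives in crossbeta.config / crossbeta.observables
_HB_DIST = 0.35
_HB_ANGLE = 90.0
_CANONICAL_SPACING = 0.48
_CLASH_DIST = 0.15


class InvalidSpecError(ValueError):
    """Raised for inconsistent mutant labels or malformed peptide specs."""


class BuildClashError(RuntimeError):
    """Raised when a built sheet contains an inter-peptide steric clash."""

    def __init__(self, pair: tuple[str, str], distance: float):
        self.pair = pair
        self.distance = distance
        super().__init__(
            f"steric clash between peptides {pair[0]} and {pair[1]} "
            f"({distance:.3f} nm < {_CLASH_DIST} nm)"
        )


@dataclass(frozen=True)
class PeptideSpec:
    sequence: str = T.WILD_TYPE
    termini: str = "charged"  # 'charged' (NH3+/COO-) or 'neutral' (NH2/COOH)

    def __post_init__(self):
        if len(self.sequence) != 7:
            raise InvalidSpecError(f"sequence must have 7 residues, got {self.sequence!r}")
        for aa in self.sequence:
            if aa not in T.ONE_TO_THREE:
                raise InvalidSpecError(f"no residue template for {aa!r}")
        if self.termini not in ("charged", "neutral"):
            raise InvalidSpecError(f"termini must be 'charged' or 'neutral', got {self.termini!r}")


@dataclass(frozen=True)
class AggregateSpec:
    n_peptides: int
    inter_strand_spacing: float = 0.48  # nm, canonical cross-β value
    register_offset: int = 0  # residues, applied cumulatively strand-to-strand
    per_pair_twist: float = 0.0  # degrees about the stacking axis, cumulative
    orientations: tuple[str, ...] = field(default=())  # per adjacent pair

    def pair_orientations(self) -> tuple[str, ...]:
        if self.orientations:
            if len(self.orientations) != self.n_peptides - 1:
                raise InvalidSpecError("need one orientation per adjacent pair")
            return self.orientations
        return ("parallel",) * (self.n_peptides - 1)


def mutate_sequence(base: str, label: str) -> str:
    """Apply a point-mutation label of the form XpY (e.g. N2D) to a sequence."""
    if len(label) != 3 or not label[1].isdigit():
        raise InvalidSpecError(f"malformed mutant label {label!r}")
    wt, pos, mut = label[0], int(label[1]), label[2]
    if not 1 <= pos <= len(base):
        raise InvalidSpecError(f"position {pos} outside 1..{len(base)}")
    if base[pos - 1] != wt:
        raise InvalidSpecError(
            f"label {label!r} inconsistent: position {pos} of {base} is {base[pos - 1]}, not {wt}"
        )
    if mut not in T.ONE_TO_THREE:
        raise InvalidSpecError(f"no residue template for {mut!r}")
    return base[: pos - 1] + mut + base[pos:]


# ---------------------------------------------------------------------------
# single-strand construction


def _build_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C positions for an ideal extended strand."""
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([T.BOND_N_CA, 0.0, 0.0])
    ang = np.radians(T.ANGLE_N_CA_C)
    c = ca + T.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_res):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], T.BOND_C_N, T.ANGLE_CA_C_N, T.PSI_BETA)
        ca = place_atom(prev["CA"], prev["C"], n, T.BOND_N_CA, T.ANGLE_C_N_CA, T.OMEGA_TRANS)
        c = place_atom(prev["C"], n, ca, T.BOND_CA_C, T.ANGLE_N_CA_C, T.PHI_BETA)
        residues.append({"N": n, "CA": ca, "C": c})
    return residues


def _add_oxygens_and_sidechains(residues: list[dict[str, np.ndarray]]) -> None:
    n_res = len(residues)
    for i, res in enumerate(residues):
        # carbonyl O anti to the next amide N (ideal trans peptide plane)
        res["O"] = place_atom(res["N"], res["CA"], res["C"], T.BOND_C_O, T.ANGLE_CA_C_O, T.PSI_BETA + 180.0)
        if i == n_res - 1:
            res["OXT"] = place_atom(res["N"], res["CA"], res["C"], T.BOND_C_OXT, T.ANGLE_CA_C_OXT, T.PSI_BETA)


def _add_cb_and_sidechain(res: dict[str, np.ndarray], resname: str) -> None:
    if resname == "GLY":
        return
    res["CB"] = place_atom(res["N"], res["C"], res["CA"], T.BOND_CA_CB, T.ANGLE_C_CA_CB, T.CB_TORSION)
    for name, _el, refs, bond, angle, torsion in T.SIDE_CHAINS[resname]:
        a, b, c = (res[r] for r in refs)
        res[name] = place_atom(a, b, c, bond, angle, torsion)


def _strand_atoms(spec: PeptideSpec):
    """Build one strand; returns (names per atom, coords, residue metadata)."""
    resnames = [T.ONE_TO_THREE[aa] for aa in spec.sequence]
    residues = _build_backbone(len(resnames))
    _add_oxygens_and_sidechains(residues)
    for res, resname in zip(residues, resnames):
        _add_cb_and_sidechain(res, resname)

    atom_rows: list[tuple[int, str, str, str]] = []  # (res_idx, resname, atom, element)
    coords: list[np.ndarray] = []
    for i, (res, resname) in enumerate(zip(residues, resnames), start=1):
        names = ["N", "CA", "C", "O"] + T.sidechain_atom_names(resname)
        if i == len(resnames):
            names.append("OXT")
        for nm in names:
            el = nm[0] if nm[0] in T.MASSES else nm[:1]
            atom_rows.append((i, resname, nm, el))
            coords.append(res[nm])
    return atom_rows, np.array(coords)


def _annotate(atom_rows, termini: str):
    """Backbone flags and donor/acceptor chemistry for one strand."""
    n_atoms = len(atom_rows)
    backbone = np.zeros(n_atoms, dtype=bool)
    is_donor = np.zeros(n_atoms, dtype=bool)
    is_acceptor = np.zeros(n_atoms, dtype=bool)
    antecedent = np.full(n_atoms, -1, dtype=int)

    index = {(r, nm): i for i, (r, _rn, nm, _el) in enumerate(atom_rows)}
    n_res = max(r for r, *_ in atom_rows)

    for i, (r, resname, nm, _el) in enumerate(atom_rows):
        if nm in T.BACKBONE_ATOMS:
            backbone[i] = True
        if nm == "N":
            # amide NH donor; at the N-terminus an ammonium (charged) or
            # amine (neutral) — donor either way, CA as antecedent
            is_donor[i] = True
            antecedent[i] = index[(r, "CA")]
        elif nm == "O":
            is_acceptor[i] = True
        elif nm == "OXT":
            if termini == "charged":
                is_acceptor[i] = True  # carboxylate: both oxygens accept
            else:
                is_donor[i] = True  # carboxylic acid OH
                antecedent[i] = index[(r, "C")]
        else:
            don = T.SIDECHAIN_DONORS[resname]
            if nm in don:
                is_donor[i] = True
                antecedent[i] = index[(r, don[nm])]
            if nm in T.SIDECHAIN_ACCEPTORS[resname]:
                is_acceptor[i] = True
    assert n_res >= 1
    return backbone, is_donor, is_acceptor, antecedent


def _count_interstrand_hbonds(coords, is_donor, is_acceptor, antecedent, shift) -> int:
    """Backbone+side-chain H-bonds between a strand and its +shift copy.

    Used only to pick the canonical roll angle; the same distance/angle
    criterion as the analysis default.
    """
    other = coords + shift
    count = 0
    for layer_a, layer_b in ((coords, other), (other, coords)):
        di = np.nonzero(is_donor)[0]
        ai = np.nonzero(is_acceptor)[0]
        d_xyz = layer_a[di]
        ant_xyz = layer_a[antecedent[di]]
        a_xyz = layer_b[ai]
        dist = cdist(d_xyz, a_xyz)
        for u, v in zip(*np.nonzero(dist <= _HB_DIST)):
            vec1 = ant_xyz[u] - d_xyz[u]
            vec2 = a_xyz[v] - d_xyz[u]
            cosang = np.dot(vec1, vec2) / (np.linalg.norm(vec1) * np.linalg.norm(vec2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= _HB_ANGLE:
                count += 1
    return count


@functools.lru_cache(maxsize=32)
def _canonical_strand(sequence: str, termini: str):
    spec = PeptideSpec(sequence, termini)
    atom_rows, coords = _strand_atoms(spec)
    backbone, is_donor, is_acceptor, antecedent = _annotate(atom_rows, termini)

    # center on the Cα centroid
    ca_mask = np.array([nm == "CA" for _r, _rn, nm, _el in atom_rows])
    coords = coords - coords[ca_mask].mean(axis=0)

    # align Cα2→Cα6 exactly onto +x
    index = {(r, nm): i for i, (r, _rn, nm, _el) in enumerate(atom_rows)}
    v = coords[index[(6, "CA")]] - coords[index[(2, "CA")]]
    vhat = unit(v)
    target = np.array([1.0, 0.0, 0.0])
    axis = np.cross(vhat, target)
    if np.linalg.norm(axis) > 1e-12:
        ang = np.degrees(np.arccos(np.clip(np.dot(vhat, target), -1, 1)))
        coords = coords @ rotation_matrix(axis, ang).T
    coords = coords - coords[ca_mask].mean(axis=0)

    # roll about x: orient amide/carbonyl faces for maximal inter-strand
    # H-bonding at the canonical spacing (deterministic 1° grid, first max)
    shift = np.array([0.0, 0.0, _CANONICAL_SPACING])
    best_angle, best_count = 0.0, -1
    for alpha in np.arange(0.0, 360.0, 1.0):
        rolled = coords @ rotation_matrix([1.0, 0.0, 0.0], alpha).T
        c = _count_interstrand_hbonds(rolled, is_donor, is_acceptor, antecedent, shift)
        if c > best_count:
            best_angle, best_count = alpha, c
    coords = coords @ rotation_matrix([1.0, 0.0, 0.0], best_angle).T
    coords = coords - coords[ca_mask].mean(axis=0)

    return atom_rows, coords, (backbone, is_donor, is_acceptor, antecedent)


def build_strand(spec: PeptideSpec) -> Frame:
    """Build a single extended β-strand in canonical orientation (peptide A)."""
    atom_rows, coords, (backbone, is_donor, is_acceptor, antecedent) = _canonical_strand(
        spec.sequence, spec.termini
    )
    n = len(atom_rows)
    top = Topology(
        peptide_ids=np.array(["A"] * n),
        residue_index=np.array([r for r, *_ in atom_rows]),
        residue_names=np.array([rn for _r, rn, *_ in atom_rows]),
        atom_names=np.array([nm for _r, _rn, nm, _el in atom_rows]),
        elements=np.array([el for *_x, el in atom_rows]),
        backbone=backbone.copy(),
        is_donor=is_donor.copy(),
        is_acceptor=is_acceptor.copy(),
        antecedent=antecedent.copy(),
        termini=spec.termini,
    )
    return Frame(top, coords.copy())


def build_sheet(pspec: PeptideSpec, aspec: AggregateSpec) -> Frame:
    """Stack strands into a single sheet along +z.

    Strand k sits at z = k·spacing. Antiparallel pairs flip the strand 180°
    about the stacking axis through its own centroid; the cumulative
    per-pair twist is applied about the common stacking axis.
    """
    if aspec.n_peptides < 2:
        raise InvalidSpecError("a sheet needs at least 2 peptides")
    if aspec.n_peptides > len(PEPTIDE_LETTERS):
        raise InvalidSpecError(f"at most {len(PEPTIDE_LETTERS)} peptides supported")

    atom_rows, coords0, (backbone, is_donor, is_acceptor, antecedent) = _canonical_strand(
        pspec.sequence, pspec.termini
    )
    n_atoms = len(atom_rows)
    index = {(r, nm): i for i, (r, _rn, nm, _el) in enumerate(atom_rows)}
    rise = np.linalg.norm(coords0[index[(6, "CA")]] - coords0[index[(2, "CA")]]) / 4.0

    orientations = aspec.pair_orientations()
    flipped = False
    all_coords = []
    for k in range(aspec.n_peptides):
        if k > 0 and orientations[k - 1] == "antiparallel":
            flipped = not flipped
        c = coords0.copy()
        if flipped:
            c = c @ rotation_matrix([0.0, 0.0, 1.0], 180.0).T
        c[:, 0] += k * aspec.register_offset * rise
        if aspec.per_pair_twist != 0.0:
            c = c @ rotation_matrix([0.0, 0.0, 1.0], k * aspec.per_pair_twist).T
        c[:, 2] += k * aspec.inter_strand_spacing
        all_coords.append(c)

    peptides = [PEPTIDE_LETTERS[k] for k in range(aspec.n_peptides)]
    for a in range(aspec.n_peptides):
        for b in range(a + 1, aspec.n_peptides):
            dmin = cdist(all_coords[a], all_coords[b]).min()
            if dmin < _CLASH_DIST:
                raise BuildClashError((peptides[a], peptides[b]), float(dmin))

    reps = aspec.n_peptides
    offset = np.arange(reps) * n_atoms
    top = Topology(
        peptide_ids=np.repeat(peptides, n_atoms),
        residue_index=np.tile([r for r, *_ in atom_rows], reps),
        residue_names=np.tile([rn for _r, rn, *_ in atom_rows], reps),
        atom_names=np.tile([nm for _r, _rn, nm, _el in atom_rows], reps),
        elements=np.tile([el for *_x, el in atom_rows], reps),
        backbone=np.tile(backbone, reps),
        is_donor=np.tile(is_donor, reps),
        is_acceptor=np.tile(is_acceptor, reps),
        antecedent=np.concatenate([np.where(antecedent >= 0, antecedent + o, -1) for o in offset]),
        termini=pspec.termini,
    )
    return Frame(top, np.concatenate(all_coords))


def apply_rigid_transform(
    frame: Frame,
    peptide_id: str,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    center: np.ndarray | None = None,
) -> Frame:
    """Rigidly transform one peptide, leaving all others untouched.

    The rotation is applied about ``center`` (default: the peptide's own
    centroid), then the translation is added.
    """
    if peptide_id not in frame.topology.peptides:
        raise KeyError(f"unknown peptide id {peptide_id!r}")
    out = frame.copy()
    mask = frame.topology.select(peptide=peptide_id)
    xyz = out.coords[mask]
    if rotation is not None and np.array_equal(rotation, np.eye(3)):
        rotation = None  # identity stays bitwise-exact
    if rotation is not None:
        ctr = xyz.mean(axis=0) if center is None else np.asarray(center, dtype=float)
        xyz = (xyz - ctr) @ np.asarray(rotation).T + ctr
    if translation is not None:
        xyz = xyz + np.asarray(translation, dtype=float)
    out.coords[mask] = xyz
    return out
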