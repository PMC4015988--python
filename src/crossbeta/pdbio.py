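"""Trajectory interchange as multi-model PDB (via biotite).

Chains are peptide ids, residues are numbered 1..7, coordinates are stored
in Å (the package works in nm internally). Donor/acceptor annotation is not
representable in PDB, so the termini protonation state and the frame
spacing are carried in ``REMARK 250`` lines and re-derived from the residue
templates on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .builder import _annotate
from .core import Frame, Topology, Trajectory
from .templates import MASSES

__all__ = ["TrajectoryFormatError", "write_trajectory", "read_trajectory"]

_REMARK_TERMINI = "REMARK 250 CROSSBETA TERMINI"
_REMARK_DT = "REMARK 250 CROSSBETA FRAME_DT_NS"


class TrajectoryFormatError(ValueError):
    """Malformed or inconsistent multi-model PDB input."""


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (Å)."""
    top = traj.topology
    n = top.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = top.peptide_ids.astype("<U4")
    template.res_id = top.residue_index
    template.res_name = top.residue_names.astype("<U5")
    template.atom_name = top.atom_names.astype("<U6")
    template.element = top.elements.astype("<U2")
    template.hetero = np.zeros(n, dtype=bool)

    stack = struc.AtomArrayStack(traj.n_frames, n)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.coords * 10.0  # nm -> Å

    pdb = PDBFile()
    pdb.set_structure(stack)
    dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 0.0
    remarks = [
        f"{_REMARK_TERMINI} {top.termini.upper()}",
        f"{_REMARK_DT} {dt:.6f}",
    ]
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


def write_frame(frame: Frame, path: str | Path) -> None:
    """Write a single frame as a one-model PDB file."""
    traj = Trajectory(frame.topology, frame.coords[None, :, :], np.array([frame.time]))
    write_trajectory(traj, path)


def _check_model_consistency(lines: list[str]) -> None:
    counts: list[int] = []
    current = None
    for ln in lines:
        if ln.startswith("MODEL"):
            current = 0
        elif ln.startswith("ENDMDL"):
            counts.append(current or 0)
            current = None
        elif ln.startswith(("ATOM", "HETATM")) and current is not None:
            current += 1
    if counts and len(set(counts)) > 1:
        ref = counts[0]
        for i, c in enumerate(counts, start=1):
            if c != ref:
                raise TrajectoryFormatError(
                    f"model {i} has {c} atoms, expected {ref}: inconsistent roster"
                )


def read_trajectory(
    path: str | Path,
    termini: str | None = None,
    frame_dt: float | None = None,
) -> Trajectory:
    """Read a (single- or multi-model) PDB file into a Trajectory.

    ``termini`` and ``frame_dt`` default to the values recorded in the
    file's REMARK lines, falling back to 'charged' and 0.5 ns.
    """
    pdb = PDBFile.read(str(path))
    _check_model_consistency(pdb.lines)
    for ln in pdb.lines:
        if ln.startswith(_REMARK_TERMINI) and termini is None:
            termini = ln.split()[-1].lower()
        elif ln.startswith(_REMARK_DT) and frame_dt is None:
            frame_dt = float(ln.split()[-1])
    termini = termini or "charged"
    frame_dt = 0.5 if frame_dt is None else frame_dt

    stack = pdb.get_structure(model=None)
    first = stack[0]

    # rebuild topology with template-derived chemistry, chain by chain
    peptide_ids = np.asarray(first.chain_id, dtype="<U1")
    residue_index = np.asarray(first.res_id, dtype=int)
    residue_names = np.asarray(first.res_name, dtype="<U3")
    atom_names = np.asarray(first.atom_name, dtype="<U4")
    elements = np.asarray([e[:1] for e in first.element], dtype="<U1")
    for el in np.unique(elements):
        if el not in MASSES:
            raise TrajectoryFormatError(f"unsupported element {el!r} in {path}")

    backbone = np.zeros(len(first), dtype=bool)
    is_donor = np.zeros(len(first), dtype=bool)
    is_acceptor = np.zeros(len(first), dtype=bool)
    antecedent = np.full(len(first), -1, dtype=int)
    for chain in dict.fromkeys(peptide_ids):  # preserve order
        idx = np.nonzero(peptide_ids == chain)[0]
        rows = [
            (int(residue_index[i]), str(residue_names[i]), str(atom_names[i]), str(elements[i]))
            for i in idx
        ]
        try:
            bb, don, acc, ant = _annotate(rows, termini)
        except KeyError as exc:
            raise TrajectoryFormatError(f"chain {chain}: unknown residue/atom {exc}") from exc
        backbone[idx], is_donor[idx], is_acceptor[idx] = bb, don, acc
        antecedent[idx] = np.where(ant >= 0, idx[0] + ant, -1)

    topology = Topology(
        peptide_ids=peptide_ids,
        residue_index=residue_index,
        residue_names=residue_names,
        atom_names=atom_names,
        elements=elements,
        backbone=backbone,
        is_donor=is_donor,
        is_acceptor=is_acceptor,
        antecedent=antecedent,
        termini=termini,
    )
    coords = stack.coord / 10.0  # Å -> nm
    times = np.arange(coords.shape[0]) * frame_dt if frame_dt > 0 else np.arange(coords.shape[0], dtype=float)
    return Trajectory(topology, coords, times, {"source": str(path)})
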