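"""In-memory containers: Topology, Frame, Trajectory.

A Topology is the constant atom roster of an aggregate: peptide identity
(letters A.. along the stacking axis), 1-based residue index, residue/atom
names, element, backbone flag and donor/acceptor annotation. Frames and
Trajectories carry coordinates (nm) against a shared Topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .templates import MASSES

PEPTIDE_LETTERS = "ABCDEFGH"


@dataclass
class Topology:
    """Constant per-atom metadata for an aggregate."""

    peptide_ids: np.ndarray  # '<U1'
    residue_index: np.ndarray  # int, 1-based within each peptide
    residue_names: np.ndarray  # '<U3'
    atom_names: np.ndarray  # '<U4'
    elements: np.ndarray  # '<U1'
    backbone: np.ndarray  # bool
    is_donor: np.ndarray  # bool
    is_acceptor: np.ndarray  # bool
    antecedent: np.ndarray  # int index of donor antecedent atom, -1 otherwise
    termini: str = "charged"

    def __post_init__(self) -> None:
        self.peptide_ids = np.asarray(self.peptide_ids)
        self.residue_index = np.asarray(self.residue_index, dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def peptides(self) -> list[str]:
        """Peptide ids in stacking order (first occurrence order)."""
        seen: list[str] = []
        for p in self.peptide_ids:
            if p not in seen:
                seen.append(str(p))
        return seen

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max())

    @property
    def masses(self) -> np.ndarray:
        return np.array([MASSES[e] for e in self.elements])

    def select(
        self,
        peptide: str | Iterable[str] | None = None,
        residue: int | Iterable[int] | None = None,
        atom: str | Iterable[str] | None = None,
        backbone: bool | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if peptide is not None:
            pep = [peptide] if isinstance(peptide, str) else list(peptide)
            mask &= np.isin(self.peptide_ids, pep)
        if residue is not None:
            res = [residue] if isinstance(residue, int) else list(residue)
            mask &= np.isin(self.residue_index, res)
        if atom is not None:
            at = [atom] if isinstance(atom, str) else list(atom)
            mask &= np.isin(self.atom_names, at)
        if backbone is not None:
            mask &= self.backbone == backbone
        return mask

    def index_of(self, peptide: str, residue: int, atom: str) -> int:
        idx = np.nonzero(self.select(peptide=peptide, residue=residue, atom=atom))[0]
        if len(idx) != 1:
            raise KeyError(f"atom {peptide}/{residue}/{atom} not found (or ambiguous)")
        return int(idx[0])

    def sequence(self, peptide: str | None = None) -> list[str]:
        """Residue names (3-letter) of one peptide, in residue order."""
        pep = peptide or self.peptides[0]
        out = []
        for r in range(1, self.n_residues + 1):
            mask = self.select(peptide=pep, residue=r, atom="CA")
            names = self.residue_names[mask]
            out.append(str(names[0]))
        return out


@dataclass
class Frame:
    """One snapshot: coordinates (nm) plus a time stamp (ns)."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )

    def copy(self) -> "Frame":
        return Frame(self.topology, self.coords.copy(), self.time)

    def com(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted centre of mass of the selected atoms."""
        if mask is None:
            mask = np.ones(self.topology.n_atoms, dtype=bool)
        m = self.topology.masses[mask]
        return (self.coords[mask] * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class Trajectory:
    """Ordered frames over a constant atom roster."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ns, strictly increasing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != len(self.times):
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], float(self.times[i]))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def trajectory_from_frames(frames: Sequence[Frame], provenance: dict | None = None) -> Trajectory:
    if not frames:
        raise ValueError("need at least one frame")
    top = frames[0].topology
    coords = np.stack([f.coords for f in frames])
    times = np.array([f.time for f in frames])
    return Trajectory(top, coords, times, provenance or {})
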