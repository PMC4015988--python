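"""Synthetic trajectory generation: scripted molecular events plus noise.

The generator emulates the phenomenology the analysis layer must detect —
progressive sheet twist, end fraying, peptide disorder, dissociation,
rearrangement, disintegration and collapse — as smooth kinematic
transformations of an idealized starting aggregate, with isotropic Gaussian
positional noise about the scripted geometry. No forces or solvent are
involved; temperature is metadata only.

Noise is rigid-body filtered per peptide (the mass-weighted mean
displacement is subtracted), so the scripted geometry is the exact mean of
each peptide's centre of mass and parameter recovery is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .config import AnalysisConfig, DEFAULT_CONFIG
from .core import Frame, Trajectory
from .geometry import rotation_matrix

__all__ = [
    "ScheduledEvent",
    "ScenarioScript",
    "ScriptConflictError",
    "generate_trajectory",
    "preset_scenarios",
    "expected_split_frame",
]

EVENT_TYPES = (
    "progressive_twist",
    "end_fray",
    "disorder",
    "dissociation",
    "rearrangement",
    "disintegration",
    "collapse",
)

#: event types that terminate the initial organisation (used by presets'
#: expected outcomes; detection lives in crossbeta.events)
TERMINAL_EVENTS = ("dissociation", "disintegration", "collapse")


class ScriptConflictError(ValueError):
    """Raised when two scheduled events contradict each other."""


@dataclass(frozen=True)
class ScheduledEvent:
    type: str
    peptides: tuple[str, ...]
    start_frame: int
    end_frame: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError("event window must satisfy 0 <= start < end")
        if self.type == "dissociation" and len(self.peptides) != 1:
            raise ValueError("dissociation names exactly one peptide")
        if self.type == "rearrangement" and len(self.peptides) != 2:
            raise ValueError("rearrangement names one pair of peptides")
        if self.type == "disintegration":
            part = self.params.get("partition")
            if not part or len(part) < 2 or any(len(b) < 1 for b in part):
                raise ValueError("disintegration needs a partition into >= 2 non-empty blocks")

    def scale(self, t: int) -> float:
        """Linear interpolation parameter in [0, 1]; holds at 1 after the end."""
        if t <= self.start_frame:
            return 0.0
        if t >= self.end_frame:
            return 1.0
        return (t - self.start_frame) / (self.end_frame - self.start_frame)


@dataclass(frozen=True)
class ScenarioScript:
    n_frames: int = 100
    frame_dt: float = 0.5  # ns
    noise_sigma: float = 0.01  # nm
    seed: int = 0
    events: tuple[ScheduledEvent, ...] = ()
    # declared outcome, used by scenario-recovery experiments
    expected_verdict: str | None = None
    expected_key_event: str | None = None

    def __post_init__(self):
        starts = [e.start_frame for e in self.events]
        if starts != sorted(starts):
            raise ValueError("events must be sorted by start frame")
        for e in self.events:
            if e.end_frame >= self.n_frames:
                raise ValueError("event window extends past the trajectory")

    def with_seed(self, seed: int) -> "ScenarioScript":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# event kinematics


def _rotate_about(coords: np.ndarray, axis, angle_deg: float, center: np.ndarray) -> np.ndarray:
    R = rotation_matrix(axis, angle_deg)
    return (coords - center) @ R.T + center


def _dihedral_draw(rng: np.random.Generator, sigma: float, n_res: int) -> np.ndarray:
    """Random-sign φ/ψ targets with magnitude uniform in [σ/2, 3σ/2].

    The magnitude floor guarantees that a scripted disorder event genuinely
    melts the strand at its nominal scale for every draw, instead of
    occasionally sampling a near-identity perturbation.
    """
    mag = rng.uniform(0.5 * sigma, 1.5 * sigma, size=(n_res, 2))
    sign = rng.choice((-1.0, 1.0), size=(n_res, 2))
    return sign * mag


def _materialise(event: ScheduledEvent, frame0: Frame, rng: np.random.Generator) -> dict:
    """Draw any random kinematic targets once, so the script is reproducible."""
    drawn: dict = {}
    if event.type == "disorder":
        sigma = event.params.get("dihedral_sigma", 25.0)
        n_res = frame0.topology.n_residues
        drawn["dihedral_deltas"] = {
            pep: _dihedral_draw(rng, sigma, n_res) for pep in event.peptides
        }
    elif event.type == "collapse":
        axes, angles = {}, {}
        lo, hi = event.params.get("rotation_range", (60.0, 150.0))
        for pep in event.peptides:
            v = rng.normal(size=3)
            axes[pep] = v / np.linalg.norm(v)
            angles[pep] = rng.uniform(lo, hi)
        drawn["axes"], drawn["angles"] = axes, angles
        # amorphous compaction also melts the strands internally
        sigma = event.params.get("dihedral_sigma", 20.0)
        n_res = frame0.topology.n_residues
        drawn["dihedral_deltas"] = {
            pep: _dihedral_draw(rng, sigma, n_res) for pep in event.peptides
        }
    return drawn


def _apply_event(
    coords: np.ndarray,
    frame0: Frame,
    event: ScheduledEvent,
    s: float,
    drawn: dict,
) -> np.ndarray:
    if s == 0.0:
        return coords
    top = frame0.topology
    p = event.params

    if event.type == "progressive_twist":
        target = p.get("twist_per_pair", 10.0)
        centroids = np.array([frame0.coords[top.select(peptide=q)].mean(axis=0) for q in top.peptides])
        axis_point = np.array([centroids[:, 0].mean(), centroids[:, 1].mean(), 0.0])
        order = {q: k for k, q in enumerate(top.peptides)}
        for q in event.peptides:
            mask = top.select(peptide=q)
            coords[mask] = _rotate_about(coords[mask], [0, 0, 1], order[q] * target * s, axis_point)

    elif event.type == "end_fray":
        residues = tuple(p.get("residues", (1,)))
        angle = p.get("angle", 70.0)
        boundary = max(residues) + 1 if min(residues) == 1 else min(residues) - 1
        order = {q: k for k, q in enumerate(top.peptides)}
        for q in event.peptides:
            pivot = frame0.coords[top.index_of(q, boundary, "CA")]
            mask = top.select(peptide=q, residue=list(residues))
            # swing the frayed residues laterally (about the stacking axis,
            # perpendicular to their offset from the pivot), alternating the
            # direction so fraying is incoherent across strands and actually
            # breaks the terminal H-bond ladder
            sign = 1.0 if order[q] % 2 == 0 else -1.0
            coords[mask] = _rotate_about(coords[mask], [0, 0, 1], sign * angle * s, pivot)

    elif event.type == "disorder":
        for q in event.peptides:
            coords = _apply_disorder(coords, frame0, q, drawn["dihedral_deltas"][q] * s)

    elif event.type == "dissociation":
        direction = np.asarray(p.get("direction", (0.0, 0.0, 1.0)), dtype=float)
        direction = direction / np.linalg.norm(direction)
        dist = p.get("distance", 2.0)
        mask = top.select(peptide=event.peptides[0])
        coords[mask] = coords[mask] + direction * dist * s

    elif event.type == "rearrangement":
        q = event.peptides[0]
        angle = p.get("angle", 180.0)
        mask = top.select(peptide=q)
        center = coords[mask].mean(axis=0)
        coords[mask] = _rotate_about(coords[mask], p.get("axis", (0, 0, 1)), angle * s, center)

    elif event.type == "disintegration":
        partition = p["partition"]
        translations = p.get("translations")
        if translations is None:
            translations = [np.array([0.0, 0.0, 0.0])]
            for b in range(1, len(partition)):
                sign = 1.0 if b % 2 == 1 else -1.0
                translations.append(np.array([0.0, 0.0, sign * 2.0 * b]))
        for block, tvec in zip(partition, translations):
            mask = top.select(peptide=list(block))
            coords[mask] = coords[mask] + np.asarray(tvec, dtype=float) * s

    elif event.type == "collapse":
        factor = p.get("contraction", 0.7)
        masses = top.masses
        sel_all = top.select(peptide=list(event.peptides))
        agg_com = (coords[sel_all] * masses[sel_all, None]).sum(axis=0) / masses[sel_all].sum()
        for q in event.peptides:
            coords = _apply_disorder(coords, frame0, q, drawn["dihedral_deltas"][q] * s)
            mask = top.select(peptide=q)
            m = masses[mask]
            com = (coords[mask] * m[:, None]).sum(axis=0) / m.sum()
            new_com = agg_com + (com - agg_com) * (1.0 - (1.0 - factor) * s)
            rot = rotation_matrix(drawn["axes"][q], drawn["angles"][q] * s)
            coords[mask] = (coords[mask] - com) @ rot.T + new_com

    return coords


def _apply_disorder(coords: np.ndarray, frame0: Frame, peptide: str, deltas: np.ndarray) -> np.ndarray:
    """Backbone φ/ψ perturbation of one peptide, centre of mass preserved."""
    top = frame0.topology
    pep_mask = top.select(peptide=peptide)
    masses = top.masses[pep_mask]
    com_before = (coords[pep_mask] * masses[:, None]).sum(axis=0) / masses.sum()

    pep_idx = np.nonzero(pep_mask)[0]
    res_of = top.residue_index[pep_idx]
    names = top.atom_names[pep_idx]
    local = coords[pep_idx].copy()

    def li(res, name):
        hit = np.nonzero((res_of == res) & (names == name))[0]
        return int(hit[0])

    n_res = top.n_residues
    for r in range(1, n_res + 1):
        dphi, dpsi = deltas[r - 1]
        n_xyz, ca_xyz = local[li(r, "N")], local[li(r, "CA")]
        # φ: rotate C/O of r and everything downstream about N→CA
        moving = ((res_of > r) | ((res_of == r) & np.isin(names, ["C", "O", "OXT"])))
        local[moving] = _rotate_about(local[moving], ca_xyz - n_xyz, dphi, ca_xyz)
        # ψ: rotate O of r and residues beyond about CA→C
        c_xyz = local[li(r, "C")]
        moving = ((res_of > r) | ((res_of == r) & np.isin(names, ["O", "OXT"])))
        local[moving] = _rotate_about(local[moving], c_xyz - local[li(r, "CA")], dpsi, c_xyz)

    com_after = (local * masses[:, None]).sum(axis=0) / masses.sum()
    local += com_before - com_after
    coords[pep_idx] = local
    return coords


# ---------------------------------------------------------------------------
# generation


def _check_conflicts(script: ScenarioScript) -> None:
    evs = script.events
    for a in range(len(evs)):
        for b in range(a + 1, len(evs)):
            ea, eb = evs[a], evs[b]
            if ea.start_frame < eb.end_frame and eb.start_frame < ea.end_frame:
                shared = set(ea.peptides) & set(eb.peptides)
                if shared:
                    raise ScriptConflictError(
                        f"events {ea.type} and {eb.type} overlap on peptides {sorted(shared)}"
                    )


def generate_trajectory(frame0: Frame, script: ScenarioScript) -> Trajectory:
    """Realise a scenario script as a trajectory.

    Frame t applies every event at its interpolation parameter s(t) to a
    copy of ``frame0`` (events compose in script order and persist after
    their window), then adds rigid-body-filtered Gaussian noise. The output
    is fully determined by (frame0, script, script.seed).
    """
    top = frame0.topology
    known = set(top.peptides)
    for e in script.events:
        missing = set(e.peptides) - known
        if missing:
            raise ValueError(f"event {e.type} names unknown peptides {sorted(missing)}")
        if e.type == "disintegration":
            flat = [q for b in e.params["partition"] for q in b]
            if sorted(flat) != sorted(set(flat)) or set(flat) - known:
                raise ValueError("disintegration partition must be disjoint known peptides")
    _check_conflicts(script)

    rng = np.random.default_rng([script.seed & 0x7FFFFFFF, 0xC0FFEE])
    drawn = [_materialise(e, frame0, np.random.default_rng([script.seed & 0x7FFFFFFF, i + 1]))
             for i, e in enumerate(script.events)]

    masses = top.masses
    pep_masks = {q: top.select(peptide=q) for q in top.peptides}

    frames = np.empty((script.n_frames, top.n_atoms, 3))
    for t in range(script.n_frames):
        coords = frame0.coords.copy()
        for e, dr in zip(script.events, drawn):
            coords = _apply_event(coords, frame0, e, e.scale(t), dr)
        if script.noise_sigma > 0:
            eps = rng.normal(0.0, script.noise_sigma, size=coords.shape)
            for q, mask in pep_masks.items():
                m = masses[mask]
                eps[mask] -= (eps[mask] * m[:, None]).sum(axis=0) / m.sum()
            coords = coords + eps
        frames[t] = coords

    times = np.arange(script.n_frames) * script.frame_dt
    prov = {"seed": script.seed, "noise_sigma": script.noise_sigma,
            "events": [(e.type, e.peptides, e.start_frame, e.end_frame) for e in script.events]}
    return Trajectory(top, frames, times, prov)


def expected_split_frame(frame0: Frame, event: ScheduledEvent,
                         config: AnalysisConfig = DEFAULT_CONFIG) -> int:
    """First frame at which a scripted dissociation/disintegration separates
    the moving group beyond the contact cutoff (zero-noise arithmetic).

    Backbone hydrogen bonds break well before the contact cutoff is
    exceeded, so contact distance is the binding criterion. The frame is
    found by evaluating the scripted displacement on the actual geometry.
    """
    top = frame0.topology
    if event.type == "dissociation":
        moving = list(event.peptides)
        direction = np.asarray(event.params.get("direction", (0.0, 0.0, 1.0)), dtype=float)
        direction = direction / np.linalg.norm(direction)
        shift = direction * event.params.get("distance", 2.0)
    elif event.type == "disintegration":
        moving = list(event.params["partition"][1])
        translations = event.params.get("translations")
        shift = np.asarray(translations[1], dtype=float) if translations is not None \
            else np.array([0.0, 0.0, 2.0])
    else:
        raise ValueError("expected_split_frame applies to dissociation/disintegration")
    rest = [q for q in top.peptides if q not in moving]
    mv = frame0.coords[top.select(peptide=moving)]
    rs = frame0.coords[top.select(peptide=rest)]
    for t in range(event.start_frame, event.end_frame + 1):
        if cdist(mv + shift * event.scale(t), rs).min() > config.contact_distance:
            return t
    raise ValueError("scripted displacement never exceeds the contact cutoff")


# ---------------------------------------------------------------------------
# presets


def preset_scenarios(
    n_peptides: int = 6,
    noise_sigma: float = 0.01,
    seed: int = 0,
    n_frames: int = 100,
    frame_dt: float = 0.5,
) -> dict[str, ScenarioScript]:
    """Named scenario scripts covering the event taxonomy.

    Each script carries the verdict and key event its construction forces,
    for use by scenario-recovery experiments.
    """
    if n_peptides < 4:
        raise ValueError("presets assume at least 4 peptides")
    letters = [chr(ord("A") + k) for k in range(n_peptides)]
    common = dict(n_frames=n_frames, frame_dt=frame_dt, noise_sigma=noise_sigma, seed=seed)

    scenarios = {
        "stable_twisted": ScenarioScript(
            events=(
                ScheduledEvent("progressive_twist", tuple(letters), 10, 60,
                               {"twist_per_pair": 10.0}),
            ),
            expected_verdict="stable",
            expected_key_event=None,
            **common,
        ),
        "end_fraying": ScenarioScript(
            events=(
                ScheduledEvent("end_fray", tuple(letters), 20, 50,
                               {"residues": (1,), "angle": 70.0}),
            ),
            expected_verdict="stable",
            expected_key_event=None,
            **common,
        ),
        "edge_dissociation": ScenarioScript(
            events=(
                ScheduledEvent("dissociation", (letters[-1],), 40, 60,
                               {"direction": (0.0, 0.0, 1.0), "distance": 2.0}),
            ),
            expected_verdict="unstable",
            expected_key_event="dissociation",
            **common,
        ),
        "disintegration_4_2": ScenarioScript(
            events=(
                ScheduledEvent(
                    "disintegration", tuple(letters), 50, 52,
                    {"partition": (tuple(letters[:-2]), tuple(letters[-2:])),
                     "translations": [np.zeros(3), np.array([0.0, 0.0, 2.0])]},
                ),
            ),
            expected_verdict="unstable",
            expected_key_event="disintegration",
            **common,
        ),
        "antiparallel_rearrangement": ScenarioScript(
            events=(
                ScheduledEvent("rearrangement", (letters[1], letters[2]), 30, 55,
                               {"angle": 180.0, "axis": (0, 0, 1)}),
            ),
            expected_verdict="unstable",
            expected_key_event="rearrangement",
            **common,
        ),
        "collapse_amorphous": ScenarioScript(
            events=(
                ScheduledEvent("collapse", tuple(letters), 30, 42,
                               {"contraction": 0.55, "dihedral_sigma": 45.0,
                                "rotation_range": (90.0, 180.0)}),
            ),
            expected_verdict="unstable",
            expected_key_event="collapse",
            **common,
        ),
        "disorder_edge": ScenarioScript(
            events=(
                ScheduledEvent("disorder", (letters[-1],), 25, 45,
                               {"dihedral_sigma": 60.0}),
            ),
            expected_verdict="unstable",
            expected_key_event="disorder",
            **common,
        ),
    }
    return scenarios
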