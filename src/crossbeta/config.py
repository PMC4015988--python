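"""Analysis configuration: every numeric cutoff in one serialisable place.

Defaults reproduce the printed criteria of the study design where a value
is printed (ring-plane stacking < 0.5 nm, ΔRg stability gate 0.1 nm); the
remaining cutoffs are documented conventions (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class AnalysisConfig:
    # printed criteria
    stacking_distance: float = 0.5  # nm, Tyr ring-plane distance for stacking
    delta_rg_threshold: float = 0.1  # nm, stability gate on |ΔRg|

    # hydrogen-bond criterion (donor/acceptor heavy atoms; no hydrogens)
    hbond_distance: float = 0.35  # nm
    hbond_angle: float = 90.0  # degrees, antecedent-donor-acceptor minimum

    # peptide connectivity
    contact_distance: float = 0.45  # nm, min heavy-atom distance
    cluster_min_bb_hbonds: int = 2

    # pair orientation classes from the twist angle
    parallel_max_twist: float = 50.0  # degrees
    antiparallel_min_twist: float = 130.0  # degrees

    # event detection
    persistence_frames: int = 5
    window_fraction: float = 0.05  # ΔRg edge-window fraction of frames
    collapse_sheet_fraction: float = 0.5  # of initial mean sheet content
    disorder_min_sheet_residues: int = 2
    # internal (superposed) backbone deformation separating a disordered
    # peptide from an intact strand that merely moved
    internal_rmsd_threshold: float = 0.1  # nm

    # build/generation defaults
    inter_strand_spacing: float = 0.48  # nm
    noise_sigma: float = 0.01  # nm
    frame_dt: float = 0.5  # ns
    n_frames: int = 100
    seed: int = 0

    # ring-plane distance construction: 'plane' (centroid-to-plane) or 'centroid'
    ring_distance_mode: str = "plane"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def digest(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


DEFAULT_CONFIG = AnalysisConfig()
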