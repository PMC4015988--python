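"""Event detection, stability verdicts, oligomer census."""

import numpy as np
import pytest

from crossbeta.builder import AggregateSpec, PeptideSpec, apply_rigid_transform, build_sheet
from crossbeta.config import AnalysisConfig
from crossbeta.core import Trajectory
from crossbeta.events import (
    TrajectoryAnalysis,
    cluster_peptides,
    detect_events,
    oligomer_census,
    pair_orientation,
    stability_verdict,
)
from crossbeta.geometry import rotation_matrix
from crossbeta.observables import radius_of_gyration
from crossbeta.synthgen import (
    ScenarioScript,
    ScheduledEvent,
    expected_split_frame,
    generate_trajectory,
    preset_scenarios,
)


def run(frame0, script):
    traj = generate_trajectory(frame0, script)
    an = TrajectoryAnalysis(traj)
    events = detect_events(traj, analysis=an)
    verdict = stability_verdict(traj, analysis=an, events=events)
    return traj, an, events, verdict


class TestClustering:
    def test_intact_sheet_is_one_cluster(self, wt_sheet6):
        parts = cluster_peptides(wt_sheet6)
        assert parts == [frozenset("ABCDEF")]

    def test_partition_is_disjoint_and_exhaustive(self, wt_sheet6):
        f = apply_rigid_transform(wt_sheet6, "F", translation=np.array([0, 0, 2.0]))
        parts = cluster_peptides(f)
        union = set().union(*parts)
        assert union == set("ABCDEF")
        assert sum(len(c) for c in parts) == 6
        assert sorted(len(c) for c in parts) == [1, 5]


class TestPairOrientation:
    def test_planar_build_is_parallel(self, wt_sheet6):
        assert pair_orientation(wt_sheet6, "A", "B") == "parallel"

    @pytest.mark.parametrize("angle,expected", [
        (40.0, "parallel"), (90.0, "crossed"), (135.0, "antiparallel"), (180.0, "antiparallel"),
    ])
    def test_twist_thresholds(self, wt_sheet6, angle, expected):
        # rotate B about an axis perpendicular to its strand vector
        f = apply_rigid_transform(wt_sheet6, "B", rotation=rotation_matrix([0, 0, 1], angle))
        assert pair_orientation(f, "A", "B") == expected


class TestDetectEvents:
    def test_stable_preset_has_no_events(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.0)["stable_twisted"]
        _, _, events, verdict = run(wt_sheet6, script)
        assert events == []
        assert verdict.verdict == "stable"

    def test_dissociation_onset_near_script(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.0)["edge_dissociation"]
        _, _, events, verdict = run(wt_sheet6, script)
        assert verdict.key_event == "dissociation"
        ons = [e.onset_frame for e in events if e.type == "dissociation"]
        split = expected_split_frame(wt_sheet6, script.events[0])
        assert any(abs(o - split) <= 1 for o in ons)

    def test_rearrangement_names_the_scripted_pair(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.0)["antiparallel_rearrangement"]
        _, _, events, verdict = run(wt_sheet6, script)
        assert verdict.key_event == "rearrangement"
        named = {p for e in events if e.type == "rearrangement" for p in e.peptides}
        assert "B" in named

    def test_collapse_preset(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.0, seed=1)["collapse_amorphous"]
        _, _, events, verdict = run(wt_sheet6, script)
        assert verdict.verdict == "unstable"
        assert verdict.key_event == "collapse"

    def test_disintegration_increases_cluster_count(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.0)["disintegration_4_2"]
        traj, an, events, verdict = run(wt_sheet6, script)
        assert verdict.key_event == "disintegration"
        (rec,) = [e for e in events if e.type == "disintegration"]
        assert len(an.clusters[rec.onset_frame]) > len(an.clusters[rec.onset_frame - 1])

    def test_disorder_preset(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.01, seed=0)["disorder_edge"]
        _, _, events, verdict = run(wt_sheet6, script)
        assert verdict.verdict == "unstable"
        assert verdict.key_event == "disorder"
        (rec,) = [e for e in events if e.type == "disorder"]
        assert rec.peptides == ("F",)

    def test_label_determinism(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.01, seed=5)["edge_dissociation"]
        traj = generate_trajectory(wt_sheet6, script)
        assert detect_events(traj) == detect_events(traj)


class TestVerdictBoundary:
    def _two_frame_traj(self, frame, rg_delta):
        """Uniformly scale the aggregate so ΔRg is exactly rg_delta."""
        rg0 = radius_of_gyration(frame)
        k = (rg0 + rg_delta) / rg0
        com = frame.com()
        second = com + (frame.coords - com) * k
        coords = np.stack([frame.coords, second])
        return Trajectory(frame.topology, coords, np.array([0.0, 0.5]))

    @pytest.mark.parametrize("delta,expected", [
        (0.0999, "stable"), (0.1, "unstable"), (-0.1, "unstable"), (-0.0999, "stable"),
    ])
    def test_delta_rg_gate_is_strict(self, wt_sheet6, delta, expected):
        traj = self._two_frame_traj(wt_sheet6, delta)
        v = stability_verdict(traj)
        assert abs(abs(v.delta_rg) - abs(delta)) < 1e-9
        assert v.verdict == expected


class TestCensus:
    def test_stable_sheet_single_record(self, wt_sheet6):
        traj = generate_trajectory(wt_sheet6, ScenarioScript(n_frames=20, noise_sigma=0.0))
        recs = oligomer_census(traj)
        assert len(recs) == 1
        (r,) = recs
        assert r.size == 6 and r.birth_frame == 0 and r.death_frame == 20
        assert r.lifetime == pytest.approx(20 * 0.5)
        assert r.ordered

    def test_disintegration_42_sizes_and_lifetimes(self, wt_sheet6):
        script = preset_scenarios(6, noise_sigma=0.0)["disintegration_4_2"]
        traj = generate_trajectory(wt_sheet6, script)
        recs = oligomer_census(traj)
        split = expected_split_frame(wt_sheet6, script.events[0])
        by_size = {r.size: r for r in recs}
        assert set(by_size) == {6, 4, 2}
        dt = 0.5
        assert by_size[6].lifetime == pytest.approx(split * dt)
        assert by_size[4].birth_frame == split
        assert by_size[4].lifetime == pytest.approx((script.n_frames - split) * dt)
        assert by_size[2].lifetime == pytest.approx((script.n_frames - split) * dt)

    def test_sequential_dissociations_yield_decreasing_sizes(self):
        sheet = build_sheet(PeptideSpec("GNNQQNY", "neutral"), AggregateSpec(5))
        evs = (
            ScheduledEvent("dissociation", ("E",), 20, 25, {"distance": 2.0}),
            ScheduledEvent("dissociation", ("A",), 50, 55,
                           {"direction": (0.0, 0.0, -1.0), "distance": 2.0}),
        )
        traj = generate_trajectory(sheet, ScenarioScript(n_frames=80, noise_sigma=0.0, events=evs))
        recs = oligomer_census(traj)
        sizes = [r.size for r in sorted(recs, key=lambda r: r.birth_frame)]
        assert sizes == [5, 4, 3]
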