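"""Geometric observables: Rg, twist, registry, stacking, H-bonds, sheet."""

import numpy as np
import pytest

from crossbeta.builder import AggregateSpec, PeptideSpec, build_sheet
from crossbeta.config import AnalysisConfig
from crossbeta.core import Frame, Topology, Trajectory
from crossbeta.geometry import rotation_matrix
from crossbeta.observables import (
    assign_sheet,
    delta_rg,
    detect_hbonds,
    classify_edge,
    pair_twist,
    radius_of_gyration,
    registry_distances,
    residue_profiles,
    sheet_content,
    tyr_ring_distance,
)
from crossbeta.synthgen import ScenarioScript, ScheduledEvent, generate_trajectory

from .oracles import brute_force_hbonds, brute_force_rg


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self, wt_sheet6):
        mask = np.zeros(wt_sheet6.topology.n_atoms, dtype=bool)
        mask[0] = True
        assert radius_of_gyration(wt_sheet6, mask) == 0.0

    def test_two_equal_mass_atoms(self, wt_sheet6):
        top = wt_sheet6.topology
        cas = np.nonzero(top.atom_names == "CA")[0][:2]
        f = wt_sheet6.copy()
        f.coords[cas[0]] = [0.0, 0.0, 0.0]
        f.coords[cas[1]] = [0.2, 0.0, 0.0]
        mask = np.zeros(top.n_atoms, dtype=bool)
        mask[cas] = True
        assert radius_of_gyration(f, mask) == pytest.approx(0.1, abs=1e-12)

    def test_matches_direct_sum_oracle(self, wt_sheet6, rng):
        for _ in range(10):
            f = wt_sheet6.copy()
            f.coords += rng.normal(0, 0.3, size=f.coords.shape)
            assert radius_of_gyration(f) == pytest.approx(brute_force_rg(f, np.ones(f.topology.n_atoms, bool)), abs=1e-12)

    def test_rigid_motion_invariance(self, wt_sheet6, rng):
        base = radius_of_gyration(wt_sheet6)
        f = wt_sheet6.copy()
        R = rotation_matrix(rng.normal(size=3), 77.0)
        f.coords = f.coords @ R.T + np.array([1.0, -2.0, 3.0])
        assert radius_of_gyration(f) == pytest.approx(base, abs=1e-12)

    def test_empty_selection_raises(self, wt_sheet6):
        with pytest.raises(ValueError):
            radius_of_gyration(wt_sheet6, np.zeros(wt_sheet6.topology.n_atoms, bool))


class TestDeltaRg:
    def test_constant_trajectory_is_zero(self, wt_sheet6):
        traj = generate_trajectory(wt_sheet6, ScenarioScript(n_frames=20, noise_sigma=0.0))
        assert delta_rg(traj) == 0.0

    def test_dissociation_exceeds_gate(self, wt_sheet6):
        ev = ScheduledEvent("dissociation", ("F",), 5, 10, {"distance": 2.0})
        traj = generate_trajectory(wt_sheet6, ScenarioScript(n_frames=20, noise_sigma=0.0, events=(ev,)))
        assert delta_rg(traj) > 0.1
        # agrees with direct end-frame computation at window fraction 0
        cfg = AnalysisConfig(window_fraction=0.0)
        direct = radius_of_gyration(traj.frame(19)) - radius_of_gyration(traj.frame(0))
        assert delta_rg(traj, cfg) == pytest.approx(direct, abs=1e-12)

    def test_collapse_decreases_rg(self, wt_sheet6):
        ev = ScheduledEvent("collapse", tuple("ABCDEF"), 2, 10, {"contraction": 0.7})
        traj = generate_trajectory(wt_sheet6, ScenarioScript(n_frames=20, noise_sigma=0.0, events=(ev,), seed=5))
        assert delta_rg(traj) < 0.0


class TestPairTwist:
    def test_symmetry_and_range(self, wt_sheet6):
        assert pair_twist(wt_sheet6, "A", "C") == pair_twist(wt_sheet6, "C", "A")

    def test_global_rigid_motion_invariance(self, wt_sheet6, rng):
        sheet = build_sheet(PeptideSpec("GNNQQNY", "neutral"),
                            AggregateSpec(4, inter_strand_spacing=0.6, per_pair_twist=15.0))
        f = sheet.copy()
        R = rotation_matrix(rng.normal(size=3), 123.0)
        f.coords = f.coords @ R.T + rng.normal(size=3)
        for i, j in [("A", "B"), ("A", "D")]:
            assert pair_twist(f, i, j) == pytest.approx(pair_twist(sheet, i, j), abs=1e-9)

    def test_reversal_gives_180(self, wt_sheet6):
        f = wt_sheet6.copy()
        top = f.topology
        mask = top.select(peptide="B")
        center = f.coords[mask].mean(axis=0)
        f.coords[mask] = (f.coords[mask] - center) @ rotation_matrix([0, 0, 1], 180.0).T + center
        assert pair_twist(f, "A", "B") == pytest.approx(180.0, abs=1e-6)


class TestRegistry:
    def test_self_pair_is_zero(self, wt_sheet6):
        assert np.allclose(registry_distances(wt_sheet6, "B", "B"), 0.0)


class TestTyrStacking:
    def _two_rings(self, z_offset):
        """Two ideal coplanar hexagons in the xy plane, z apart."""
        ang = np.radians(np.arange(6) * 60.0)
        ring = np.stack([0.14 * np.cos(ang), 0.14 * np.sin(ang), np.zeros(6)], axis=1)
        coords = np.vstack([ring, ring + [0.02, 0.0, z_offset]])
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"] * 2
        top = Topology(
            peptide_ids=np.array(["A"] * 6 + ["B"] * 6),
            residue_index=np.array([7] * 12),
            residue_names=np.array(["TYR"] * 12),
            atom_names=np.array(names),
            elements=np.array(["C"] * 12),
            backbone=np.zeros(12, bool),
            is_donor=np.zeros(12, bool),
            is_acceptor=np.zeros(12, bool),
            antecedent=np.full(12, -1),
        )
        return Frame(top, coords)

    def test_coplanar_rings_have_zero_distance(self):
        f = self._two_rings(0.0)
        assert tyr_ring_distance(f, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_parallel_offset_equals_projection(self, config):
        f = self._two_rings(0.4)
        d = tyr_ring_distance(f, "A", "B")
        assert d == pytest.approx(0.4, abs=1e-12)
        assert d < config.stacking_distance  # stacked

    @pytest.mark.parametrize("z,stacked", [(0.6, False), (0.5, False), (0.499, True)])
    def test_stacking_criterion_boundary(self, z, stacked, config):
        d = tyr_ring_distance(self._two_rings(z), "A", "B")
        assert (d < config.stacking_distance) is stacked

    def test_built_sheet_tyr_rings_are_stacked(self, wt_sheet6, config):
        d = tyr_ring_distance(wt_sheet6, "B", "C")
        assert d < config.stacking_distance


class TestHBonds:
    @pytest.mark.parametrize("seq,termini,n", [
        ("GNNQQNY", "charged", 5),
        ("GNNQQNY", "neutral", 6),
        ("GSNQQNY", "neutral", 7),
        ("GNNQQDY", "neutral", 8),
    ])
    def test_matches_brute_force_oracle(self, seq, termini, n, config):
        sheet = build_sheet(PeptideSpec(seq, termini), AggregateSpec(n))
        ours = {(b.donor, b.acceptor) for b in detect_hbonds(sheet, config)}
        assert ours == brute_force_hbonds(sheet, config)

    def test_distance_cutoff(self, wt_sheet6, config):
        bonds = detect_hbonds(wt_sheet6, config)
        assert all(b.distance <= config.hbond_distance for b in bonds)
        assert all(b.angle >= config.hbond_angle for b in bonds)

    def test_interior_pairs_have_at_least_four_backbone_bonds(self, wt_sheet6):
        bonds = detect_hbonds(wt_sheet6)
        peps = wt_sheet6.topology.peptides
        for i, j in zip(peps[:-1], peps[1:]):
            n_bb = sum(
                1 for b in bonds
                if {b.donor_peptide, b.acceptor_peptide} == {i, j}
                and b.hb_class == "backbone-backbone"
            )
            assert n_bb >= 4

    def test_ser_forms_fewer_sidechain_ladder_bonds_than_asn(self):
        def pos2_ladder(seq):
            sheet = build_sheet(PeptideSpec(seq, "neutral"), AggregateSpec(6))
            return sum(
                1 for b in detect_hbonds(sheet)
                if b.inter_peptide and b.hb_class == "sidechain-sidechain"
                and b.donor_residue == 2 and b.acceptor_residue == 2
            )
        assert pos2_ladder("GSNQQNY") < pos2_ladder("GNNQQNY")


class TestSheetAssignment:
    def test_interior_residues_of_interior_peptides_are_sheet(self, wt_sheet6):
        states = assign_sheet(wt_sheet6)
        for p in ("B", "C", "D", "E"):
            assert np.all(states[p][1:6] == "E")

    def test_isolated_strand_is_coil(self):
        from crossbeta.builder import build_strand
        strand = build_strand(PeptideSpec("GNNQQNY", "charged"))
        assert np.all(assign_sheet(strand)["A"] == "C")

    def test_end_fray_drops_residue1_sheet_frequency(self, wt_sheet6):
        ev = ScheduledEvent("end_fray", tuple("ABCDEF"), 2, 5, {"residues": (1,), "angle": 70.0})
        traj = generate_trajectory(wt_sheet6, ScenarioScript(n_frames=10, noise_sigma=0.0, events=(ev,)))
        prof = residue_profiles(traj, exclude_edges=True)
        assert prof.sheet_frequency[0] < 0.5
        assert np.all(prof.sheet_frequency[1:6] > 0.8)


class TestResidueProfiles:
    def test_constant_trajectory_equals_single_frame(self, wt_sheet6):
        traj = generate_trajectory(wt_sheet6, ScenarioScript(n_frames=5, noise_sigma=0.0))
        prof = residue_profiles(traj, exclude_edges=True)
        sc0 = sheet_content(wt_sheet6)
        interior_mean = np.mean([sc0[p] for p in prof.peptides_used])
        assert prof.sheet_frequency.sum() * 1.0 == pytest.approx(interior_mean, abs=1e-12)

    def test_asp6_sidechain_bonds_not_more_than_asn6(self):
        def profile(seq):
            sheet = build_sheet(PeptideSpec(seq, "neutral"), AggregateSpec(6))
            traj = generate_trajectory(sheet, ScenarioScript(n_frames=2, noise_sigma=0.0))
            return residue_profiles(traj, exclude_edges=True)
        assert profile("GNNQQDY").sc_hbonds[5] <= profile("GNNQQNY").sc_hbonds[5]

    def test_two_peptide_system_has_no_interior(self):
        sheet = build_sheet(PeptideSpec("GNNQQNY", "neutral"), AggregateSpec(2))
        traj = generate_trajectory(sheet, ScenarioScript(n_frames=2, noise_sigma=0.0))
        with pytest.raises(ValueError):
            residue_profiles(traj, exclude_edges=True)


class TestEdgeClassification:
    def test_interior_peptide(self, wt_sheet6):
        assert classify_edge(wt_sheet6, "C") == "interior"

    def test_edges_get_opposite_labels(self, wt_sheet6):
        labels = {classify_edge(wt_sheet6, "A"), classify_edge(wt_sheet6, "F")}
        assert labels == {"N-edge", "C-edge"}

    def test_detached_peptide(self, wt_sheet6):
        from crossbeta.builder import apply_rigid_transform
        f = apply_rigid_transform(wt_sheet6, "F", translation=np.array([0.0, 0.0, 3.0]))
        assert classify_edge(f, "F") == "detached"
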