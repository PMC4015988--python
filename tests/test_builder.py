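"""Sheet builder: mutation labels, strand geometry, stacking, transforms."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from crossbeta.builder import (
    AggregateSpec,
    BuildClashError,
    InvalidSpecError,
    PeptideSpec,
    apply_rigid_transform,
    build_sheet,
    build_strand,
    mutate_sequence,
)
from crossbeta.events import pair_orientation
from crossbeta.geometry import rotation_matrix
from crossbeta.observables import pair_twist, radius_of_gyration, registry_distances


class TestMutateSequence:
    @pytest.mark.parametrize(
        "label,expected",
        [("N2D", "GDNQQNY"), ("N2S", "GSNQQNY"), ("N6D", "GNNQQDY"), ("N2N", "GNNQQNY")],
    )
    def test_point_mutations(self, label, expected):
        assert mutate_sequence("GNNQQNY", label) == expected

    def test_inconsistent_label_rejected(self):
        with pytest.raises(InvalidSpecError):
            mutate_sequence("GNNQQNY", "Q2D")  # position 2 is N, not Q


class TestStrand:
    def test_consecutive_ca_distances(self):
        f = build_strand(PeptideSpec("GNNQQNY", "charged"))
        ca = f.coords[f.topology.select(atom="CA")]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 0.38) < 0.01)

    def test_charged_cterm_has_oxt_acceptor(self):
        f = build_strand(PeptideSpec("GNNQQNY", "charged"))
        top = f.topology
        i = top.index_of("A", 7, "OXT")
        assert top.is_acceptor[i] and not top.is_donor[i]

    def test_neutral_cterm_is_donor(self):
        top = build_strand(PeptideSpec("GNNQQNY", "neutral")).topology
        i = top.index_of("A", 7, "OXT")
        assert top.is_donor[i]

    def test_ser_og_is_donor_and_acceptor(self):
        top = build_strand(PeptideSpec("GSNQQNY", "neutral")).topology
        i = top.index_of("A", 2, "OG")
        assert top.is_donor[i] and top.is_acceptor[i]

    def test_unknown_residue_rejected(self):
        with pytest.raises(InvalidSpecError):
            PeptideSpec("GXNQQNY", "charged")


class TestSheet:
    def test_deterministic(self):
        a = build_sheet(PeptideSpec("GNNQQNY", "neutral"), AggregateSpec(6))
        b = build_sheet(PeptideSpec("GNNQQNY", "neutral"), AggregateSpec(6))
        assert np.array_equal(a.coords, b.coords)

    def test_planar_build_has_zero_twist(self, wt_sheet6):
        peps = wt_sheet6.topology.peptides
        for i, j in zip(peps[:-1], peps[1:]):
            assert pair_twist(wt_sheet6, i, j) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [5.0, 15.0])
    def test_imposed_twist_measured_exactly(self, theta):
        sheet = build_sheet(
            PeptideSpec("GNNQQNY", "neutral"),
            AggregateSpec(4, inter_strand_spacing=0.6, per_pair_twist=theta),
        )
        for i, j in [("A", "B"), ("B", "C"), ("C", "D")]:
            assert pair_twist(sheet, i, j) == pytest.approx(theta, abs=1e-6)
        # twist composes over non-adjacent pairs
        assert pair_twist(sheet, "A", "C") == pytest.approx(2 * theta, abs=1e-6)

    def test_in_register_registry_equals_spacing(self, wt_sheet6):
        d = registry_distances(wt_sheet6, "A", "B")
        assert np.allclose(d, 0.48, atol=1e-9)

    def test_peptide_ids_consecutive_letters(self, wt_sheet6):
        assert wt_sheet6.topology.peptides == ["A", "B", "C", "D", "E", "F"]

    def test_steric_clash_detected(self):
        with pytest.raises(BuildClashError) as err:
            build_sheet(PeptideSpec("GNNQQNY", "neutral"),
                        AggregateSpec(5, inter_strand_spacing=0.05))
        assert err.value.pair  # names the offending pair

    def test_register_offset_increases_registry_distances(self):
        sheet = build_sheet(PeptideSpec("GNNQQNY", "neutral"),
                            AggregateSpec(3, register_offset=1))
        d = registry_distances(sheet, "A", "B")
        assert np.all(d > 0.48)


class TestRigidTransform:
    def test_identity_is_bitwise_equal(self, wt_sheet6):
        out = apply_rigid_transform(wt_sheet6, "B", rotation=np.eye(3))
        assert np.array_equal(out.coords, wt_sheet6.coords)

    def test_translation_preserves_rg(self, wt_sheet6):
        mask = wt_sheet6.topology.select(peptide="C")
        before = radius_of_gyration(wt_sheet6, mask)
        out = apply_rigid_transform(wt_sheet6, "C", translation=np.array([1.0, -2.0, 0.5]))
        assert radius_of_gyration(out, mask) == pytest.approx(before, abs=1e-12)
        # others untouched
        other = wt_sheet6.topology.select(peptide="A")
        assert np.array_equal(out.coords[other], wt_sheet6.coords[other])

    def test_internal_distances_preserved(self, wt_sheet6, rng):
        axis = rng.normal(size=3)
        R = rotation_matrix(axis, 37.0)
        out = apply_rigid_transform(wt_sheet6, "B", rotation=R, translation=np.array([0.3, 0, 0]))
        mask = wt_sheet6.topology.select(peptide="B")
        d0 = cdist(wt_sheet6.coords[mask], wt_sheet6.coords[mask])
        d1 = cdist(out.coords[mask], out.coords[mask])
        assert np.abs(d0 - d1).max() < 1e-9

    def test_180_flip_gives_antiparallel_pair(self, wt_sheet6):
        out = apply_rigid_transform(wt_sheet6, "B", rotation=rotation_matrix([0, 0, 1], 180.0))
        assert pair_orientation(out, "A", "B") == "antiparallel"
        assert pair_twist(out, "A", "B") == pytest.approx(180.0, abs=1e-6)

    def test_unknown_peptide_raises(self, wt_sheet6):
        with pytest.raises(KeyError):
            apply_rigid_transform(wt_sheet6, "Z", translation=np.zeros(3))


class TestAntiparallelBuild:
    def test_antiparallel_orientation_flag(self):
        # a rigidly flipped strand packs slightly closer than the parallel
        # ladder; use a wider spacing to stay clash-free
        sheet = build_sheet(
            PeptideSpec("GNNQQNY", "neutral"),
            AggregateSpec(3, inter_strand_spacing=0.55,
                          orientations=("parallel", "antiparallel")),
        )
        assert pair_orientation(sheet, "A", "B") == "parallel"
        assert pair_orientation(sheet, "B", "C") == "antiparallel"
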