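"""Pore-lining identification, alignment mapping and logo matrices."""

import numpy as np
import pytest

from aquadefect.pore_logo import (PoreMapping, load_packaged_mapping, logo_frequencies,
                                  map_alignment_columns, pore_lining_residues,
                                  position_of, MAX_INFO)
from aquadefect.pore_profiler import PoreAxis, ProfilerParams, compute_profile, estimate_axis
from aquadefect.synthetic import make_bundle_channel, make_toy_alignment
from aquadefect.geometry import rotation_about_axis

from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


PARAMS = ProfilerParams(seed=5)


def aln(*rows):
    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=f"s{i + 1}", description="")
         for i, s in enumerate(rows)])


class TestPackagedMapping:
    def test_has_51_positions(self):
        assert load_packaged_mapping().n_positions == 51

    @pytest.mark.parametrize("residue,position", [
        (64, 10),    # cytoplasmic-half glycine
        (180, 41),   # extracellular-half glycine
        (181, 36),   # mercury-sensitive pore cysteine
        (187, 30),   # ar/R arginine
        (71, 21), (68, 23), (168, 26),
    ])
    def test_anchor_positions(self, residue, position):
        mapping = load_packaged_mapping()
        assert position_of(mapping, residue) == position

    def test_glycine_anchors_split_by_channel_half(self):
        mapping = load_packaged_mapping()
        mid = mapping.n_positions / 2
        assert position_of(mapping, 64) < mid < position_of(mapping, 180)

    def test_not_lining_gives_none(self):
        assert position_of(load_packaged_mapping(), 9999) is None


def closest_approach_z(residue, profile):
    """Independent plain-loop reimplementation of the ordering key."""
    interior = profile.interior()
    centers = profile.centers[interior]
    radii = profile.radius[interior]
    best_gap, best_z = float("inf"), None
    for atom in residue.atoms:
        for c, r in zip(centers, radii):
            gap = abs(float(np.linalg.norm(c - atom.xyz)) - (r + atom.vdw))
            if gap < best_gap:
                best_gap = gap
                best_z = float(profile.axis.to_frame(atom.xyz)[2])
    return best_z


# symmetry-broken bundle: varied sequences so no two residues tie in z
LINING_SEQS = ["AVAIALAMAFATACASAG", "ALAFAVAIAGATAMACAS",
               "AMACALAVAFAIASATAG", "AFAIAMALACAVAGASAT",
               "ACASAFAMAIALATAVAG", "ATAGACAFALAMAVAIAS"]


@pytest.fixture(scope="module")
def bundle_profile():
    st = make_bundle_channel(6, 9.0, 18, sequences=LINING_SEQS,
                             facing_residue=(0, 9, "L"))
    axis = estimate_axis(st)
    return st, compute_profile(st, axis, PARAMS)


class TestPoreLining:
    def test_planted_facing_residue_is_lining(self, bundle_profile):
        st, profile = bundle_profile
        lining = pore_lining_residues(st, profile, margin=1.4)
        assert any(r.number == 10 for r in lining)

    def test_ordering_is_axial_and_cytoplasmic_first(self, bundle_profile):
        st, profile = bundle_profile
        lining = pore_lining_residues(st, profile, margin=1.4)
        z = [closest_approach_z(r, profile) for r in lining]
        assert all(b >= a - 1e-9 for a, b in zip(z, z[1:]))

    def test_ordering_invariant_under_rigid_transform(self, bundle_profile):
        st, profile = bundle_profile
        lining = pore_lining_residues(st, profile, margin=1.4)
        rot = rotation_about_axis([0.3, 1.0, 0.2], 63.0)
        trans = np.array([-4.0, 9.0, 2.0])
        moved = st.copy()
        moved.transform(rot, trans)
        moved_axis = PoreAxis(origin=rot @ profile.axis.origin + trans,
                              direction=rot @ profile.axis.direction,
                              z_min=profile.axis.z_min,
                              z_max=profile.axis.z_max)
        moved_profile = compute_profile(moved, moved_axis, PARAMS)
        moved_lining = pore_lining_residues(moved, moved_profile, margin=1.4)
        base_order = [r.number for r in lining]
        moved_order = [r.number for r in moved_lining]
        # the lining set is exactly invariant; the geometric ordering is
        # invariant up to permutations of near-equal heights (the profile
        # spheres themselves are only reproduced to the optimizer tolerance)
        assert set(moved_order) == set(base_order)
        rank_base = {n: i for i, n in enumerate(base_order)}
        displacement = [abs(rank_base[n] - i) for i, n in enumerate(moved_order)]
        assert np.mean(displacement) <= 1.0

    def test_tangent_atoms_included_at_zero_margin(self):
        from conftest import single_atom_structure
        angles = 2 * np.pi * np.arange(12) / 12
        coords = np.column_stack([5.0 * np.cos(angles), 5.0 * np.sin(angles),
                                  np.zeros(12)])
        st = single_atom_structure(coords, vdw=1.5)
        axis = PoreAxis(origin=np.zeros(3), direction=[0, 0, 1],
                        z_min=-0.5, z_max=0.5)
        profile = compute_profile(st, axis, ProfilerParams(step=0.5, seed=2))
        lining = pore_lining_residues(st, profile, margin=0.0)
        # every wall atom is exactly tangent to the maximal sphere
        assert len(lining) == 12

    def test_empty_profile_rejected(self, bundle_profile):
        st, profile = bundle_profile
        crippled = type(profile)(z=profile.z, radius=profile.radius,
                                 open_flag=np.ones_like(profile.open_flag),
                                 centers=profile.centers, axis=profile.axis,
                                 z0=profile.z0, step=profile.step)
        with pytest.raises(ValueError, match="interior"):
            pore_lining_residues(st, crippled)


class TestAlignmentMapping:
    def test_ungapped_identity_alignment(self, bundle6):
        lining_like = [r for r in bundle6.residues() if r.number <= 5]
        alignment = aln("A" * 20, "A" * 20)
        mapping = map_alignment_columns(lining_like, alignment, "s1")
        assert mapping.columns() == [r.number for r in lining_like]

    def test_gap_shifts_columns(self, bundle6):
        lining_like = [r for r in bundle6.residues() if r.number in (3, 4)]
        alignment = aln("AA-AAAAAAA" + "A" * 10, "AAAAAAAAAA" + "A" * 10)
        mapping = map_alignment_columns(lining_like, alignment, "s1")
        assert mapping.columns() == [4, 5]

    def test_missing_residue_error_names_it(self, bundle6):
        lining_like = [r for r in bundle6.residues() if r.number == 515]
        alignment = aln("A" * 20)
        with pytest.raises(KeyError, match="515"):
            map_alignment_columns(lining_like, alignment, "s1")

    def test_missing_reference_error(self, bundle6):
        lining_like = [r for r in bundle6.residues() if r.number <= 2]
        with pytest.raises(KeyError, match="nope"):
            map_alignment_columns(lining_like, aln("A" * 5), "nope")


class TestLogoFrequencies:
    def test_conserved_column_has_full_information(self):
        mapping = PoreMapping(positions=[(1, 1, 1)])
        alignment = aln("G", "G", "G")
        logo = logo_frequencies(alignment, mapping)
        assert logo.frequencies.loc[1, "G"] == 1.0
        assert logo.information.loc[1] == pytest.approx(MAX_INFO)

    def test_two_sequence_split_column(self):
        mapping = PoreMapping(positions=[(1, 1, 1)])
        logo = logo_frequencies(aln("G", "A"), mapping)
        assert logo.frequencies.loc[1, "G"] == 0.5
        assert logo.information.loc[1] == pytest.approx(MAX_INFO - 1.0)

    def test_gaps_excluded_from_denominator(self):
        mapping = PoreMapping(positions=[(1, 1, 1)])
        logo = logo_frequencies(aln("G", "-", "G"), mapping)
        assert logo.frequencies.loc[1, "G"] == 1.0

    def test_fully_gapped_column_flagged_undefined(self):
        mapping = PoreMapping(positions=[(1, 1, 1)])
        logo = logo_frequencies(aln("-", "-"), mapping)
        assert np.isnan(logo.information.loc[1])

    def test_frequencies_sum_to_one(self):
        alignment = make_toy_alignment(8, 30, conserved_columns=[3, 7], seed=4)
        mapping = PoreMapping(
            positions=[(i + 1, i + 1, i + 1) for i in range(30)])
        logo = logo_frequencies(alignment, mapping)
        assert np.allclose(logo.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_sequence_order_permutation_invariant(self):
        alignment = make_toy_alignment(6, 20, conserved_columns=[5], seed=9)
        mapping = PoreMapping(
            positions=[(i + 1, i + 1, i + 1) for i in range(20)])
        a = logo_frequencies(alignment, mapping)
        reversed_aln = MultipleSeqAlignment(list(alignment)[::-1])
        b = logo_frequencies(reversed_aln, mapping)
        assert a.frequencies.equals(b.frequencies)

    def test_empty_subset_rejected(self):
        mapping = PoreMapping(positions=[(1, 1, 1)])
        with pytest.raises(ValueError):
            logo_frequencies(aln("G"), mapping, subset=[])
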