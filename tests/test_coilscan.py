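"""Unit and property tests for the axial-stagger interaction scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctomech.coilscan import (
    AssemblyMode,
    InvalidResidueError,
    NoOverlapError,
    ResidueChain,
    ResidueClassScheme,
    ScanConfig,
    axial_positions,
    classify_residue,
    combine_species,
    count_interactions,
    fft_periodicity,
    overlap_label,
    stagger_scan,
)

from conftest import brute_force_interactions, random_chain


def poly(aa, n):
    return ResidueChain(id=f"poly{aa}", sequence=aa * n, cc_span=(1, n))


class TestClassifyResidue:
    @pytest.mark.parametrize(
        "aa,expected",
        [
            ("D", "acidic"), ("E", "acidic"),
            ("R", "basic"), ("K", "basic"),
            ("L", "apolar"), ("V", "apolar"), ("F", "apolar"),
            ("G", "neutral"), ("H", "neutral"), ("X", "neutral"), ("S", "neutral"),
        ],
    )
    def test_default_classes(self, aa, expected):
        assert classify_residue(aa) == expected

    def test_invalid_residue_rejected(self):
        with pytest.raises(InvalidResidueError):
            classify_residue("B")
        with pytest.raises(InvalidResidueError):
            classify_residue("DD")

    def test_sets_must_be_disjoint(self):
        with pytest.raises(ValueError):
            ResidueClassScheme(apolar_set=frozenset("LKV"))


class TestAxialPositions:
    def test_parallel_identity_alignment(self):
        a, b = poly("A", 10), poly("A", 10)
        pos_a, pos_b, ov = axial_positions(a, b, "parallel", 0)
        assert ov == 10
        assert all(pos_a[i] == pos_b[i] for i in range(1, 11))

    def test_parallel_partial_overlap(self):
        a, b = poly("A", 10), poly("A", 10)
        pos_a, pos_b, ov = axial_positions(a, b, "parallel", 6)
        assert ov == 4
        # A residues 7..10 sit over B residues 1..4
        assert [pos_a[i] for i in (7, 8, 9, 10)] == [pos_b[j] for j in (1, 2, 3, 4)]

    def test_antiparallel_c_terminal_overlap_geometry(self):
        a, b = poly("A", 471), poly("A", 600)
        pos_a, pos_b, ov = axial_positions(a, b, "antiparallel", 421)
        assert ov == 50
        # B's C-terminal residue sits at axial = stagger; both C-terminal
        # 50-residue stretches occupy the shared interval
        assert pos_b[600] == 421
        assert pos_a[471] == 470
        shared = set(range(421, 471))
        assert {pos_a[i] for i in range(422, 472)} == shared
        assert {pos_b[j] for j in range(551, 601)} == shared


class TestCountInteractions:
    def test_no_classes_no_interactions(self):
        g = poly("G", 4)
        assert count_interactions(g, g, "parallel", 0) == (0, 0, 4)

    def test_ionic_window_enumeration(self):
        d, k = poly("D", 4), poly("K", 4)
        # oracle: ordered pairs (i, j) over 4x4 with |i-j| <= 2 -> 14
        assert count_interactions(d, k, "parallel", 0) == (0, 14, 4)

    def test_apolar_window_enumeration(self):
        l = poly("L", 4)
        # pairs with |i-j| <= 1 over 4x4 -> 10
        assert count_interactions(l, l, "parallel", 0) == (10, 0, 4)

    def test_same_charge_does_not_count(self):
        d = poly("D", 6)
        assert count_interactions(d, d, "parallel", 0)[1] == 0

    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_matches_exhaustive_oracle(self, rng, orientation):
        for _ in range(40):
            a = random_chain(rng, int(rng.integers(3, 25)), "a")
            b = random_chain(rng, int(rng.integers(3, 25)), "b")
            for s in range(-(b.cc_length - 1) - 3, a.cc_length + 3):
                got = count_interactions(a, b, orientation, s)
                assert got == brute_force_interactions(a, b, orientation, s)

    def test_parallel_swap_symmetry(self, rng):
        a = random_chain(rng, 18, "a")
        b = random_chain(rng, 14, "b")
        for s in range(-13, 18):
            na, ni, _ = count_interactions(a, b, "parallel", s)
            na2, ni2, _ = count_interactions(b, a, "parallel", -s)
            assert (na, ni) == (na2, ni2)

    def test_antiparallel_swap_symmetry(self, rng):
        # swapping chains in the antiparallel geometry preserves the pair
        # set when the stagger is transformed to keep the same axial layout
        a = random_chain(rng, 16, "a")
        b = random_chain(rng, 12, "b")
        la, lb = a.cc_length, b.cc_length
        for s in range(-11, 16):
            na, ni, ov = count_interactions(a, b, "antiparallel", s)
            s_swapped = s + lb - la  # same overlap seen from chain B
            na2, ni2, ov2 = count_interactions(b, a, "antiparallel", s_swapped)
            assert (na, ni, ov) == (na2, ni2, ov2)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        seq_a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=20),
        seq_b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=20),
        stagger=st.integers(min_value=-25, max_value=25),
        orientation=st.sampled_from(["parallel", "antiparallel"]),
    )
    def test_oracle_equivalence_property(self, seq_a, seq_b, stagger, orientation):
        a = ResidueChain(id="a", sequence=seq_a, cc_span=(1, len(seq_a)))
        b = ResidueChain(id="b", sequence=seq_b, cc_span=(1, len(seq_b)))
        got = count_interactions(a, b, orientation, stagger)
        assert got == brute_force_interactions(a, b, orientation, stagger)

    def test_neutral_reclassification_is_inert(self, rng):
        # removing a residue that is in no class from consideration cannot
        # change counts; enlarging the apolar set cannot decrease n_apolar
        a = random_chain(rng, 20, "a")
        b = random_chain(rng, 20, "b")
        base = ResidueClassScheme()
        bigger = ResidueClassScheme(apolar_set=frozenset("AFILMVWYGC"))
        for s in (-5, 0, 3, 10):
            na, ni, _ = count_interactions(a, b, "parallel", s, base)
            na_big, ni_big, _ = count_interactions(a, b, "parallel", s, bigger)
            assert na_big >= na
            assert ni_big == ni


class TestStaggerScan:
    def test_score_normalization_identity(self, rng):
        a = random_chain(rng, 40, "a")
        b = random_chain(rng, 35, "b")
        res = stagger_scan(a, b)
        for prof in (res.parallel, res.antiparallel):
            ok = prof.overlap_len > 0
            lhs = prof.score[ok] * prof.overlap_len[ok]
            rhs = (prof.n_apolar + prof.n_ionic)[ok]
            assert np.allclose(lhs, rhs)

    def test_self_scan_parallel_symmetry(self, rng):
        a = random_chain(rng, 40, "a")
        res = stagger_scan(a, a)
        prof = res.parallel
        for s in range(1, 20):
            i = np.flatnonzero(prof.staggers == s)[0]
            j = np.flatnonzero(prof.staggers == -s)[0]
            assert prof.n_apolar[i] == prof.n_apolar[j]
            assert prof.n_ionic[i] == prof.n_ionic[j]

    def test_short_span_warns_and_reports_no_significant_mode(self):
        a, b = poly("L", 10), poly("L", 10)
        with pytest.warns(UserWarning, match="min_overlap"):
            res = stagger_scan(a, b)
        assert all(m.status in ("NS", "ND") for m in res.modes)

    def test_modes_sorted_by_descending_score(self, rng):
        a = random_chain(rng, 60, "a")
        b = random_chain(rng, 50, "b")
        scores = [m.score for m in stagger_scan(a, b).modes if np.isfinite(m.score)]
        assert scores == sorted(scores, reverse=True)


class TestOverlapLabel:
    def test_cc_label_from_antiparallel_c_terminal_geometry(self):
        a, b = poly("A", 471), poly("A", 600)
        assert overlap_label(a, b, "antiparallel", 421) == "CC50"

    def test_cn_label_from_parallel_shifted_geometry(self):
        a, b = poly("A", 486), poly("A", 640)
        assert overlap_label(a, b, "parallel", 440) == "CN46"

    def test_full_overlap(self):
        a, b = poly("A", 10), poly("A", 10)
        assert overlap_label(a, b, "parallel", 0) == "FULL10"

    def test_zero_overlap_raises(self):
        a, b = poly("A", 10), poly("A", 10)
        with pytest.raises(NoOverlapError):
            overlap_label(a, b, "parallel", 10)


class TestCombineSpecies:
    def mode(self, stagger, score, orientation="antiparallel", status="significant"):
        return AssemblyMode(orientation, stagger, score, "CC50", status)

    def test_single_species_identity(self):
        modes = [self.mode(421, 0.25)]
        combined, unmatched = combine_species({"human": modes})
        assert combined == modes and unmatched == []

    def test_two_species_arithmetic_mean(self):
        combined, unmatched = combine_species(
            {"human": [self.mode(420, 0.25)], "dog": [self.mode(422, 0.26)]}
        )
        assert len(combined) == 1 and not unmatched
        assert combined[0].stagger == pytest.approx(421)
        assert combined[0].score == pytest.approx(0.255)

    def test_orientation_mismatch_not_combined(self):
        combined, unmatched = combine_species(
            {
                "human": [self.mode(421, 0.25, "parallel")],
                "dog": [self.mode(421, 0.25, "antiparallel")],
            }
        )
        assert combined == []
        assert sorted(sp for sp, _ in unmatched) == ["dog", "human"]

    def test_outside_tolerance_not_combined(self):
        combined, unmatched = combine_species(
            {"human": [self.mode(400, 0.25)], "dog": [self.mode(421, 0.25)]}
        )
        assert combined == [] and len(unmatched) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_species({})


class TestFFTPeriodicity:
    def test_heptad_apolar_indicator_gives_three_and_a_half(self):
        profile = np.array([1.0 if i % 7 in (0, 3) else 0.0 for i in range(70)])
        assert fft_periodicity(profile).dominant_period == pytest.approx(3.5)

    def test_alternating_profile_gives_two(self):
        assert fft_periodicity(np.arange(24) % 2).dominant_period == pytest.approx(2.0)

    def test_constant_profile_flagged(self):
        assert fft_periodicity(np.full(16, 3.3)).no_periodicity

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fft_periodicity(np.ones(5))
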