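import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mprtseq.construct import RtPrimer, build_section_map
from mprtseq.reactivity import (
    AssemblyConflictError,
    NormalizationError,
    ReactivityProfile,
    assemble_sections,
    mean_reactivity,
    normalize_profile,
    peaks_to_positions,
    subtract_control,
)
from mprtseq.simulate import FragmentPopulation, PeakTable, simulate_rt_traces


def _profile(values, sections=None):
    values = np.asarray(values, dtype=float)
    if sections is None:
        sections = np.full(values.size, "s1", dtype=object)
        sections[np.isnan(values)] = ""
    return ReactivityProfile(values=values, section=np.asarray(sections, dtype=object))


class TestPeaksToPositions:
    @pytest.mark.parametrize(
        "pairing_start, k, expected_pos",
        [
            (554, 1, 553),    # boundary stop just 5' of the primer
            (554, 553, 1),    # full extension reaches position 1
            (1036, 482, 554), # lands exactly on the downstream section start
        ],
    )
    def test_stop_coordinate_arithmetic(self, pairing_start, k, expected_pos):
        primer = RtPrimer("p", pairing_start, pairing_start + 17)
        table = PeakTable("p", np.array([k]), np.array([7.0]))
        assert peaks_to_positions(table, primer) == {expected_pos: 7.0}

    def test_same_position_intensities_sum(self):
        primer = RtPrimer("p", 100, 119)
        table = PeakTable("p", np.array([10, 10]), np.array([1.0, 2.0]))
        assert peaks_to_positions(table, primer) == {90: 3.0}

    def test_overlong_cdna_rejected(self):
        primer = RtPrimer("p", 100, 119)
        table = PeakTable("p", np.array([100]), np.array([1.0]))
        with pytest.raises(IndexError, match="off the template"):
            peaks_to_positions(table, primer)


class TestNormalization:
    def test_constant_vector_normalizes_to_one(self):
        prof = _profile([5.0] * 50)
        out = normalize_profile(prof)
        assert np.allclose(out.values, 1.0)

    def test_homogeneity(self, rng):
        vals = rng.uniform(0.1, 9, 80)
        a = normalize_profile(_profile(vals))
        b = normalize_profile(_profile(vals * 10))
        assert np.allclose(a.values, b.values)

    def test_factor_is_mean_of_ranks_3_to_10_for_100_values(self, rng):
        """Brute-force order-statistic oracle: with 100 values, the top 2%
        (2 values) are excluded and the next 8% (ranks 3-10) averaged."""
        vals = rng.permutation(np.arange(1.0, 101.0))
        ranked = np.sort(vals)[::-1]
        expected = ranked[2:10].mean()  # = 94.5
        out = normalize_profile(_profile(vals))
        assert out.normalization["s1"] == pytest.approx(expected)
        assert expected == pytest.approx(94.5)

    def test_order_preserved(self, rng):
        vals = rng.uniform(0, 5, 60)
        out = normalize_profile(_profile(vals))
        assert np.array_equal(np.argsort(vals), np.argsort(out.values))

    def test_all_zero_section_names_section(self):
        vals = np.concatenate([np.ones(20), np.zeros(20)])
        sections = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        with pytest.raises(NormalizationError, match="'b'"):
            normalize_profile(_profile(vals, sections))

    def test_too_few_observed_positions_rejected(self):
        with pytest.raises(NormalizationError, match=">= 10"):
            normalize_profile(_profile([1.0] * 5))

    def test_reused_factors_keep_common_scale(self):
        control = normalize_profile(_profile([2.0] * 40))
        treated = normalize_profile(
            _profile([8.0] * 40), factors=control.normalization
        )
        assert np.allclose(treated.values, 4.0)


class TestSubtractControl:
    def test_identical_profiles_give_zero(self):
        p = _profile([1.0, 2.0, 3.0])
        out = subtract_control(p, p)
        assert np.allclose(out.values, 0.0)

    def test_zero_control_returns_treated(self):
        t = _profile([1.0, 2.0, np.nan])
        out = subtract_control(t, _profile([0.0, 0.0, 0.0]))
        assert out.values[:2].tolist() == [1.0, 2.0]
        assert np.isnan(out.values[2])

    def test_negative_differences_clamped_and_counted(self):
        out = subtract_control(_profile([5.0, 2.0]), _profile([1.0, 4.0]))
        assert out.values.tolist() == [4.0, 0.0]
        assert out.clamped == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            subtract_control(_profile([1.0]), _profile([1.0, 2.0]))


class TestAssembleSections:
    def _primers(self):
        return [RtPrimer("p1", 554, 573), RtPrimer("p2", 1036, 1053)]

    def test_assembly_matches_membership_oracle(self, rng):
        """Every assembled value equals what a brute-force loop that walks
        positions and picks the owning section would produce."""
        primers = self._primers()
        sm = build_section_map(primers, 1100)
        maps = {
            "p1": {int(p): float(v) for p, v in
                   zip(rng.choice(np.arange(1, 554), 40, replace=False),
                       rng.uniform(1, 9, 40))},
            "p2": {int(p): float(v) for p, v in
                   zip(rng.choice(np.arange(400, 1036), 40, replace=False),
                       rng.uniform(1, 9, 40))},
        }
        prof = assemble_sections(maps, sm, 1100, primers=primers)
        for pos in range(1, 1101):
            sec = sm.section_of(pos)
            in_footprint = any(
                p.pairing_start <= pos <= p.pairing_end for p in primers
            )
            got = prof.values[pos - 1]
            if sec is None or in_footprint:
                assert np.isnan(got), pos
            else:
                expected = maps[sec.primer].get(pos, 0.0)
                assert got == pytest.approx(expected), pos

    def test_out_of_section_contributions_discarded(self):
        primers = self._primers()
        sm = build_section_map(primers, 1100)
        # p1 claims position 600 which belongs to p2's section
        prof = assemble_sections({"p1": {600: 5.0}}, sm, 1100, primers=primers)
        assert prof.values[599] == 0.0

    def test_single_primer_assembly_equals_clipped_map(self):
        primer = RtPrimer("p1", 554, 573)
        sm = build_section_map([primer], 600)
        prof = assemble_sections({"p1": {10: 2.0, 553: 4.0}}, sm, 600, [primer])
        assert prof.values[9] == 2.0
        assert prof.values[552] == 4.0
        assert np.isnan(prof.values[553:573]).all()  # primer footprint
        assert np.isnan(prof.values[573:]).all()  # 3' of last pairing start

    def test_unknown_primer_rejected(self):
        sm = build_section_map(self._primers(), 1100)
        with pytest.raises(AssemblyConflictError, match="no section"):
            assemble_sections({"zz": {5: 1.0}}, sm, 1100)

    def test_six_section_provenance(self, bundle):
        c = bundle.construct
        sm = bundle.section_map
        maps = {s.primer: {s.covered_start: 1.0} for s in sm}
        prof = assemble_sections(maps, sm, len(c), primers=c.primers)
        observed_sections = set(prof.section[~prof.mask_missing])
        assert observed_sections == {f"RT{i}" for i in range(1, 7)}


class TestMeanReactivity:
    def test_missing_values_excluded(self):
        assert mean_reactivity(_profile([2.0, 4.0, np.nan, 6.0])) == 4.0

    def test_all_zero(self):
        assert mean_reactivity(_profile([0.0, 0.0])) == 0.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            mean_reactivity(_profile([np.nan, np.nan]))


class TestStopRoundTrip:
    @settings(max_examples=60, deadline=None)
    @given(p=st.integers(min_value=2, max_value=479))
    def test_single_break_recovered_exactly_at_p(self, p, small_construct):
        """The stop-coordinate convention is self-inverse: a single break at
        p reads out as intensity exactly at p."""
        primer = small_construct.primers[0]
        pop = FragmentPopulation([(1, p - 1, 1), (p, 500, 1)], 1, 500)
        (table,) = simulate_rt_traces(pop, [primer])
        positions = peaks_to_positions(table, primer)
        assert positions == {p: 1.0}
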