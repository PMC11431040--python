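import numpy as np
import pytest

from mprtseq.construct import MrnaConstruct, RtPrimer
from mprtseq.simulate import (
    CleavageModel,
    DegenerateModelError,
    FragmentPopulation,
    StressDose,
    cleavage_propensity,
    simulate_electropherogram,
    simulate_fragments,
    simulate_rt_traces,
)
from mprtseq.structure import parse_dotbracket


def _flat_construct(seq: str) -> MrnaConstruct:
    return MrnaConstruct("t", seq, [("body", 1, len(seq))])


class TestCleavagePropensity:
    def test_uniform_model_is_constant(self):
        c = _flat_construct("ACGUACGUAC")
        model = CleavageModel(
            base_weights=dict.fromkeys("ACGU", 1.0),
            context_weights={"exterior": 1.0},
        )
        assert np.allclose(cleavage_propensity(c, None, model), 1.0)

    def test_base_weight_marks_c_positions(self):
        c = _flat_construct("ACCGUC")
        model = CleavageModel(
            base_weights={"A": 1, "C": 4, "G": 1, "U": 1},
            context_weights={"exterior": 1.0},
        )
        prop = cleavage_propensity(c, None, model)
        assert prop.tolist() == [1, 4, 4, 1, 1, 4]

    def test_planted_hotspot_multiplies_interval(self):
        c = _flat_construct("A" * 10)
        model = CleavageModel(
            base_weights=dict.fromkeys("ACGU", 1.0),
            context_weights={"exterior": 1.0},
            planted_hotspots=[(4, 6, 10.0)],
        )
        prop = cleavage_propensity(c, None, model)
        # hand-computed product of multipliers: 1*1*10 inside, 1 outside
        assert prop[3:6].tolist() == [10, 10, 10]
        assert prop[[0, 1, 2, 6, 9]].tolist() == [1, 1, 1, 1, 1]

    def test_structure_context_applies(self):
        c = _flat_construct("ACGUACGUA")
        struct = parse_dotbracket("(((...)))")
        model = CleavageModel(
            base_weights=dict.fromkeys("ACGU", 1.0),
            context_weights={"stem_5prime": 2, "stem_3prime": 0.5,
                             "hairpin_loop": 3, "exterior": 1},
        )
        prop = cleavage_propensity(c, struct, model)
        assert prop.tolist() == [2, 2, 2, 3, 3, 3, 0.5, 0.5, 0.5]

    def test_length_mismatch_rejected(self):
        c = _flat_construct("ACGU")
        struct = parse_dotbracket("......")
        with pytest.raises(ValueError, match="length"):
            cleavage_propensity(c, struct, CleavageModel())


class TestSimulateFragments:
    def test_zero_dose_yields_full_length_only(self):
        prop = np.ones(100)
        pop = simulate_fragments(prop, StressDose("freeze_thaw", 0), 500, 0, 0.1)
        assert pop.fragments == [(1, 100, 500)]

    def test_single_permitted_site_forces_two_fragments(self):
        prop = np.zeros(100)
        prop[49] = 1.0  # only site 50 can be cut
        pop = simulate_fragments(prop, StressDose("freeze_thaw", 50), 200, 0, 1.0)
        assert {(s, e) for s, e, _ in pop.fragments} <= {(1, 49), (50, 100), (1, 100)}
        # at expected 50 cuts/molecule essentially every molecule is cut
        counts = dict(((s, e), c) for s, e, c in pop.fragments)
        assert counts.get((1, 49), 0) == counts.get((50, 100), 0) > 190

    def test_nucleotide_conservation(self):
        rng = np.random.default_rng(5)
        prop = rng.uniform(0.1, 2.0, 300)
        pop = simulate_fragments(prop, StressDose("heat_37C", 10), 1000, rng, 0.05)
        assert pop.total_nucleotides() == 1000 * 300

    def test_cut_site_frequencies_follow_propensity(self):
        """Empirical cut-site frequencies over 1e5 molecules match the
        multinomial expectation within 3 standard errors."""
        rng = np.random.default_rng(77)
        prop = np.concatenate([[1.0], np.tile([1.0, 2.0, 4.0, 0.5], 12)])  # L=49
        pop = simulate_fragments(prop, StressDose("freeze_thaw", 1), 100_000, rng, 0.5)
        cut_counts = np.zeros(prop.size + 1)
        for s, _, c in pop.fragments:
            if s > 1:
                cut_counts[s] += c
        total = cut_counts.sum()
        p_exp = prop[1:] / prop[1:].sum()
        for site in range(2, prop.size + 1):
            exp = total * p_exp[site - 2]
            se = np.sqrt(total * p_exp[site - 2] * (1 - p_exp[site - 2]))
            assert abs(cut_counts[site] - exp) <= 3 * se + 1, f"site {site}"

    def test_all_zero_propensity_rejected(self):
        with pytest.raises(DegenerateModelError):
            simulate_fragments(np.zeros(50), StressDose("freeze_thaw", 5), 10, 0, 1.0)

    def test_reproducible_for_fixed_seed(self):
        prop = np.ones(200)
        a = simulate_fragments(prop, StressDose("freeze_thaw", 10), 500, 3, 0.05)
        b = simulate_fragments(prop, StressDose("freeze_thaw", 10), 500, 3, 0.05)
        assert a.fragments == b.fragments


class TestRtTraces:
    def test_intact_molecules_give_single_full_extension_peak(self, small_construct):
        pop = FragmentPopulation([(1, 500, 100)], 100, 500)
        tables = simulate_rt_traces(pop, small_construct.primers)
        (t,) = tables
        assert t.lengths.tolist() == [479]  # pairing_start 480 - fragment start 1
        assert t.intensities.tolist() == [100.0]

    def test_break_upstream_of_pairing_site_stop_arithmetic(self):
        # break at 300 on a primer pairing 554-573: downstream fragment
        # starts at 300, cDNA length 554 - 300 = 254
        primer = RtPrimer("p1", 554, 573)
        pop = FragmentPopulation([(1, 299, 1), (300, 1000, 1)], 1, 1000)
        (t,) = simulate_rt_traces(pop, [primer])
        assert t.lengths.tolist() == [254]

    def test_fragment_without_pairing_site_contributes_nothing(self):
        primer = RtPrimer("p1", 554, 573)
        pop = FragmentPopulation([(1, 560, 1)], 1, 1000)  # site truncated
        (t,) = simulate_rt_traces(pop, [primer])
        assert t.lengths.size == 0

    def test_noise_free_read_out_is_deterministic(self, small_construct):
        pop = FragmentPopulation([(1, 200, 5), (201, 500, 5)], 5, 500)
        t1 = simulate_rt_traces(pop, small_construct.primers, 0.0, 1)
        t2 = simulate_rt_traces(pop, small_construct.primers, 0.0, 2)
        assert t1[0].lengths.tolist() == t2[0].lengths.tolist()
        assert t1[0].intensities.tolist() == t2[0].intensities.tolist()


class TestElectropherogram:
    def test_delta_input_centres_at_full_length(self):
        pop = FragmentPopulation([(1, 2896, 1000)], 1000, 2896)
        eph = simulate_electropherogram(pop, sizing_sd=25.0)
        assert abs(eph.axis[np.argmax(eph.signal)] - 2896) <= 1

    def test_equal_mass_gives_equal_area_peaks(self):
        # 50/50 nucleotide mass at 1000 nt and 2500 nt
        pop = FragmentPopulation([(1, 1000, 25), (1, 2500, 10)], 35, 2500)
        eph = simulate_electropherogram(pop, sizing_sd=10.0)
        split = 1750
        left = eph.signal[eph.axis < split].sum()
        right = eph.signal[eph.axis >= split].sum()
        assert abs(left - right) / (left + right) < 0.01

    def test_total_area_proportional_to_mass(self):
        pop = FragmentPopulation([(1, 500, 10), (501, 800, 10)], 10, 800)
        eph = simulate_electropherogram(pop, sizing_sd=5.0)
        assert eph.signal.sum() == pytest.approx(pop.total_nucleotides(), rel=1e-3)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_electropherogram(FragmentPopulation([], 0, 100), 10.0)
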