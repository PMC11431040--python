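import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mprtseq.degmodel import (
    DegradationBaseline,
    FREEZE_THAW_BASELINE,
    HEAT_BASELINE,
    baseline_at,
    classify_high_intensity,
    composition_stats,
    find_hotspots,
    fold_change,
)
from mprtseq.reactivity import ReactivityProfile


def _profile(values):
    return ReactivityProfile(values=np.asarray(values, dtype=float))


class TestBaseline:
    def test_regime_parameters_return_A_at_origin(self):
        assert baseline_at(FREEZE_THAW_BASELINE, 0) == 3.5
        assert baseline_at(HEAT_BASELINE, 0) == 8.8

    def test_doubling_identity(self):
        assert baseline_at(DegradationBaseline(A=1, q=1), 3) == 8

    def test_strictly_increasing_when_q_positive(self):
        b = DegradationBaseline(A=2.0, q=0.001)
        vals = baseline_at(b, np.arange(0, 50))
        assert np.all(np.diff(vals) > 0)

    def test_constant_when_q_zero(self):
        b = DegradationBaseline(A=2.0, q=0.0)
        assert np.unique(baseline_at(b, np.arange(0, 50))).tolist() == [2.0]

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            baseline_at(FREEZE_THAW_BASELINE, -1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DegradationBaseline(A=0.0, q=0.1)
        with pytest.raises(ValueError):
            DegradationBaseline(A=1.0, q=-0.1)


class TestClassifyHighIntensity:
    def test_exact_baseline_is_low(self):
        b = DegradationBaseline(A=2.0, q=0.0)
        mask = classify_high_intensity(_profile([2.0, 2.0, 2.0]), b)
        assert not mask.any()  # "higher than" is strict

    def test_single_position_above(self):
        b = DegradationBaseline(A=2.0, q=0.0)
        mask = classify_high_intensity(_profile([1.0, 4.0, 2.0]), b)
        assert mask.tolist() == [False, True, False]

    def test_missing_is_low(self):
        b = DegradationBaseline(A=1.0, q=0.0)
        mask = classify_high_intensity(_profile([np.nan, 5.0]), b)
        assert mask.tolist() == [False, True]

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=1, max_size=60
        ),
        A=st.floats(0.1, 50, allow_nan=False),
        q=st.floats(0, 0.01, allow_nan=False),
    )
    def test_matches_elementwise_oracle(self, values, A, q):
        b = DegradationBaseline(A=A, q=q)
        mask = classify_high_intensity(_profile(values), b)
        for i, v in enumerate(values, start=1):
            assert mask[i - 1] == (v > A * (1 + q) ** i)


class TestFindHotspots:
    def _mask(self, length, highs):
        m = np.zeros(length, dtype=bool)
        m[np.asarray(list(highs), dtype=int) - 1] = True
        return m

    def test_reference_fixture_yields_exactly_four_calls(self, bundle):
        masks = {
            r: classify_high_intensity(p, bundle.baselines[r])
            for r, p in bundle.profiles.items()
        }
        calls = find_hotspots(masks, sequence=bundle.construct.sequence)
        assert [h.span for h in calls] == [
            (1986, 1988), (2307, 2312), (2438, 2442), (2750, 2753)
        ]
        assert [h.sequence for h in calls] == ["GCC", "CCGACC", "UUCGU", "UUGG"]

    def test_single_condition_run_dropped_when_all_required(self):
        masks = {
            "a": self._mask(50, range(10, 16)),
            "b": self._mask(50, []),
        }
        assert find_hotspots(masks) == []

    def test_isolated_highs_dropped_by_min_high(self):
        # gap 4 > max_gap 3 keeps {10} and {15} apart; each is then below
        # min_high=2 — brute-force over gap placements
        for gap in range(1, 8):
            masks = {"a": self._mask(40, [10, 10 + gap + 1])}
            calls = find_hotspots(masks, min_high=2, max_gap=3)
            if gap <= 3:
                assert [h.span for h in calls] == [(10, 11 + gap)]
            else:
                assert calls == []

    def test_condition_order_invariance(self, bundle):
        masks = {
            r: classify_high_intensity(p, bundle.baselines[r])
            for r, p in bundle.profiles.items()
        }
        fwd = find_hotspots(dict(masks), sequence=bundle.construct.sequence)
        rev = find_hotspots(dict(reversed(list(masks.items()))),
                            sequence=bundle.construct.sequence)
        assert [h.span for h in fwd] == [h.span for h in rev]

    def test_calls_never_overlap(self, rng):
        for _ in range(20):
            masks = {
                "a": rng.random(200) < 0.2,
                "b": rng.random(200) < 0.2,
            }
            calls = find_hotspots(masks)
            for h1, h2 in zip(calls, calls[1:]):
                assert h1.end < h2.start

    def test_empty_condition_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_hotspots({})


class TestFoldChange:
    @pytest.mark.parametrize(
        "window_mean, reference, expected",
        [
            (471.1, 3.5, 134.6),    # division oracle
            (510.51, 23.1, 22.1),   # division oracle
            (7.7, 7.7, 1.0),        # identity
        ],
    )
    def test_division_oracle(self, window_mean, reference, expected):
        prof = _profile([window_mean] * 5)
        assert fold_change(prof, 1, 5, reference) == pytest.approx(expected)

    def test_all_missing_window_rejected(self):
        prof = _profile([np.nan, np.nan, 1.0])
        with pytest.raises(ValueError, match="no observed"):
            fold_change(prof, 1, 2, 3.5)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            fold_change(_profile([1.0]), 1, 1, 0.0)


class TestCompositionStats:
    def test_direct_count(self):
        mask = np.array([True, True, True, True, False])
        stats = composition_stats(mask, "CCGAU")
        assert stats["count"] == 4
        assert stats["proportions"] == {"C": 0.5, "G": 0.25, "A": 0.25, "U": 0.0}

    def test_all_on_one_base(self):
        stats = composition_stats(np.array([True, True]), "CC")
        assert stats["proportions"]["C"] == 1.0

    def test_empty_mask_flagged_undefined(self):
        stats = composition_stats(np.zeros(4, dtype=bool), "ACGU")
        assert stats == {"count": 0, "proportions": None}

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_matches_tally_oracle(self, data):
        n = data.draw(st.integers(1, 80))
        seq = "".join(np.random.default_rng(n).choice(list("ACGU"), n))
        mask = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        stats = composition_stats(mask, seq)
        tally = {b: 0 for b in "CGAU"}
        for i in range(n):
            if mask[i]:
                tally[seq[i]] += 1
        total = sum(tally.values())
        if total == 0:
            assert stats["proportions"] is None
        else:
            assert sum(stats["proportions"].values()) == pytest.approx(1.0)
            for b in "CGAU":
                assert stats["proportions"][b] == pytest.approx(tally[b] / total)
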