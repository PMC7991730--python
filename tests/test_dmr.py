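import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methrevert.core_io import Comparison
from methrevert.dmr import (
    CandidateWindow,
    call_dmrs,
    chain_candidates,
    mwu_test,
    segment,
)
from methrevert.quant import MethylationMatrix

from _oracles import mwu_two_sided_enumerate


def _matrix_from_ratios(positions, ratios_by_sample, groups, depth=20):
    """Build a matrix whose per-site ratios are exactly the given values."""
    samples = list(ratios_by_sample)
    n = len(positions)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    depths = np.full((n, len(samples)), depth, dtype=np.int64)
    for j, s in enumerate(samples):
        vals = np.asarray(ratios_by_sample[s], dtype=float)
        missing = np.isnan(vals)
        depths[missing, j] = 0
        meth[~missing, j] = np.round(vals[~missing] * depth).astype(int)
    return MethylationMatrix(
        sites=pd.DataFrame({"chrom": "chr1", "pos": positions}),
        samples=samples,
        groups=pd.Series(groups),
        meth=meth,
        depth=depths,
    )


class TestChaining:
    def _matrix(self, positions):
        return _matrix_from_ratios(
            positions,
            {"a": [0.5] * len(positions), "b": [0.5] * len(positions)},
            {"a": "SD", "b": "FFC"},
        )

    def test_contiguous_run_forms_one_window(self):
        windows = chain_candidates(self._matrix([0, 100, 200, 300, 400]))
        assert len(windows) == 1
        assert windows[0].site_indices == (0, 1, 2, 3, 4)
        assert (windows[0].start, windows[0].end) == (0, 401)

    def test_large_gap_splits_and_short_runs_drop(self):
        windows = chain_candidates(
            self._matrix([0, 100, 200, 600, 700, 800, 900, 1000])
        )
        # gap of 400 splits: left run of 3 CpGs discarded, right run of 5 kept
        assert len(windows) == 1
        assert windows[0].site_indices == (3, 4, 5, 6, 7)

    def test_below_min_cpgs_yields_nothing(self):
        assert chain_candidates(self._matrix([0, 100, 200, 300])) == []


class TestMwu:
    def test_complete_separation_small_n(self):
        # exactly 2 of the C(6,3)=20 labelings are as extreme
        assert mwu_test([0.1, 0.2, 0.3], [0.4, 0.5, 0.6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert mwu_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_study_sized_separation_matches_exact_tail(self):
        a = [0.1 * i for i in range(1, 8)]
        b = [0.1 * i for i in range(8, 18)]
        from math import comb

        assert mwu_test(a, b) == pytest.approx(2 / comb(17, 7))

    def test_too_few_values_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert np.isnan(mwu_test([0.1], [0.2, 0.3]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        na=st.integers(2, 6),
        nb=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_exact_path_matches_labeling_enumeration(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1, na + nb + 1) / 10.0)
        a, b = pooled[:na], pooled[na:]
        assert mwu_test(a, b) == pytest.approx(
            mwu_two_sided_enumerate(a, b), rel=1e-12
        )


class TestSegmentation:
    def _setup(self, profile_a, profile_b):
        positions = list(range(0, 100 * len(profile_a), 100))
        matrix = _matrix_from_ratios(
            positions,
            {"a1": profile_a, "a2": profile_a, "b1": profile_b, "b2": profile_b},
            {"a1": "G1", "a2": "G1", "b1": "G2", "b2": "G2"},
        )
        window = CandidateWindow(
            "chr1", positions[0], positions[-1] + 1, tuple(range(len(positions)))
        )
        return matrix, window, Comparison.versus("G1", "G2")

    def test_flat_profile_emits_whole_window(self):
        base = [0.5] * 10
        shifted = [0.3] * 10
        matrix, window, comparison = self._setup(base, shifted)
        assert segment(window, matrix, comparison) == [window]

    def test_change_point_is_found(self):
        a = [0.5] * 5 + [0.8] * 5
        b = [0.5] * 10
        matrix, window, comparison = self._setup(a, b)
        parts = segment(window, matrix, comparison)
        assert [p.site_indices for p in parts] == [tuple(range(5)), tuple(range(5, 10))]

    def test_minimal_window_cannot_split(self):
        a = [0.1, 0.9, 0.1, 0.9, 0.1]
        matrix, window, comparison = self._setup(a, [0.5] * 5)
        assert segment(window, matrix, comparison) == [window]


class TestCallDmrs:
    def _planted(self, delta, n_sd=7, n_ffc=10, seed=0, n_windows=6):
        rng = np.random.default_rng(seed)
        positions = []
        for w in range(n_windows):
            positions.extend(range(w * 10_000, w * 10_000 + 800, 100))
        positions = sorted(positions)
        n = len(positions)
        data, groups = {}, {}
        shift = np.zeros(n)
        shift[:8] = delta  # effect confined to the first window
        for i in range(n_sd):
            data[f"sd{i}"] = np.clip(0.4 + 0.03 * rng.standard_normal(n), 0, 1)
            groups[f"sd{i}"] = "SD"
        for i in range(n_ffc):
            data[f"f{i}"] = np.clip(0.4 + shift + 0.03 * rng.standard_normal(n), 0, 1)
            groups[f"f{i}"] = "FFC"
        return _matrix_from_ratios(positions, data, groups, depth=100)

    def test_planted_effect_is_called_and_nulls_are_not(self):
        matrix = self._planted(delta=0.3)
        result = call_dmrs(matrix, Comparison.versus("FFC", "SD"))
        assert len(result) == 1
        d = result[0]
        assert d.direction == "hyper" and d.diff > 0.25
        assert d.start < 800

    def test_every_emitted_dmr_meets_all_criteria(self):
        matrix = self._planted(delta=0.3)
        result = call_dmrs(matrix, Comparison.versus("FFC", "SD"))
        for d in result:
            assert d.n_cpgs >= 5
            assert abs(d.diff) > 0.1
            assert d.p_adj < 0.05
            assert d.p_adj == pytest.approx(min(1.0, d.p_raw * result.n_tested))

    def test_diff_at_threshold_is_rejected_strictly(self):
        # a difference exactly at min_abs_diff fails the strict > criterion
        matrix = self._planted(delta=0.3)
        comparison = Comparison.versus("FFC", "SD")
        (d,) = call_dmrs(matrix, comparison)
        boundary = call_dmrs(matrix, comparison, min_abs_diff=abs(d.diff))
        assert boundary.n_tested > 0 and len(boundary) == 0

    def test_swapping_groups_negates_diff_keeps_p(self):
        matrix = self._planted(delta=0.3)
        comparison = Comparison.versus("FFC", "SD")
        fwd = call_dmrs(matrix, comparison)
        rev = call_dmrs(matrix, comparison.swapped())
        assert len(fwd) == len(rev) == 1
        assert fwd[0].diff == pytest.approx(-rev[0].diff)
        assert fwd[0].p_raw == pytest.approx(rev[0].p_raw)
        assert {fwd[0].direction, rev[0].direction} == {"hyper", "hypo"}

    def test_emitted_dmrs_do_not_overlap(self, planted_study):
        from methrevert.quant import filter_missing_by_group

        comparison = Comparison.versus("FFC", "SD")
        filtered = filter_missing_by_group(planted_study["matrix"], comparison)
        result = call_dmrs(filtered, comparison)
        assert len(result) > 10
        intervals = sorted((d.chrom, d.start, d.end) for d in result)
        for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
            assert c1 != c2 or e1 <= s2
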