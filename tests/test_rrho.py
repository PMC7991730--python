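import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methrevert.rrho import (
    effect_spearman,
    extract_concordant,
    hypergeom_upper_tail,
    rank_elements,
    rrho_map,
    signed_score,
)

from _oracles import (
    hypergeom_tail_enumerate,
    hypergeom_tail_fraction,
    spearman_two_sided_enumerate,
)


class TestRanking:
    def test_descending_by_signed_score(self):
        assert rank_elements({"a": 3.0, "b": 0.0, "c": -2.0}) == ["a", "b", "c"]

    def test_all_zero_breaks_ties_lexicographically(self):
        assert rank_elements({"z": 0.0, "a": 0.0, "m": 0.0}) == ["a", "m", "z"]

    def test_sign_flip_reverses_order(self):
        scores = {"a": 3.0, "b": 1.5, "c": -2.0, "d": 0.5}
        flipped = {k: -v for k, v in scores.items()}
        assert rank_elements(flipped) == rank_elements(scores)[::-1]

    def test_score_is_zero_iff_p_is_one(self):
        assert signed_score(0.2, 1.0) == 0.0
        assert signed_score(-0.2, 0.1) == pytest.approx(-1.0)
        assert np.isfinite(signed_score(0.5, 0.0))  # floored, not infinite


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,s1,s2,n,expected",
        [
            (5, 5, 5, 10, 1 / 252),
            (0, 3, 4, 10, 1.0),
            (1, 1, 1, 2, 0.5),
        ],
    )
    def test_small_closed_forms(self, k, s1, s2, n, expected):
        assert hypergeom_upper_tail(k, s1, s2, n) == pytest.approx(expected, rel=1e-12)

    def test_matches_subset_enumeration(self):
        for n in range(1, 8):
            for s1 in range(n + 1):
                for s2 in range(n + 1):
                    for k in range(min(s1, s2) + 1):
                        assert hypergeom_upper_tail(k, s1, s2, n) == pytest.approx(
                            float(hypergeom_tail_enumerate(k, s1, s2, n)), rel=1e-11
                        )

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 5, 10)


class TestRrhoMap:
    def _ranking(self, n):
        return [f"e{i:04d}" for i in range(n)]

    def test_identical_rankings_hit_closed_form_diagonal(self):
        ranked = self._ranking(100)
        result = rrho_map(ranked, ranked, step=10)
        for i, t in enumerate(result.thresholds):
            expected = -np.log10(float(hypergeom_tail_fraction(t, t, t, 100)))
            assert result.map[i, i] == pytest.approx(expected, rel=1e-9)

    def test_transpose_symmetry(self, rng):
        a = self._ranking(200)
        b = list(rng.permutation(a))
        ab = rrho_map(a, b, step=10)
        ba = rrho_map(b, a, step=10)
        np.testing.assert_allclose(ab.map, ba.map.T, rtol=1e-9)

    def test_rank_only_invariance(self):
        """The map depends on score order, not score magnitude."""
        scores = {f"e{i}": float(10 - i) for i in range(50)}
        squashed = {k: np.tanh(v / 20) for k, v in scores.items()}  # monotone
        a = rank_elements(scores)
        assert rank_elements(squashed) == a

    def test_reversed_ranking_shows_no_shared_enrichment(self):
        """Anti-correlated lists light up only the discordance quadrants,
        which the enrichment-only map deliberately leaves unsigned: the map
        stays near zero, in contrast to identical rankings."""
        a = self._ranking(100)
        reversed_result = rrho_map(a, a[::-1], step=10)
        identical_result = rrho_map(a, a, step=10)
        assert reversed_result.map.max() <= 1.0  # nothing near significance
        assert identical_result.map.max() > 10.0

    def test_too_few_elements_raise(self):
        with pytest.raises(ValueError):
            rrho_map(["a"], ["a"])


class TestConcordant:
    def test_sign_rule(self):
        a = {"x": 2.0, "y": -1.0, "z": 1.0}
        b = {"x": 1.0, "y": -3.0, "z": -1.0}
        up, down = extract_concordant(a, b, mode="sign")
        assert up == {"x"} and down == {"y"}

    def test_disjoint_signs_give_empty_sets(self):
        a = {"x": 1.0, "y": 2.0}
        b = {"x": -1.0, "y": -2.0}
        up, down = extract_concordant(a, b, mode="sign")
        assert up == set() and down == set()

    def test_quadrant_mode_recovers_shared_top_and_bottom(self, rng):
        n = 200
        base = rng.standard_normal(n) * 3
        a = {f"e{i:03d}": base[i] for i in range(n)}
        b = {f"e{i:03d}": base[i] + 0.1 * rng.standard_normal() for i in range(n)}
        up, down = extract_concordant(a, b, mode="rrho_quadrant")
        top = {k for k, v in a.items() if v > 1.5}
        assert len(top & up) / len(top) > 0.8


class TestEffectSpearman:
    def test_monotone_transform_gives_unity(self):
        x = [0.1, 0.4, 0.2, 0.9]
        rho, _ = effect_spearman(x, [2 * v for v in x])
        assert rho == pytest.approx(1.0)
        rho, _ = effect_spearman(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_from_permutations_n4(self):
        rho, p = effect_spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)
        assert p == pytest.approx(8 / 24)  # 24 permutations, 8 as extreme

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(4, 7), seed=st.integers(0, 999))
    def test_exact_p_matches_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        _, p = effect_spearman(x, y)
        assert p == pytest.approx(spearman_two_sided_enumerate(x, y), rel=1e-9)

    def test_constant_vector_is_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = effect_spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)
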