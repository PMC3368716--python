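import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from stratanet import (
    ALLOWED_ALPHAS,
    ConstantVectorError,
    LayeredNetwork,
    pearson_critical_r,
    pearson_r,
    recurrent_correlations,
    significant_correlations,
    spearman_r,
    spearman_significance,
)


class TestPearsonR:
    def test_perfect_positive(self):
        x = [1.0, 2, 3, 4]
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov/(sx*sy) computed by hand: r = 0.8
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pairwise_complete_missing(self):
        x = [1.0, 2, np.nan, 4, 5]
        y = [1.0, 2, 3, 4, np.nan]
        # uses the three complete pairs (1,1),(2,2),(4,4)
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_constant_vector_errors_not_zero(self):
        with pytest.raises(ConstantVectorError):
            pearson_r([1.0, 1, 1], [1.0, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson_r([1.0, 2], [3.0, 4])


class TestCriticalR:
    def test_three_points_alpha_05(self):
        """df = 1: the minimal significant |r| is 0.997 to three decimals."""
        assert round(pearson_critical_r(3, 0.05), 3) == 0.997

    def test_df_is_n_minus_2(self):
        # n = 3 must behave as a single-degree-of-freedom t threshold
        t_crit = sps.t.ppf(0.975, 1)
        expected = t_crit / np.sqrt(t_crit**2 + 1)
        assert pearson_critical_r(3, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_n12_alpha_05_from_t_table(self):
        # two-sided t critical value at df = 10 is 2.228
        assert round(pearson_critical_r(12, 0.05), 3) == 0.576

    def test_strictly_decreasing_in_n(self):
        vals = [pearson_critical_r(n, 0.05) for n in range(3, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.15  # -> 0 as n grows

    def test_increasing_as_alpha_shrinks(self):
        for n in (3, 10, 50):
            vals = [pearson_critical_r(n, a) for a in (0.10, 0.05, 0.02, 0.01)]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rejects_small_n_and_odd_alpha(self):
        with pytest.raises(ValueError):
            pearson_critical_r(2, 0.05)
        with pytest.raises(ValueError):
            pearson_critical_r(10, 0.03)


class TestSpearmanSignificance:
    def test_r_zero(self):
        t, p = spearman_significance(0.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_r05_n11(self):
        t, p = spearman_significance(0.5, 11)
        assert t == pytest.approx(0.5 * 3 / np.sqrt(0.75), rel=1e-12)
        assert p == pytest.approx(0.117, abs=5e-4)

    def test_perfect_correlation_limit(self):
        _, p = spearman_significance(1.0, 5)
        assert p == 0.0
        _, p = spearman_significance(-1.0, 5)
        assert p == 0.0

    @pytest.mark.parametrize("n", [3, 5, 11, 30, 100])
    def test_matches_independent_arithmetic_on_grid(self, n):
        for r in np.linspace(-0.95, 0.95, 21):
            t, p = spearman_significance(float(r), n)
            t_direct = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert t == pytest.approx(t_direct, rel=1e-13)
            p_direct = 2 * (1 - sps.t.cdf(abs(t_direct), n - 2))
            assert p == pytest.approx(p_direct, abs=1e-10)

    def test_consistency_with_critical_r(self):
        """The t-based p-value and the critical-|r| rule agree at the edge."""
        for n in (3, 5, 12, 40):
            for alpha in ALLOWED_ALPHAS:
                rc = pearson_critical_r(n, alpha)
                _, p_below = spearman_significance(rc * (1 - 1e-6), n)
                _, p_above = spearman_significance(min(rc * (1 + 1e-6), 1.0), n)
                assert p_below > alpha
                assert p_above < alpha


def _layer_net(vectors: dict[str, list[float]], layers=("L",)):
    n_t = len(next(iter(vectors.values())))
    values = {}
    for lay in layers:
        for e, v in vectors.items():
            values[(lay, e)] = np.asarray(v, dtype=float)
    return LayeredNetwork(
        list(layers), list(vectors), [f"t{i}" for i in range(n_t)], values
    )


class TestSignificantCorrelations:
    def test_planted_perfect_pair_reported_positive(self):
        net = _layer_net({
            "a": [0.0, 1, 2], "b": [1.0, 3, 5], "c": [4.0, 0, 3],
        })
        recs = significant_correlations(net, "L", alpha=0.05)
        pairs = {(r.entity_a, r.entity_b): r for r in recs}
        assert ("a", "b") in pairs
        assert pairs[("a", "b")].sign == "positive"
        assert pairs[("a", "b")].n == 3

    def test_r_099_not_significant_at_n3(self):
        """|r| = 0.99 < 0.997 fails the three-point threshold."""
        x = np.array([0.0, 1.0, 2.0])
        y = x + np.array([0.0, 0.0, 0.5])  # r ≈ 0.993
        assert abs(pearson_r(x, y)) < 0.997
        net = _layer_net({"a": list(x), "b": list(y)})
        assert significant_correlations(net, "L", alpha=0.05) == []

    def test_sign_filter(self):
        net = _layer_net({
            "a": [0.0, 1, 2], "b": [2.0, 1, 0], "c": [0.0, 2, 4],
        })
        pos = significant_correlations(net, "L", sign_filter="positive")
        neg = significant_correlations(net, "L", sign_filter="negative")
        assert {(r.entity_a, r.entity_b) for r in pos} == {("a", "c")}
        assert {(r.entity_a, r.entity_b) for r in neg} == {
            ("a", "b"), ("b", "c"),
        }

    def test_constant_pairs_skipped(self):
        net = _layer_net({"a": [1.0, 1, 1], "b": [0.0, 1, 2]})
        assert significant_correlations(net, "L") == []

    def test_spearman_route(self):
        net = _layer_net({
            "a": list(range(8)), "b": [x**3 for x in range(8)],
        })
        recs = significant_correlations(net, "L", method="spearman")
        assert len(recs) == 1 and recs[0].r == pytest.approx(1.0)

    def test_unknown_inputs_rejected(self):
        net = _layer_net({"a": [0.0, 1, 2], "b": [1.0, 0, 2]})
        with pytest.raises(ValueError):
            significant_correlations(net, "X")
        with pytest.raises(ValueError):
            significant_correlations(net, "L", method="kendall")
        with pytest.raises(ValueError):
            significant_correlations(net, "L", alpha=0.07)

    def test_records_symmetric_no_self_pairs(self):
        rng = np.random.default_rng(2)
        net = _layer_net({f"e{i}": list(rng.normal(size=5)) for i in range(6)})
        recs = significant_correlations(net, "L", alpha=0.10)
        for r in recs:
            assert r.entity_a != r.entity_b
        keys = [(r.entity_a, r.entity_b) for r in recs]
        assert len(keys) == len(set(map(lambda k: tuple(sorted(k)), keys)))


class TestTypeIError:
    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_gaussian_noise_calibration(self, n):
        """False-positive fraction ≈ alpha on independent Gaussian pairs."""
        rng = np.random.default_rng(100 + n)
        n_pairs = 10_000
        x = rng.normal(size=(n_pairs, n))
        y = rng.normal(size=(n_pairs, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        for alpha in ALLOWED_ALPHAS:
            frac = np.mean(np.abs(r) >= pearson_critical_r(n, alpha))
            se = np.sqrt(alpha * (1 - alpha) / n_pairs)
            assert abs(frac - alpha) < 3 * se


class TestRecurrent:
    def test_planted_pair_on_two_of_four_layers(self):
        layers = ["L1", "L2", "L3", "L4"]
        rng = np.random.default_rng(4)
        vectors = {f"e{i}": None for i in range(4)}
        values = {}
        for lay in layers:
            for e in vectors:
                values[(lay, e)] = rng.normal(size=4)
        # plant an exact pair on L1 and L3 only
        base = np.array([0.0, 1, 2, 3])
        for lay in ("L1", "L3"):
            values[(lay, "e0")] = base
            values[(lay, "e1")] = 2 * base + 1
        net = LayeredNetwork(layers, list(vectors), ["t0", "t1", "t2", "t3"],
                             values)
        recs = recurrent_correlations(net, alpha=0.05)
        planted = [r for r in recs if {r.entity_a, r.entity_b} == {"e0", "e1"}]
        assert len(planted) == 1
        assert set(planted[0].layers) >= {"L1", "L3"}
        assert planted[0].consistent_sign

    def test_single_layer_significance_not_recurrent(self):
        net = _layer_net(
            {"a": [0.0, 1, 2], "b": [1.0, 3, 5], "c": [5.0, 1, 2]},
            layers=("L1",),
        )
        assert recurrent_correlations(net) == []

    def test_min_layers_validation(self):
        net = _layer_net({"a": [0.0, 1, 2], "b": [1.0, 3, 5]})
        with pytest.raises(ValueError, match="min_layers"):
            recurrent_correlations(net, min_layers=1)

    def test_mixed_signs_reported_and_filterable(self):
        layers = ["L1", "L2"]
        base = np.array([0.0, 1, 2, 3])
        values = {
            ("L1", "a"): base, ("L1", "b"): base * 3 + 1,      # positive
            ("L2", "a"): base, ("L2", "b"): -base + 5,         # negative
        }
        net = LayeredNetwork(layers, ["a", "b"], list("0123"), values)
        recs = recurrent_correlations(net)
        assert len(recs) == 1
        assert set(recs[0].signs) == {"positive", "negative"}
        assert not recs[0].consistent_sign
        assert recurrent_correlations(net, sign_filter="positive") == []


@settings(max_examples=40, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    r1 = spearman_r(x, y)
    r2 = spearman_r(np.exp(x), y)          # strictly increasing transform
    r3 = spearman_r(x, y**3)               # strictly increasing (odd power)
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert r1 == pytest.approx(r3, abs=1e-12)
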