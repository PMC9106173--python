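import math

import numpy as np
import pandas as pd
import pytest

from topogait.persistence import Bar, Barcode, sublevel_barcode
from topogait.signal import InvalidInputError, TimeSeries
from topogait.bottleneck import (
    bar_distance,
    bottleneck_distance,
    diagonal_gap,
    distance_matrix,
)

from .conftest import random_barcode
from .oracles import brute_bottleneck

INF = math.inf


def make(bars):
    return Barcode([Bar(b, d) for b, d in bars])


class TestBarDistance:
    @pytest.mark.parametrize("b1, b2, expected", [
        ((0, INF), (1, INF), 1.0),
        ((0, 2), (1, 5), 3.0),
        ((0, 2), (0, INF), INF),
        ((0, 2), (0, 2), 0.0),
    ])
    def test_case_analysis(self, b1, b2, expected):
        assert bar_distance(Bar(*b1), Bar(*b2)) == expected

    @pytest.mark.parametrize("bar, expected", [
        ((0, 2), 1.0),
        ((3, 3 + 1e-6), 5e-7),
        ((0, INF), INF),
    ])
    def test_diagonal_gap(self, bar, expected):
        assert diagonal_gap(Bar(*bar)) == pytest.approx(expected)


class TestBottleneckDistance:
    def test_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            B = make(random_barcode(rng))
            assert bottleneck_distance(B, B) == 0.0

    def test_single_bar_vs_empty_goes_to_diagonal(self):
        assert bottleneck_distance(make([(0, 2)]), make([])) == 1.0

    def test_direct_match_vs_diagonal_tradeoff(self):
        assert bottleneck_distance(make([(0, 2)]), make([(0, 4)])) == 2.0
        assert bottleneck_distance(make([(0, 10)]), make([(1, 9)])) == 1.0

    def test_mixed_infinite_counts_give_infinity(self):
        assert bottleneck_distance(make([(0, INF)]), make([])) == INF

    def test_matches_enumeration_oracle(self):
        """Solver equals exhaustive enumeration on 200 random pairs."""
        rng = np.random.default_rng(42)
        for i in range(200):
            with_inf = bool(i % 2)
            b1 = random_barcode(rng, max_finite=5, with_infinite=with_inf)
            b2 = random_barcode(rng, max_finite=5, with_infinite=with_inf)
            got = bottleneck_distance(make(b1), make(b2))
            want = brute_bottleneck(b1, b2)
            assert got == pytest.approx(want, abs=1e-9)

    def test_metric_axioms_on_random_barcodes(self):
        """Symmetry, identity, triangle inequality (within 1e-9)."""
        rng = np.random.default_rng(7)
        bcs = [make(random_barcode(rng, max_finite=8)) for _ in range(18)]
        n = len(bcs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = bottleneck_distance(bcs[i], bcs[j])
                d[j, i] = bottleneck_distance(bcs[j], bcs[i])
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
        count = 0
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
                    count += 1
        assert count >= 200 * 3

    def test_stability_under_sup_norm_perturbation(self):
        """d_Bot(B(f), B(f+eta)) <= sup|eta| for random signals."""
        rng = np.random.default_rng(11)
        for i in range(100):
            eps = (0.01, 0.1, 1.0)[i % 3]
            f = np.cumsum(rng.standard_normal(50))
            eta = rng.uniform(-eps, eps, size=50)
            B = sublevel_barcode(TimeSeries(values=f))
            Bp = sublevel_barcode(TimeSeries(values=f + eta))
            assert bottleneck_distance(B, Bp) <= eps + 1e-12

    def test_step_mismatch_raises_distance_and_trimming_reduces_it(self):
        """An extra gait cycle inflates the untrimmed distance; trimming
        by each trial's own step count dampens the effect."""
        from topogait.persistence import trim_barcode
        from topogait.synthetic import NoiseSpec, generate_trial

        base = generate_trial(n_cycles=4, noise=NoiseSpec(5.0), seed=3)
        longer = generate_trial(n_cycles=5, noise=NoiseSpec(5.0), seed=3)
        b1, b2 = sublevel_barcode(base), sublevel_barcode(longer)
        d_untrimmed = bottleneck_distance(
            Barcode(b1.finite_bars), Barcode(b2.finite_bars)
        )
        d_trimmed = bottleneck_distance(trim_barcode(b1, 4), trim_barcode(b2, 5))
        d_same = bottleneck_distance(
            Barcode(b1.finite_bars),
            Barcode(sublevel_barcode(
                generate_trial(n_cycles=4, noise=NoiseSpec(5.0), seed=4)
            ).finite_bars),
        )
        assert d_untrimmed > d_same       # step mismatch dominates untrimmed
        assert d_trimmed < d_untrimmed    # trimming removes the mismatch


class TestDistanceMatrix:
    def test_duplicate_barcodes_give_zero_matrix(self):
        B = make([(0, 2), (1, 5)])
        dm = distance_matrix([B, B])
        assert np.array_equal(dm.to_numpy(), np.zeros((2, 2)))

    def test_known_entry(self):
        dm = distance_matrix([make([(0, 2)]), make([])], ["a", "b"])
        assert dm.loc["a", "b"] == 1.0
        assert dm.loc["b", "a"] == 1.0

    def test_matches_oracle_entrywise(self):
        rng = np.random.default_rng(5)
        bars = [random_barcode(rng, max_finite=3, with_infinite=False)
                for _ in range(5)]
        dm = distance_matrix([make(b) for b in bars]).to_numpy()
        for i in range(5):
            for j in range(5):
                assert dm[i, j] == pytest.approx(
                    brute_bottleneck(bars[i], bars[j]), abs=1e-9
                )

    def test_mixed_infinite_counts_warn(self):
        with pytest.warns(UserWarning, match="infinite bottleneck"):
            distance_matrix([make([(0, INF)]), make([(0, 1)])])

    def test_cache_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        bcs = [make(random_barcode(rng)) for _ in range(4)]
        first = distance_matrix(bcs, cache_dir=tmp_path)
        again = distance_matrix(bcs, cache_dir=tmp_path)
        pd.testing.assert_frame_equal(first, again)

    def test_rejects_fewer_than_two(self):
        with pytest.raises(InvalidInputError):
            distance_matrix([make([(0, 1)])])
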