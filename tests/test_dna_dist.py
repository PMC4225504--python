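import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylokit.dna_dist import (
    PairCountsDNA,
    count_pair,
    distance_matrix,
    iter_distance_rows,
    jc_distance,
    k2p_distance,
    p_distance,
    partition_rows,
    tn93_distance,
)
from phylokit.errors import (
    AlignmentShapeError,
    AlphabetError,
    UnsupportedCombinationError,
)
from phylokit.matrix import DistanceMatrix
from phylokit.seqio import Alignment
from phylokit.synthdata import SimulationConfig, evolve_sequences, random_tree

from _reference import count_pair_naive


def counts(valid, matches, ts_ag=0.0, ts_ct=0.0, tv=0.0, freq=None):
    if freq is None:
        freq = np.full(4, valid / 2.0)
    return PairCountsDNA(valid, matches, ts_ag, ts_ct, tv, np.asarray(freq, float))


class TestCountPair:
    def test_hand_categories(self):
        c = count_pair("ACGT", "ACGA")
        assert c.valid_sites == 4
        assert c.matches == 3
        assert c.tv == 1  # T<->A is a transversion

    def test_ambiguous_pair_spreads_uniformly(self):
        c = count_pair("A", "R", ambiguity=True)
        assert c.valid_sites == 1
        assert c.matches == pytest.approx(0.5)
        assert c.ts_AG == pytest.approx(0.5)

    def test_gap_and_n_sites_dropped_without_ambiguity(self):
        c = count_pair("AN-T", "AC-T", ambiguity=False)
        assert c.valid_sites == 2
        assert c.matches == 2

    def test_length_mismatch(self):
        with pytest.raises(AlignmentShapeError):
            count_pair("ACG", "AC")

    def test_non_iupac_symbol(self):
        with pytest.raises(AlphabetError):
            count_pair("AOG", "ACG")

    @pytest.mark.parametrize("ambiguity", [True, False])
    def test_against_per_site_oracle(self, rng, ambiguity):
        symbols = "ACGTRYSWKMBDHVN-"
        for _ in range(5):
            a = "".join(rng.choice(list(symbols), size=200))
            b = "".join(rng.choice(list(symbols), size=200))
            c = count_pair(a, b, ambiguity=ambiguity)
            valid, tallies, freq = count_pair_naive(a, b, ambiguity)
            assert c.valid_sites == pytest.approx(valid)
            assert c.matches == pytest.approx(tallies["match"])
            assert c.ts_AG == pytest.approx(tallies["ts_AG"])
            assert c.ts_CT == pytest.approx(tallies["ts_CT"])
            assert c.tv == pytest.approx(tallies["tv"])
            np.testing.assert_allclose(c.freq, freq)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_category_conservation_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        symbols = list("ACGTRYSWKMBDHVN-")
        a = "".join(r.choice(symbols, size=60))
        b = "".join(r.choice(symbols, size=60))
        for amb in (True, False):
            c = count_pair(a, b, ambiguity=amb)
            assert c.matches + c.ts_AG + c.ts_CT + c.tv == pytest.approx(
                c.valid_sites, abs=1e-9
            )
            assert c.freq.sum() == pytest.approx(2 * c.valid_sites, abs=1e-9)
            d = count_pair(b, a, ambiguity=amb)
            assert d.matches == pytest.approx(c.matches)
            assert d.tv == pytest.approx(c.tv)
            assert d.ts_AG == pytest.approx(c.ts_AG)

    def test_unambiguous_input_identical_across_modes(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = "".join(rng.choice(list("ACGT"), size=500))
        c1 = count_pair(a, b, ambiguity=True)
        c2 = count_pair(a, b, ambiguity=False)
        assert (c1.valid_sites, c1.matches, c1.ts_AG, c1.ts_CT, c1.tv) == (
            c2.valid_sites, c2.matches, c2.ts_AG, c2.ts_CT, c2.tv
        )


class TestEstimators:
    def test_p_distance_values(self):
        assert p_distance(counts(4, 4)) == 0.0
        assert p_distance(counts(4, 3, tv=1.0)) == 0.25

    def test_p_distance_no_overlap_is_nan(self):
        assert math.isnan(p_distance(counts(0, 0, freq=np.zeros(4))))

    def test_jc_closed_form(self):
        assert jc_distance(counts(4, 4)) == 0.0
        c = counts(4, 3, tv=1.0)
        assert jc_distance(c) == pytest.approx(0.30409883108112329, rel=1e-12)

    def test_jc_saturation(self):
        assert math.isnan(jc_distance(counts(4, 1, tv=3.0)))  # p = 0.75

    def test_k2p_closed_form(self):
        c = counts(100, 85, ts_ag=10.0, tv=5.0)  # P=0.1, Q=0.05
        assert k2p_distance(c) == pytest.approx(0.17018116514034704, rel=1e-12)
        assert k2p_distance(counts(10, 10)) == 0.0

    def test_k2p_reduces_to_jc(self):
        # with P = p/3 and Q = 2p/3 the K2P formula collapses to JC
        for p in np.linspace(0.01, 0.74, 25):
            c = counts(300, 300 * (1 - p), ts_ag=300 * p / 3, tv=300 * 2 * p / 3)
            assert k2p_distance(c) == pytest.approx(jc_distance(c), rel=1e-10)

    def test_tn93_identical_sequences(self):
        c = count_pair("ACGTACGT", "ACGTACGT")
        assert tn93_distance(c) == pytest.approx(0.0, abs=1e-12)

    def test_tn93_reduces_to_k2p_under_uniform_frequencies(self):
        for P, Q in [(0.05, 0.02), (0.1, 0.05), (0.2, 0.1), (0.02, 0.2)]:
            n = 1000.0
            c = counts(
                n,
                n * (1 - P - Q),
                ts_ag=n * P / 2,
                ts_ct=n * P / 2,
                tv=n * Q,
                freq=np.full(4, n / 2),
            )
            assert tn93_distance(c) == pytest.approx(k2p_distance(c), rel=1e-10)

    @pytest.mark.parametrize(
        "est", [p_distance, jc_distance, k2p_distance, tn93_distance]
    )
    def test_monotone_in_difference_proportion(self, est):
        # each estimator increases in its own difference proportions
        prev = -1.0
        for p in np.linspace(0.0, 0.6, 13):
            n = 600.0
            c = counts(
                n,
                n * (1 - p),
                ts_ag=n * p / 4,
                ts_ct=n * p / 4,
                tv=n * p / 2,
                freq=np.full(4, n / 2),
            )
            d = est(c)
            assert d > prev or (p == 0.0 and d == 0.0)
            prev = d


class TestSimulationConsistency:
    @pytest.mark.parametrize(
        "model,estimator",
        [("jc", jc_distance), ("k2p", k2p_distance), ("tn93", tn93_distance)],
    )
    def test_estimator_recovers_true_distance(self, model, estimator):
        # two taxa at true distance 0.3, long sequences: the estimate must sit
        # within 3 Monte-Carlo standard errors of the truth
        d_true = 0.3
        reps = 8
        estimates = []
        for rep in range(reps):
            cfg = SimulationConfig(
                n_taxa=2, seq_length=100_000, seed=1000 + rep, model=model,
            )
            tree = random_tree(cfg)
            # force the exact true distance on the single edge
            tree.root.children[0].length = d_true / 2
            tree.root.children[1].length = d_true / 2
            aln = evolve_sequences(tree, cfg)
            estimates.append(estimator(count_pair(aln.rows[0], aln.rows[1])))
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / math.sqrt(reps)
        assert abs(estimates.mean() - d_true) < 3 * max(se, 1e-4)


class TestMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3, "dna")
        m = distance_matrix(aln)
        np.testing.assert_array_equal(m.values, np.zeros((3, 3)))

    def test_default_model_is_k2p(self):
        cfg = SimulationConfig(n_taxa=6, seq_length=300, seed=9)
        aln = evolve_sequences(random_tree(cfg), cfg)
        assert distance_matrix(aln) == distance_matrix(aln, model="k2p")

    def test_streamed_rows_match_in_memory_bitwise(self):
        cfg = SimulationConfig(n_taxa=40, seq_length=400, seed=4)
        aln = evolve_sequences(random_tree(cfg), cfg)
        full = distance_matrix(aln, ambiguity=False)
        collected = {}
        distance_matrix(
            aln, ambiguity=False,
            row_sink=lambda i, row: collected.__setitem__(i, row.copy()),
        )
        streamed = DistanceMatrix.from_upper_rows(
            aln.taxa, [collected[i] for i in range(len(aln.taxa) - 1)]
        )
        # bit-for-bit equality (NaN marks saturated entries in both modes)
        assert np.array_equal(full.values, streamed.values, equal_nan=True)

    def test_streaming_with_ambiguity_rejected(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"], "dna")
        with pytest.raises(UnsupportedCombinationError):
            distance_matrix(aln, ambiguity=True, row_sink=lambda i, r: None)

    def test_saturation_substitution(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"], "dna")
        m = distance_matrix(aln, model="jc")
        assert math.isnan(m.values[0, 1])
        rows = list(iter_distance_rows(aln, model="jc", saturation_distance=9.9))
        assert rows[0][0] == 9.9


class TestPartitionRows:
    def test_single_block(self):
        assert partition_rows(4, 1) == [(0, 4)]

    def test_cover_and_disjoint(self):
        parts = partition_rows(10, 3)
        covered = [i for lo, hi in parts for i in range(lo, hi)]
        assert covered == list(range(10))

    def test_workload_balance(self):
        n, blocks = 1000, 8
        parts = partition_rows(n, blocks)
        loads = [sum(n - 1 - i for i in range(lo, hi)) for lo, hi in parts]
        assert max(loads) - min(loads) <= n - 1  # within one largest row
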