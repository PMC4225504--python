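import math

import numpy as np
import pytest
import scipy.linalg

from phylokit.errors import PhylokitError
from phylokit.matrix import DistanceMatrix
from phylokit.prot_dist import (
    DistancePrior,
    ESTIMATOR_NAMES,
    MODEL_NAMES,
    count_pair_protein,
    default_prior,
    expected_distance,
    jc20_distance,
    kimura_protein_distance,
    load_model,
    ml_distance,
    pair_log_likelihood,
    protein_distance_matrix,
)
from phylokit.seqio import AMINO_ACIDS, Alignment
from phylokit.synthdata import SimulationConfig, evolve_sequences, random_tree


def grid_search_argmax(c, m, lo=1e-6, hi=10.0, points=10_000) -> float:
    """Independent grid-search oracle for the ML distance: a 10^4-point
    coarse pass followed by a refining pass inside the bracketing cell."""
    grid = np.geomspace(lo, hi, points)
    ll = np.array([pair_log_likelihood(c, m, g) for g in grid])
    k = int(np.argmax(ll))
    lo2 = grid[max(k - 1, 0)]
    hi2 = grid[min(k + 1, points - 1)]
    fine = np.linspace(lo2, hi2, points)
    ll2 = np.array([pair_log_likelihood(c, m, g) for g in fine])
    return float(fine[int(np.argmax(ll2))])


def simulate_pair(d: float, seed: int, length: int = 350, model: str = "wag"):
    cfg = SimulationConfig(
        n_taxa=2, seq_length=length, seed=seed, model=model,
    )
    tree = random_tree(cfg)
    tree.root.children[0].length = d / 2
    tree.root.children[1].length = d / 2
    aln = evolve_sequences(tree, cfg)
    return count_pair_protein(aln.rows[0], aln.rows[1])


class TestCounting:
    def test_hand_counts(self):
        c = count_pair_protein("AR", "AR")
        a, r = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("R")
        assert c.table[a, a] == 1 and c.table[r, r] == 1
        assert c.valid_sites == 2

    def test_gap_and_x_excluded(self):
        c = count_pair_protein("A-X", "AAA")
        assert c.valid_sites == 1

    def test_against_per_site_oracle(self, rng):
        a = "".join(rng.choice(list(AMINO_ACIDS + "X-"), size=350))
        b = "".join(rng.choice(list(AMINO_ACIDS + "X-"), size=350))
        c = count_pair_protein(a, b)
        expect = np.zeros((20, 20))
        for x, y in zip(a, b):
            if x in AMINO_ACIDS and y in AMINO_ACIDS:
                expect[AMINO_ACIDS.index(x), AMINO_ACIDS.index(y)] += 1
        np.testing.assert_array_equal(c.table, expect)


class TestModels:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_generator_invariants(self, name):
        m = load_model(name)
        Q, pi = m.generator, m.frequencies
        flux = pi[:, None] * Q
        assert abs(flux - flux.T).max() < 1e-10  # detailed balance
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -pi @ np.diag(Q) == pytest.approx(1.0, abs=1e-12)
        lam = m.eigenvalues
        assert lam.max() == pytest.approx(0.0, abs=1e-10)
        assert (lam <= 1e-10).all()
        assert (np.abs(lam) < 1e-8).sum() == 1  # exactly one zero eigenvalue

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_spectral_reconstruction(self, name):
        m = load_model(name)
        rebuilt = (m._left * m.eigenvalues) @ m._right
        assert abs(rebuilt - m.generator).max() < 1e-10

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_transition_matrix_stochastic_and_semigroup(self, name):
        m = load_model(name)
        for d in (0.01, 0.1, 1.0, 10.0):
            P = m.transition_matrix(d)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12
        s, t = 0.37, 0.81
        assert abs(
            m.transition_matrix(s + t) - m.transition_matrix(s) @ m.transition_matrix(t)
        ).max() < 1e-8

    def test_long_time_limit_is_stationary(self):
        m = load_model("lg")
        P = m.transition_matrix(300.0)
        np.testing.assert_allclose(P, np.tile(m.frequencies, (20, 1)), atol=1e-8)


class TestLikelihood:
    def test_identity_at_zero_distance(self):
        c = count_pair_protein("ARNDC", "ARNDC")
        pi = load_model("wag").frequencies
        expect = sum(math.log(pi[AMINO_ACIDS.index(x)]) for x in "ARNDC")
        assert pair_log_likelihood(c, load_model("wag"), 0.0) == pytest.approx(expect)

    def test_matches_independent_expm_oracle(self):
        m = load_model("wag")
        c = simulate_pair(0.7, seed=42)
        d = 0.7
        P = scipy.linalg.expm(m.generator * d)
        expect = float(np.sum(c.table * np.log(m.frequencies[:, None] * P)))
        assert pair_log_likelihood(c, m, d) == pytest.approx(expect, abs=1e-8)

    def test_negative_distance_rejected(self):
        c = count_pair_protein("AR", "AR")
        with pytest.raises(PhylokitError):
            pair_log_likelihood(c, load_model("wag"), -0.1)


class TestMlDistance:
    def test_identical_pair_returns_d_min(self):
        c = simulate_pair(1e-9, seed=7)
        m = load_model("wag")
        d, status = ml_distance(c, m, full_output=True)
        assert d == pytest.approx(1e-6)
        assert status in ("identical", "minimum")

    @pytest.mark.parametrize("d_true,seed", [(0.1, 1), (0.5, 2), (1.0, 3), (2.5, 4)])
    def test_matches_grid_search_oracle(self, d_true, seed):
        m = load_model("wag")
        c = simulate_pair(d_true, seed=seed)
        d = ml_distance(c, m)
        assert abs(d - grid_search_argmax(c, m)) <= 1e-4

    @pytest.mark.parametrize("d_true", [0.1, 0.5, 1.0])
    def test_parameter_recovery(self, d_true):
        m = load_model("wag")
        reps = 60
        est = np.array(
            [ml_distance(simulate_pair(d_true, seed=10_000 + r), m) for r in range(reps)]
        )
        se = est.std(ddof=1) / math.sqrt(reps)
        assert abs(est.mean() - d_true) < 3 * se


class TestExpectedDistance:
    def test_symmetric_two_point_prior(self):
        # equal likelihoods at both support points -> posterior mean is midpoint
        c = count_pair_protein("A", "A")
        m = load_model("wag")
        d1, d2 = 0.2, 0.4
        l1 = pair_log_likelihood(c, m, d1)
        l2 = pair_log_likelihood(c, m, d2)
        # single identical site: likelihood pi_A * P_AA(d), decreasing in d;
        # reweight the prior so the two posterior terms are equal
        w1 = 1.0
        w2 = math.exp(l1 - l2)
        prior = DistancePrior(np.array([d1, d2]), np.array([w1, w2]))
        assert expected_distance(c, m, prior) == pytest.approx((d1 + d2) / 2, rel=1e-9)

    def test_posterior_concentrates_on_ml(self):
        m = load_model("wag")
        c = simulate_pair(0.3, seed=77, length=10_000)
        assert abs(expected_distance(c, m) - ml_distance(c, m)) < 0.01

    def test_matches_fine_grid_oracle(self):
        m = load_model("wag")
        c = simulate_pair(0.5, seed=5)
        prior = default_prior()
        # independent dense evaluation of the same quadrature
        ll = np.array([pair_log_likelihood(c, m, d) for d in prior.grid])
        w = prior.weights * np.exp(ll - ll.max())
        expect = float((prior.grid * w).sum() / w.sum())
        assert expected_distance(c, m, prior) == pytest.approx(expect, abs=1e-10)
        assert expected_distance(c, m, prior) >= 0

    def test_support_extension_monotone_for_saturated_pair(self):
        # a deeply saturated pair: widening a flat prior's support upward
        # never decreases the posterior mean
        m = load_model("wag")
        c = simulate_pair(6.0, seed=13, length=80)
        prev = 0.0
        for d_max in (5.0, 10.0, 20.0):
            prior = default_prior(n_points=300, d_max=d_max)
            e = expected_distance(c, m, prior)
            assert e >= prev - 1e-9
            prev = e


class TestCorrections:
    def test_zero_at_zero(self):
        assert jc20_distance(0.0) == 0.0
        assert kimura_protein_distance(0.0) == 0.0

    def test_closed_form_values(self):
        assert jc20_distance(0.5) == pytest.approx(0.70985368173871, rel=1e-12)
        assert kimura_protein_distance(0.5) == pytest.approx(0.79850769621777, rel=1e-12)

    def test_saturation(self):
        assert math.isnan(jc20_distance(0.96))
        assert math.isnan(kimura_protein_distance(0.999))


class TestMatrix:
    def test_exactly_seven_estimator_names(self):
        assert len(ESTIMATOR_NAMES) == 7
        assert set(ESTIMATOR_NAMES) == {"jc", "jck", "wag", "jtt", "day", "mvr", "lg"}

    def test_unknown_estimator_lists_valid_names(self):
        aln = Alignment(["a", "b"], ["AR", "AR"], "protein")
        with pytest.raises(PhylokitError, match="jck"):
            protein_distance_matrix(aln, estimator="blosum")

    @pytest.mark.parametrize("est", ["jc", "jck"])
    def test_zero_matrix_for_identical_sequences(self, est):
        aln = Alignment(["a", "b", "c"], ["ARNDC"] * 3, "protein")
        m = protein_distance_matrix(aln, estimator=est)
        np.testing.assert_array_equal(m.values, np.zeros((3, 3)))

    def test_streamed_matches_in_memory(self):
        cfg = SimulationConfig(n_taxa=12, seq_length=200, seed=21, model="lg")
        aln = evolve_sequences(random_tree(cfg), cfg)
        full = protein_distance_matrix(aln, estimator="lg", method="ml")
        collected = {}
        protein_distance_matrix(
            aln, estimator="lg", method="ml",
            row_sink=lambda i, row: collected.__setitem__(i, row.copy()),
        )
        streamed = DistanceMatrix.from_upper_rows(
            aln.taxa, [collected[i] for i in range(len(aln.taxa) - 1)]
        )
        assert np.array_equal(full.values, streamed.values, equal_nan=True)
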