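import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import triplet_hawkes as th
from triplet_hawkes import motifs
from triplet_hawkes.networks import StabilityError


PAPER = th.RegularParams(n=1000, n_e=800, n_i=200, p=0.1, g_e=0.015, g_i=-0.075)


def _random_valid_params(rng):
    n = int(rng.integers(50, 3000))
    n_e = int(rng.integers(1, n))
    p = float(rng.uniform(0.01, 0.5))
    g_e = float(rng.uniform(0.001, 0.1))
    g_i = float(-rng.uniform(0.001, 0.5))
    params = th.RegularParams(n=n, n_e=n_e, n_i=n - n_e, p=p, g_e=g_e, g_i=g_i)
    if params.n * th.mu_common_input(params, 1) >= 0.99:
        return None
    return params


class TestCommonInput:
    def test_reference_values(self):
        assert th.mu_common_input(PAPER, 1) == pytest.approx(-3.0e-4, rel=1e-12)
        assert th.mu_common_input(PAPER, 2) == pytest.approx(1.305e-4, rel=1e-12)

    def test_parity_of_signs_when_inhibition_dominated(self):
        assert PAPER.is_inhibition_dominated()
        for k in range(1, 9):
            mu = th.mu_common_input(PAPER, k)
            assert (mu < 0) == (k % 2 == 1)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            th.mu_common_input(PAPER, 0)


class TestLambdaBar:
    def test_no_recurrence(self):
        params = th.RegularParams(n=100, n_e=80, n_i=20, p=0.0,
                                  g_e=0.015, g_i=-0.075)
        assert th.lambda_bar(params) == 1.0

    def test_reference_value(self):
        assert th.lambda_bar(PAPER) == pytest.approx(1 / 1.3, rel=1e-12)

    def test_vanishes_for_large_networks(self):
        vals = [th.lambda_bar(th.RegularParams(n=n, n_e=int(0.8 * n),
                                               n_i=n - int(0.8 * n), p=0.1,
                                               g_e=0.015, g_i=-0.075))
                for n in (1000, 10_000, 100_000)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.05

    def test_stability_error(self):
        params = th.RegularParams(n=1000, n_e=1000, n_i=0, p=0.1,
                                  g_e=0.02, g_i=-0.075)  # N mu1 = 2
        with pytest.raises(StabilityError):
            th.lambda_bar(params)


class TestAggregateClosedForms:
    def test_zero_weights_vanish(self):
        params = th.RegularParams(n=100, n_e=80, n_i=20, p=0.0,
                                  g_e=1e-12, g_i=-1e-12)
        total, terms = th.kbar3_regular(params)
        assert total == 0.0 and all(v == 0.0 for v in terms.values())

    def test_identity_with_simplified_form(self):
        """The six-term aggregate and its rearranged form are algebraically
        identical over randomized valid parameter draws."""
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 1000:
            params = _random_valid_params(rng)
            if params is None:
                continue
            total, _ = th.kbar3_regular(params)
            simplified = th.kbar3_simplified(params)
            assert total == pytest.approx(simplified, rel=1e-12, abs=1e-300)
            checked += 1

    def test_quadratic_term_is_t6(self):
        total, terms = th.kbar3_regular(PAPER)
        assert th.ktilde3(PAPER) == pytest.approx(terms["T6"], rel=1e-12)

    def test_quadratic_approximation_improves_with_n(self):
        for p in (0.05, 0.1, 0.2):
            gaps = []
            for n in (256, 512, 1024, 2048):
                params = th.RegularParams(n=n, n_e=int(0.8 * n),
                                          n_i=n - int(0.8 * n), p=p,
                                          g_e=0.015, g_i=-0.075)
                total, _ = th.kbar3_regular(params)
                gaps.append(abs(th.ktilde3(params) / total - 1.0))
            assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestTreeShapes:
    def test_structural_invariants(self):
        mults = [th.TREE_SHAPES[f"T{i}"].multiplicity for i in range(1, 7)]
        assert mults == [1, 3, 3, 6, 6, 3]
        for shape in th.TREE_SHAPES.values():
            assert shape.n_branches == shape.n_nodes - 1
            assert sum(shape.internal_out_degrees) == shape.n_branches

    def test_branch_lengths_validation(self):
        with pytest.raises(ValueError):
            th.BranchLengths((1, 0))
        assert th.BranchLengths((2, 3)).total == 5


class TestTreeTermRegular:
    def test_t2_reference_value(self):
        term = th.tree_term_regular(PAPER, "T2", (1, 1))
        # 3 * (lbar/N^3) * N^3 * p * mu2
        expected = 3 * (1 / 1.3) * 0.1 * 1.305e-4
        assert term.value == pytest.approx(expected, rel=1e-10)
        assert term.predicted_sign == 1

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            th.tree_term_regular(PAPER, "T2", (1, 1, 1))

    def test_decay_with_total_length(self):
        vals = [abs(th.tree_term_regular(PAPER, "T6", (l, 1, 1, 1)).value)
                for l in range(1, 12)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # each extra unit of length multiplies by |N mu^(1)| < 1
        np.testing.assert_allclose(np.array(vals[1:]) / np.array(vals[:-1]),
                                   0.3, rtol=1e-9)

    def test_single_length_increment_flips_sign(self):
        base = th.tree_term_regular(PAPER, "T3", (1, 1, 1)).value
        bumped = th.tree_term_regular(PAPER, "T3", (2, 1, 1)).value
        assert np.sign(base) == -np.sign(bumped)

    def test_resummation_converges_to_geometric_total(self):
        """Explicit sums over length tuples converge geometrically (ratio
        |N mu^(1)| per unit of extra length) to the analytic resummation."""
        for sid in th.TREE_SHAPES:
            total = motifs.tree_series_total(PAPER, sid)
            partial = motifs.tree_series_partial(PAPER, sid, max_total=20)
            assert partial == pytest.approx(total, rel=1e-5)
            shorter = motifs.tree_series_partial(PAPER, sid, max_total=10)
            assert abs(total - partial) < abs(total - shorter)


class TestSignRule:
    @pytest.mark.parametrize("sid", list(th.TREE_SHAPES))
    def test_sign_rule_matches_closed_form(self, sid):
        """Parity rule (odd internal out-degrees, total branch length)
        predicts the sign of every fixed-length contribution, for all
        tuples with total length <= 6 under inhibition-dominated weights."""
        shape = th.TREE_SHAPES[sid]
        nb = shape.n_branches
        for tup in itertools.product(range(1, 7), repeat=nb):
            if sum(tup) > 6:
                continue
            term = th.tree_term_regular(PAPER, sid, tup)
            assert np.sign(term.value) == term.predicted_sign
            predicted = th.tree_sign(shape, th.BranchLengths(tup), PAPER)
            assert predicted == term.predicted_sign

    def test_t2_and_t5_minimal_tuples_positive(self):
        assert th.tree_sign(th.TREE_SHAPES["T2"], th.BranchLengths((1, 1)),
                            PAPER) == 1
        assert th.tree_sign(th.TREE_SHAPES["T5"], th.BranchLengths((1, 1)),
                            PAPER) == 1

    def test_non_inhibition_dominated_path(self):
        params = th.RegularParams(n=100, n_e=90, n_i=10, p=0.05,
                                  g_e=0.02, g_i=-0.01)  # excitation-dominated
        assert not params.is_inhibition_dominated()
        for sid in th.TREE_SHAPES:
            shape = th.TREE_SHAPES[sid]
            tup = (1,) * shape.n_branches
            term = th.tree_term_regular(params, sid, tup)
            assert np.sign(term.value) == th.tree_sign(
                shape, th.BranchLengths(tup), params)


class TestTreeTermMatrix:
    def test_zero_matrix_vanishes(self):
        net = th.WeightedNetwork(np.zeros((8, 8)), th.NeuronTypes.block(8, 0),
                                 1.0, -1.0)
        rates = th.stationary_rates(net)
        for sid, shape in th.TREE_SHAPES.items():
            assert th.tree_term_matrix(net, rates, sid,
                                       (1,) * shape.n_branches) == 0.0

    def test_matches_einsum_oracle_on_tiny_matrix(self):
        """Contraction-based evaluation equals a literal einsum over all
        node labels, for every shape, length tuple and root weighting."""
        rng = np.random.default_rng(6)
        n = 7
        g = rng.normal(0.0, 0.1, (n, n))
        np.fill_diagonal(g, 0.0)
        net = th.WeightedNetwork(g, th.NeuronTypes.block(n, 0), 1.0, -1.0)
        rates = th.stationary_rates(net)
        mp = np.linalg.matrix_power
        specs = {
            "T1": ("im,jm,km,m->", 3),
            "T2": ("ik,jk,k->", 2),
            "T3": ("im,jm,mk,k->", 3),
            "T4": ("ij,jn,kn,n->", 3),
            "T5": ("ij,jk,k->", 2),
            "T6": ("im,jm,mn,kn,n->", 4),
        }
        order = {"T6": (0, 1, 3, 2)}  # operand order vs length-tuple order
        for sid, (pattern, nb) in specs.items():
            shape = th.TREE_SHAPES[sid]
            for tup in [(1,) * nb, (2, 1) + (1,) * (nb - 2), (1, 2) + (2,) * (nb - 2)]:
                ls = list(tup)
                if sid in order:
                    ops = [mp(g, ls[i]) for i in order[sid]]
                else:
                    ops = [mp(g, l) for l in ls]
                for root_weighted in (False, True):
                    root = rates if root_weighted else np.ones(n)
                    bracket = np.einsum(pattern, *ops, root)
                    weight = 1.0 if root_weighted else rates.mean()
                    expected = shape.multiplicity * weight * bracket / n ** 3
                    got = th.tree_term_matrix(net, rates, sid, tup,
                                              root_weighted=root_weighted)
                    assert got == pytest.approx(expected, rel=1e-10, abs=1e-15)

    def test_single_type_regular_t2_identity(self):
        """On a K-regular single-type network the T2 bracket collapses to
        N (K g)^(l1+l2) exactly."""
        params = th.RegularParams(n=30, n_e=30, n_i=0, p=0.2, g_e=0.04, g_i=-1.0)
        net = th.generate_regular(params, seed=3)  # K = 6
        rates = th.stationary_rates(net)
        kg = 6 * 0.04
        lbar = rates.mean()
        for l1, l2 in [(1, 1), (2, 1), (2, 3)]:
            expected = 3 * lbar / 30 ** 3 * 30 * kg ** (l1 + l2)
            assert th.tree_term_matrix(net, rates, "T2", (l1, l2)) == \
                pytest.approx(expected, rel=1e-10)

    def test_unstable_matrix_finite_lengths_allowed(self):
        """Fixed-length brackets are polynomials in G, so they remain valid
        on matrices whose own dynamics are unstable (the assortative-hub
        use case); a scalar homogeneous root weight must be supplied."""
        g = np.array([[0.0, 1.2], [1.2, 0.0]])
        net = th.WeightedNetwork(g, th.NeuronTypes.block(2, 0), 1.2, -1.0)
        assert net.spectral_radius() > 1.0
        val = th.tree_term_matrix(net, 0.5, "T2", (1, 1))
        # bracket = sum_k (colsum G)_k^2 = 2 * 1.2^2; x 3 * 0.5 / 8
        assert val == pytest.approx(3 * 0.5 * 2 * 1.2 ** 2 / 8, rel=1e-12)

    def test_matrix_power_overflow_raises(self):
        g = np.array([[0.0, 3.0], [3.0, 0.0]])
        net = th.WeightedNetwork(g, th.NeuronTypes.block(2, 0), 3.0, -1.0)
        with pytest.raises(StabilityError, match="overflow"):
            th.tree_term_matrix(net, 0.5, "T2", (400, 400))

    def test_root_weighted_requires_vector(self):
        g = np.zeros((3, 3))
        net = th.WeightedNetwork(g, th.NeuronTypes.block(3, 0), 1.0, -1.0)
        with pytest.raises(ValueError, match="rate vector"):
            th.tree_term_matrix(net, 1.0, "T2", (1, 1), root_weighted=True)


class TestExpectedTreeCount:
    def test_small_enumeration_value(self):
        assert th.expected_tree_count(4, 0.5, 2) == pytest.approx(3.0)

    def test_single_node(self):
        assert th.expected_tree_count(7, 0.3, 1) == 7

    def test_grows_for_small_k(self):
        # The count C(N,k) p^(k-1) (1-p)^(C(k,2)-k+1) grows while the
        # binomial and p^(k-1) factors dominate the vacancy factor; at
        # N=1000, p=0.1 that holds for the first dozen sizes.  (It cannot
        # grow all the way to N/2: the (1-p)^C(k,2) factor eventually wins.)
        vals = [th.expected_tree_count(1000, 0.1, k) for k in range(1, 13)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            th.expected_tree_count(10, 0.1, 0)


def test_motif_diagnostics_surfaces_convention_gap(small_er_net):
    """The aggregate closed form and the per-tree resummation are different
    conventions; the diagnostic must expose both plus the exact matrix value."""
    params, net = small_er_net
    report = th.motif_diagnostics(params, net=net)
    assert set(report) >= {"kbar3_aggregate", "kbar3_simplified", "ktilde3",
                           "kbar3_tree_resummation", "kbar3_matrix_exact"}
    assert report["kbar3_aggregate"] == pytest.approx(
        report["kbar3_simplified"], rel=1e-12)
    # the two conventions genuinely disagree for inhibition-dominated weights
    assert report["kbar3_aggregate"] != pytest.approx(
        report["kbar3_tree_resummation"], rel=0.01)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_aggregate_identity_property(seed):
    rng = np.random.default_rng(seed)
    params = _random_valid_params(rng)
    if params is None:
        return
    total, _ = th.kbar3_regular(params)
    assert total == pytest.approx(th.kbar3_simplified(params), rel=1e-12,
                                  abs=1e-300)
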