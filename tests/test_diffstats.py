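"""Edge-wise paired tests, FDR decisions, hub identification."""

import numpy as np
import pytest

from cohnet import (
    differential_network,
    edgewise_paired_test,
    fdr_correct,
    identify_hubs,
    network_property_tests,
)
from cohnet.design import CHANNELS_10_20
from cohnet.diffstats import PairedCoherenceTest

from conftest import make_matrix


def matrices_from_edge_values(values_per_subject, n_nodes=4):
    """Build per-subject CoherenceMatrix dicts with edge (0,1) set per subject."""
    out = {}
    for s, v in enumerate(values_per_subject, start=1):
        m = np.full((n_nodes, n_nodes), 0.3)
        np.fill_diagonal(m, 1.0)
        m[0, 1] = m[1, 0] = v
        out[s] = make_matrix(m)
    return out


def paired_t_closed_form(diffs):
    """Textbook paired t: mean(d) / (sd(d)/sqrt(n))."""
    d = np.asarray(diffs, float)
    return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))


def bh_stepup(pvals, alpha=0.05):
    """Hand step-up enumeration of Benjamini-Hochberg decisions."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = len(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestEdgewisePairedTest:
    def test_identical_sessions_nothing_significant(self):
        s1 = matrices_from_edge_values([0.3, 0.4, 0.5, 0.35])
        with pytest.warns(UserWarning, match="zero difference variance"):
            t, p, labels = edgewise_paired_test(s1, s1)
        np.testing.assert_array_equal(t, 0.0)
        assert (p[np.triu_indices(4, 1)] == 1.0).all()
        assert fdr_correct(p).sum() == 0

    def test_matches_closed_form_paired_t(self):
        diffs = [0.1, 0.2, 0.15, 0.05, 0.1]
        base = [0.3, 0.32, 0.31, 0.29, 0.3]
        s1 = matrices_from_edge_values(base)
        s2 = matrices_from_edge_values([b + d for b, d in zip(base, diffs)])
        with pytest.warns(UserWarning):  # untouched edges have zero variance
            t, p, _ = edgewise_paired_test(s1, s2)
        assert t[0, 1] == pytest.approx(paired_t_closed_form(diffs))
        assert t[1, 0] == t[0, 1]

    def test_large_effect_edge_has_minimum_p(self):
        rng = np.random.default_rng(8)
        n = 6
        s1, s2 = {}, {}
        for s in range(1, 21):
            base = 0.3 + 0.02 * rng.standard_normal((n, n))
            base = (base + base.T) / 2
            np.fill_diagonal(base, 1.0)
            follow = base + 0.02 * rng.standard_normal((n, n))
            follow = (follow + follow.T) / 2
            follow[0, 1] = follow[1, 0] = base[0, 1] + 0.1  # d >> 1 on one edge
            np.fill_diagonal(follow, 1.0)
            s1[s] = make_matrix(np.clip(base, 0, 1))
            s2[s] = make_matrix(np.clip(follow, 0, 1))
        t, p, _ = edgewise_paired_test(s1, s2)
        iu = np.triu_indices(n, 1)
        assert p[0, 1] == p[iu].min()

    def test_subject_mismatch_fails_with_listing(self):
        s1 = matrices_from_edge_values([0.3, 0.4, 0.5])
        s2 = matrices_from_edge_values([0.3, 0.4, 0.5, 0.6])
        with pytest.raises(ValueError, match=r"only in session 2: \[4\]"):
            edgewise_paired_test(s1, s2)


class TestFDR:
    def test_all_ones_empty_network(self):
        p = np.ones((5, 5))
        assert fdr_correct(p).sum() == 0

    def test_all_tiny_complete_network(self):
        p = np.full((5, 5), 0.001)
        adj = fdr_correct(p)
        assert adj.sum() == 5 * 4  # complete undirected, counted both ways

    @pytest.mark.parametrize("seed", range(5))
    def test_bh_matches_stepup_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 5  # 10 unique edges
        pv = np.concatenate([[0.001, 0.01, 0.02, 0.03, 0.2],
                             rng.uniform(0.05, 1.0, 5)])
        rng.shuffle(pv)
        pmat = np.ones((n, n))
        iu = np.triu_indices(n, 1)
        pmat[iu] = pv
        pmat[(iu[1], iu[0])] = pv
        adj = fdr_correct(pmat, 0.05, "bh")
        np.testing.assert_array_equal(adj[iu].astype(bool), bh_stepup(pv))

    def test_by_variant_is_more_conservative(self):
        rng = np.random.default_rng(11)
        pv = rng.uniform(0.001, 0.2, 10)
        pmat = np.ones((5, 5))
        iu = np.triu_indices(5, 1)
        pmat[iu] = pv
        pmat[(iu[1], iu[0])] = pv
        assert fdr_correct(pmat, 0.05, "by").sum() <= fdr_correct(pmat, 0.05, "bh").sum()


class TestHubs:
    def test_equal_degrees_yield_no_hubs(self):
        hubs, _ = identify_hubs(np.array([3, 3, 3, 3]), list("abcd"))
        assert hubs == ()

    def test_star_center_is_unique_hub(self):
        hubs, _ = identify_hubs(np.array([3, 1, 1, 1]), ["hub", "a", "b", "c"])
        assert hubs == ("hub",)

    def test_published_theta_degrees_give_frontal_hubs(self):
        degrees = np.array([7, 6, 1, 10, 15, 12, 4, 5, 5, 2, 2, 5, 4, 4, 6, 2, 5, 2, 3])
        hubs, cutoff = identify_hubs(degrees, CHANNELS_10_20)
        assert set(hubs) == {"F3", "Fz", "F4"}
        assert cutoff == pytest.approx(degrees.mean() + degrees.std(ddof=1))

    def test_explicit_cutoff_rule(self):
        hubs, cutoff = identify_hubs(np.array([5, 8, 2, 8]), list("abcd"), rule=8)
        assert hubs == ("b", "d") and cutoff == 8.0

    def test_hub_set_invariant_under_relabeling(self):
        rng = np.random.default_rng(4)
        degrees = rng.integers(0, 10, 12)
        labels = [f"n{i}" for i in range(12)]
        perm = rng.permutation(12)
        hubs1, _ = identify_hubs(degrees, labels)
        hubs2, _ = identify_hubs(degrees[perm], [labels[i] for i in perm])
        assert set(hubs1) == set(hubs2)

    def test_empty_network_has_no_hubs(self):
        hubs, _ = identify_hubs(np.zeros(5), list("abcde"))
        assert hubs == ()


class TestDifferentialNetwork:
    def test_symmetry_and_consistency_of_outputs(self):
        rng = np.random.default_rng(21)
        s1, s2 = {}, {}
        for s in range(1, 11):
            a = 0.3 + 0.03 * rng.standard_normal((5, 5))
            b = a + 0.03 * rng.standard_normal((5, 5))
            a, b = (a + a.T) / 2, (b + b.T) / 2
            np.fill_diagonal(a, 1.0)
            np.fill_diagonal(b, 1.0)
            s1[s] = make_matrix(np.clip(a, 0, 1))
            s2[s] = make_matrix(np.clip(b, 0, 1))
        dn = differential_network(s1, s2, band="alpha")
        np.testing.assert_array_equal(dn.significant, dn.significant.T)
        np.testing.assert_array_equal(dn.t_values, dn.t_values.T)
        assert (np.diag(dn.significant) == 0).all()
        np.testing.assert_array_equal(dn.node_degrees, dn.significant.sum(axis=0))
        for a_, b_ in dn.significant_edges():
            i, j = dn.node_labels.index(a_), dn.node_labels.index(b_)
            assert dn.p_values[i, j] < 0.05

    def test_estimator_wrapper_exposes_fitted_attributes(self):
        s1 = matrices_from_edge_values([0.3, 0.35, 0.4, 0.32, 0.38])
        s2 = matrices_from_edge_values([0.45, 0.5, 0.55, 0.47, 0.52])
        with pytest.warns(UserWarning):
            est = PairedCoherenceTest(band="theta").fit((s1, s2))
        assert est.significant_.shape == (4, 4)
        assert est.network_.band == "theta"
        assert est.get_params()["alpha_level"] == 0.05


class TestNetworkPropertyTests:
    def make_metrics(self, lp, cc):
        return {"Lp": lp, "Eg": 1 / lp, "CC": cc, "Eloc": cc, "Deg": 5.0,
                "gamma": 1.0, "lambda": 1.0, "sigma": 1.0}

    def test_identical_sessions_give_null_result(self):
        m = {s: self.make_metrics(2.0 + 0.1 * s, 0.4) for s in range(1, 6)}
        res = network_property_tests(m, m)
        assert (res["t"] == 0).all()
        assert (res["p"] == 1).all()

    def test_direction_of_constructed_gain(self):
        rng = np.random.default_rng(31)
        m1 = {s: self.make_metrics(2.0 + 0.05 * rng.standard_normal(),
                                   0.40 + 0.01 * rng.standard_normal())
              for s in range(1, 11)}
        m2 = {s: self.make_metrics(m1[s]["Lp"] - 0.3, m1[s]["CC"] + 0.1)
              for s in m1}
        res = network_property_tests(m1, m2).set_index("metric")
        assert res.loc["CC", "t"] > 0
        assert res.loc["Lp", "t"] < 0
        assert res.loc["Deg", "p"] == 1.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(32)
        vals1 = 2.0 + 0.2 * rng.standard_normal(8)
        deltas = 0.1 + 0.05 * rng.standard_normal(8)
        m1 = {s: self.make_metrics(vals1[s - 1], 0.4) for s in range(1, 9)}
        m2 = {s: self.make_metrics(vals1[s - 1] + deltas[s - 1], 0.4)
              for s in range(1, 9)}
        res = network_property_tests(m1, m2).set_index("metric")
        assert res.loc["Lp", "t"] == pytest.approx(paired_t_closed_form(deltas))
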