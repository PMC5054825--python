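"""WNES/NES/NS/ES construction, the RT aligned-rank test, and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import wnes
from wnes.group_estimates import GroupSummaries

from conftest import group_data


def _summaries(merged, mean, var, beta=None, evar=None, group="D", n=100):
    M = merged.M
    return GroupSummaries(
        group=group,
        n=n,
        merged=merged,
        node_mean=np.asarray(mean, dtype=float),
        node_var=np.asarray(var, dtype=float),
        node_present=np.ones(merged.K, dtype=bool),
        edge_beta=np.zeros(M) if beta is None else np.asarray(beta, dtype=float),
        edge_var=np.zeros(M) if evar is None else np.asarray(evar, dtype=float),
        edge_present=np.ones(M, dtype=bool),
    )


@pytest.fixture
def pair_merged():
    net = wnes.DirectedNetwork(["A", "B"], [("A", "B")])
    return wnes.merge_structures(net, net)


class TestNodeTerms:
    def test_identical_summaries_give_zero(self, pair_merged):
        s = _summaries(pair_merged, [1.0, 2.0], [1.0, 1.0])
        np.testing.assert_array_equal(wnes.node_terms(s, s, 100, 100), [0.0, 0.0])

    def test_hand_evaluation(self, pair_merged):
        d = _summaries(pair_merged, [1.0, 0.0], [1.0, 1.0])
        c = _summaries(pair_merged, [0.0, 0.0], [1.0, 1.0], group="C")
        U = wnes.node_terms(d, c, 100, 100)
        assert U[0] == pytest.approx(50.0)  # 1 / (1/100 + 1/100)
        assert U[1] == 0.0

    def test_node_present_only_in_one_group(self, pair_merged):
        # zero-fill on the other side: U = 2^2 / (1/100 + 0)
        d = _summaries(pair_merged, [2.0, 0.0], [1.0, 1.0])
        c = _summaries(pair_merged, [0.0, 0.0], [0.0, 1.0], group="C")
        assert wnes.node_terms(d, c, 100, 100)[0] == pytest.approx(400.0)

    def test_degenerate_denominator_with_signal_raises(self, pair_merged):
        d = _summaries(pair_merged, [1.0, 0.0], [0.0, 1.0])
        c = _summaries(pair_merged, [0.0, 0.0], [0.0, 1.0], group="C")
        with pytest.raises(wnes.DegenerateDataError, match="'A'"):
            wnes.node_terms(d, c, 100, 100)

    def test_equals_squared_welch_t(self):
        """U_k is the squared Welch two-sample t statistic, to 1e-12."""
        rng = np.random.default_rng(5)
        net = wnes.DirectedNetwork(["A", "B", "C"], [])
        merged = wnes.merge_structures(net, net)
        d = group_data(rng, 40, net.node_labels, "D")
        c = group_data(rng, 25, net.node_labels, "C")
        U = wnes.node_terms(
            wnes.summarize_group(d, net, merged),
            wnes.summarize_group(c, net, merged),
            40, 25,
        )
        for k, label in enumerate(net.node_labels):
            t = stats.ttest_ind(
                d.values[label], c.values[label], equal_var=False
            ).statistic
            assert U[k] == pytest.approx(t**2, abs=1e-12)


class TestEdgeTerms:
    def test_equal_betas_give_zero(self, pair_merged):
        d = _summaries(pair_merged, [0, 0], [1, 1], beta=[0.5], evar=[0.01])
        c = _summaries(pair_merged, [0, 0], [1, 1], beta=[0.5], evar=[0.02], group="C")
        assert wnes.edge_terms(d, c)[0] == 0.0

    def test_edge_present_only_in_one_group(self, pair_merged):
        d = _summaries(pair_merged, [0, 0], [1, 1], beta=[0.5], evar=[0.01])
        c = _summaries(pair_merged, [0, 0], [1, 1], beta=[0.0], evar=[0.0], group="C")
        assert wnes.edge_terms(d, c)[0] == pytest.approx(25.0)  # 0.25 / 0.01

    def test_two_perfect_fits_with_equal_beta_use_zero_over_zero(self, pair_merged):
        d = _summaries(pair_merged, [0, 0], [1, 1], beta=[2.0], evar=[0.0])
        c = _summaries(pair_merged, [0, 0], [1, 1], beta=[2.0], evar=[0.0], group="C")
        assert wnes.edge_terms(d, c)[0] == 0.0


class TestCombine:
    def test_unit_weights_make_wnes_equal_nes(self):
        res = wnes.combine_statistics([1.0, 2.0], [3.0], np.ones(2))
        assert res.wnes == res.nes == 6.0

    def test_chain_arithmetic(self):
        res = wnes.combine_statistics([1.0, 1.0, 1.0], [2.0], [3.0, 2.0, 1.0])
        assert (res.ns, res.es, res.nes, res.wnes) == (3.0, 2.0, 5.0, 8.0)

    def test_empty_edge_set(self):
        res = wnes.combine_statistics([1.0, 2.0], [], np.ones(2))
        assert res.es == 0.0 and res.nes == res.ns == 3.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(wnes.DataInputError, match="mismatch"):
            wnes.combine_statistics([1.0, 2.0], [1.0], [1.0])

    def test_wnes_dominates_nes_with_weights_above_one(self):
        rng = np.random.default_rng(0)
        U, V = rng.chisquare(1, 5), rng.chisquare(1, 3)
        w = 1.0 + rng.random(5)
        res = wnes.combine_statistics(U, V, w)
        assert res.wnes >= res.nes


class TestRT:
    def test_identical_groups_give_zero(self):
        x = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 4)))
        assert wnes.rt_statistic(x, x.copy()) == 0.0

    def test_single_subject_hand_value(self):
        # subject ranks (1,2) vs (2,1): RT = (1/2) * ((1-2)^2 + (2-1)^2) = 1
        assert wnes.rt_statistic(np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]])) == 1.0

    def test_increasing_affine_transform_preserves_all_rank_vectors(self):
        """A common strictly increasing affine map of every measurement scales
        the aligned values positively, so each subject's rank vector — and
        hence RT — is unchanged."""
        rng = np.random.default_rng(2)
        d, c = rng.normal(size=(6, 5)), rng.normal(size=(4, 5))
        from wnes.test_statistics import aligned_ranks
        base = np.vstack([d, c])
        np.testing.assert_array_equal(
            aligned_ranks(base), aligned_ranks(3.0 * base - 7.0)
        )
        assert wnes.rt_statistic(d, c) == wnes.rt_statistic(3.0 * d - 7.0, 3.0 * c - 7.0)

    def test_needs_at_least_two_columns(self):
        with pytest.raises(wnes.DataInputError, match="2 variables"):
            wnes.rt_statistic(np.ones((3, 1)), np.zeros((3, 1)))

    def test_standardize_handles_disparate_units(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame({"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1000, 8)})
        c = pd.DataFrame({"a": rng.normal(1, 1, 8), "b": rng.normal(0, 1000, 8)})
        raw = wnes.rt_statistic(d, c)
        scaled = wnes.rt_statistic(d, c, standardize=True)
        assert scaled > 0 and raw >= 0


@pytest.fixture(scope="module")
def datasets():
    sem = wnes.fixture_sem("upr12")
    return wnes.simulate(sem, 60, 1, "D"), wnes.simulate(sem, 40, 2, "C")


class TestFullPipelineInvariants:

    def test_group_swap_symmetry(self, networks, datasets):
        d, c = datasets
        a = wnes.compute_all_statistics(d, c, networks["upr12"])
        swapped = wnes.compute_all_statistics(
            wnes.GroupData(c.values, "D"), wnes.GroupData(d.values, "C"),
            networks["upr12"],
        )
        for s in ("wnes", "nes", "ns", "es", "rt"):
            assert a.value(s) == pytest.approx(swapped.value(s), rel=1e-12)

    def test_relabeling_and_row_permutation_invariance(self, networks, datasets):
        d, c = datasets
        a = wnes.compute_all_statistics(d, c, networks["upr12"])
        mapping = {l: f"gene:{l}" for l in networks["upr12"].node_labels}
        net2 = networks["upr12"].relabel(mapping)
        rng = np.random.default_rng(9)
        d2 = wnes.GroupData(
            d.values.sample(frac=1, random_state=3).reset_index(drop=True).rename(columns=mapping),
            "D",
        )
        c2 = wnes.GroupData(c.values.rename(columns=mapping), "C")
        b = wnes.compute_all_statistics(d2, c2, net2)
        for s in ("wnes", "nes", "ns", "es", "rt"):
            assert a.value(s) == pytest.approx(b.value(s), rel=1e-9)

    def test_wnes_at_least_nes_under_default_weights(self, networks, datasets):
        d, c = datasets
        res = wnes.compute_all_statistics(d, c, networks["upr12"])
        assert (res.weights >= 1.0).all()
        assert res.wnes >= res.nes

    def test_decomposition_identities(self, networks, datasets):
        d, c = datasets
        res = wnes.compute_all_statistics(d, c, networks["upr12"])
        assert res.ns == pytest.approx(res.U.sum())
        assert res.es == pytest.approx(res.V.sum())
        assert res.nes == pytest.approx(res.ns + res.es)
        assert res.wnes == pytest.approx(res.weights @ res.U + res.es)
        assert (res.U >= 0).all() and (res.V >= 0).all()

    def test_batched_engine_matches_modular_pipeline(self, networks, datasets):
        """The permutation engine's batched recomputation reproduces the
        one-shot modular statistics on the observed labeling."""
        d, c = datasets
        res = wnes.network_permutation_test(
            d, c, networks["upr12"], n_permutations=5, seed=0
        )
        for s in ("wnes", "nes", "ns", "es", "rt"):
            assert res.permutation[s].observed == pytest.approx(
                res.observed.value(s), rel=1e-9
            )
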