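"""Network validation, descendant counting, weighting, and merging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wnes
from wnes.dag_core import merged_node_weights

from conftest import random_dag


class TestValidation:
    def test_chain_has_unique_topological_order(self, chain):
        assert wnes.validate_and_order(chain) == ("A", "B", "C")

    def test_two_cycle_rejected(self):
        with pytest.raises(wnes.NetworkStructureError, match="cycle"):
            wnes.DirectedNetwork(["A", "B"], [("A", "B"), ("B", "A")])

    def test_self_loop_rejected(self):
        with pytest.raises(wnes.NetworkStructureError, match="self-loop"):
            wnes.DirectedNetwork(["A"], [("A", "A")])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(wnes.NetworkStructureError, match="unknown node"):
            wnes.DirectedNetwork(["A"], [("A", "B")])

    def test_fixture_order_puts_every_parent_first(self, networks):
        # brute-force check of all edges against the returned order
        for net in networks.values():
            order = wnes.validate_and_order(net)
            pos = {l: i for i, l in enumerate(order)}
            assert all(pos[p] < pos[c] for p, c in net.edges)


class TestDescendantCounts:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("A", "B"), ("B", "C")], {"A": 2, "B": 1, "C": 0}),
            ([("A", "B"), ("A", "C"), ("A", "D")], {"A": 3, "B": 0, "C": 0, "D": 0}),
            # diamond: D reachable from A along two paths but counted once
            ([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")],
             {"A": 3, "B": 1, "C": 1, "D": 0}),
        ],
    )
    def test_known_topologies(self, edges, expected):
        net = wnes.DirectedNetwork(sorted(expected), edges)
        assert wnes.descendant_counts(net) == expected

    def test_direct_children_mode(self, diamond):
        assert wnes.descendant_counts(diamond, mode="children") == {
            "A": 2, "B": 1, "C": 1, "D": 0,
        }

    @given(st.integers(0, 10_000))
    def test_matches_dfs_from_every_node(self, seed):
        net = random_dag(np.random.default_rng(seed))
        counts = wnes.descendant_counts(net)
        for node in net.node_labels:
            seen, stack = set(), [node]
            while stack:
                for child in net.children(stack.pop()):
                    if child not in seen:
                        seen.add(child)
                        stack.append(child)
            assert counts[node] == len(seen)


class TestWeights:
    def test_chain_relative_weights(self, chain):
        r = wnes.relative_weights(wnes.descendant_counts(chain))
        assert r == {"A": 2 / 3, "B": 1 / 3, "C": 0.0}

    def test_edgeless_graph_gets_all_zero_relative_weights(self):
        net = wnes.DirectedNetwork(["A", "B", "C"], [])
        assert wnes.relative_weights(wnes.descendant_counts(net)) == {
            "A": 0.0, "B": 0.0, "C": 0.0,
        }

    def test_diamond_relative_weights(self, diamond):
        # counts (3,1,1,0), total 5
        r = wnes.relative_weights(wnes.descendant_counts(diamond))
        assert r == {"A": 3 / 5, "B": 1 / 5, "C": 1 / 5, "D": 0.0}

    def test_chain_additive_weights(self, chain):
        r = wnes.relative_weights(wnes.descendant_counts(chain))
        w = wnes.node_weights(r, 3, wnes.WeightScheme("additive", 1.0))
        assert w == {"A": 3.0, "B": 2.0, "C": 1.0}

    def test_unit_family_gives_all_ones(self, diamond):
        r = wnes.relative_weights(wnes.descendant_counts(diamond))
        w = wnes.node_weights(r, 4, wnes.WeightScheme("unit"))
        assert set(w.values()) == {1.0}

    def test_childless_node_has_weight_one_in_every_family(self, chain):
        r = wnes.relative_weights(wnes.descendant_counts(chain))
        for scheme in (
            wnes.WeightScheme("unit"),
            wnes.WeightScheme("additive", 0.5),
            wnes.WeightScheme("power", 2.0),
        ):
            assert wnes.node_weights(r, 3, scheme)["C"] == 1.0

    def test_smaller_tuning_inflates_topological_contribution(self, chain):
        r = wnes.relative_weights(wnes.descendant_counts(chain))
        small = wnes.node_weights(r, 3, wnes.WeightScheme("additive", 0.5))["A"]
        large = wnes.node_weights(r, 3, wnes.WeightScheme("additive", 2.0))["A"]
        assert small > large

    def test_non_positive_tuning_rejected(self):
        with pytest.raises(wnes.ConfigurationError):
            wnes.WeightScheme("additive", 0.0)

    @given(st.integers(0, 10_000))
    def test_weights_at_least_one_and_relabeling_invariant(self, seed):
        net = random_dag(np.random.default_rng(seed))
        r = wnes.relative_weights(wnes.descendant_counts(net))
        if net.edges:
            assert sum(r.values()) == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in r.values())
        for scheme in (wnes.WeightScheme("additive"), wnes.WeightScheme("power", 2.0)):
            w = wnes.node_weights(r, len(net.node_labels), scheme)
            assert all(v >= 1.0 for v in w.values())
            mapping = {l: f"relabeled:{l}" for l in net.node_labels}
            r2 = wnes.relative_weights(wnes.descendant_counts(net.relabel(mapping)))
            w2 = wnes.node_weights(r2, len(net.node_labels), scheme)
            assert w2 == {mapping[l]: v for l, v in w.items()}


class TestMergeStructures:
    def test_identical_networks(self, networks):
        m = wnes.merge_structures(networks["upr12"], networks["upr12"])
        assert (m.K, m.M) == (12, 15)
        assert all(s.in_D == s.in_C for s in m.slots)

    def test_one_reversed_edge_without_collapse(self, networks):
        m = wnes.merge_structures(networks["upr12"], networks["upr12_rev"])
        assert (m.K, m.M) == (12, 16)
        solo = [s for s in m.slots if (s.in_D is None) != (s.in_C is None)]
        assert len(solo) == 2

    def test_one_reversed_edge_with_collapse(self, networks):
        m = wnes.merge_structures(
            networks["upr12"], networks["upr12_rev"], collapse_reversed=True
        )
        assert m.M == 15
        assert sum(s.is_reversed_pair for s in m.slots) == 1

    def test_collapse_never_leaves_two_slots_per_pair(self, networks):
        m = wnes.merge_structures(
            networks["upr12"], networks["upr12_rev"], collapse_reversed=True
        )
        pairs = [frozenset(s.representative) for s in m.slots]
        assert len(pairs) == len(set(pairs))

    def test_symmetric_up_to_presence_swap(self, networks):
        a = wnes.merge_structures(networks["upr12"], networks["upr12_rev"])
        b = wnes.merge_structures(networks["upr12_rev"], networks["upr12"])
        assert set(a.union_nodes) == set(b.union_nodes)
        assert set(a.union_edges) == set(b.union_edges)
        assert a.M == b.M >= max(15, 15)

    def test_case_insensitive_collision_rejected(self):
        d = wnes.DirectedNetwork(["Tp53", "B"], [("Tp53", "B")])
        c = wnes.DirectedNetwork(["TP53", "B"], [("TP53", "B")])
        with pytest.raises(wnes.NetworkStructureError, match="case"):
            wnes.merge_structures(d, c)

    def test_merged_weights_symmetric_in_groups(self, networks):
        scheme = wnes.WeightScheme("additive")
        m_dc = wnes.merge_structures(networks["upr12"], networks["upr12_rev"])
        w_dc = merged_node_weights(m_dc, networks["upr12"], networks["upr12_rev"], scheme)
        w_cd = merged_node_weights(m_dc, networks["upr12_rev"], networks["upr12"], scheme)
        np.testing.assert_allclose(w_dc, w_cd)
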