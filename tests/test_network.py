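"""Transfer networks and degree-centrality ratios against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import egsnet as eg
from egsnet.network import NETWORK_LABELS, SCALE, RatioExclusions


def transfers_from_edges(edges):
    """Expand weighted edges into one transfer row per unit of weight."""
    rows = []
    k = 0
    for (o, d, w) in edges:
        for _ in range(w):
            rows.append((f"P{k}", o, d, "ED->IP", False))
            k += 1
    return pd.DataFrame(
        rows,
        columns=["patient_id", "origin_hospital", "destination_hospital",
                 "transfer_type", "any_operation"],
    )


def brute_force_centralities(edges, nodes, convention):
    """Independent oracle: exhaustive edge iteration, no graph library."""
    n = len(nodes)
    w_in = {v: 0.0 for v in nodes}
    w_out = {v: 0.0 for v in nodes}
    nb_in = {v: set() for v in nodes}
    nb_out = {v: set() for v in nodes}
    w_max = 1
    for (o, d, w) in edges:
        w_in[d] += w
        w_out[o] += w
        nb_in[d].add(o)
        nb_out[o].add(d)
        w_max = max(w_max, w)
    out = {}
    for v in nodes:
        if convention == "weighted":
            i, o = w_in[v] / ((n - 1) * w_max), w_out[v] / ((n - 1) * w_max)
        else:
            i, o = len(nb_in[v]) / (n - 1), len(nb_out[v]) / (n - 1)
        out[v] = (i * SCALE, o * SCALE)
    return out


class TestBuildNetwork:
    def test_edge_weights_aggregate_by_type(self):
        tf = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3"],
                "origin_hospital": ["A"] * 3,
                "destination_hospital": ["B"] * 3,
                "transfer_type": ["ED->IP", "ED->IP", "IP->IP"],
                "any_operation": [True, False, False],
            }
        )
        assert eg.build_network(tf, "all")["A"]["B"]["weight"] == 3
        assert eg.build_network(tf, "ed_to_ip")["A"]["B"]["weight"] == 2
        assert eg.build_network(tf, "with_operation")["A"]["B"]["weight"] == 1

    def test_empty_transfers_keep_declared_nodes(self):
        tf = transfers_from_edges([])
        g = eg.build_network(tf, "all", nodes=["A", "B", "C"])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0
        cent = eg.degree_centralities(g)
        assert (cent[["in_degree_scaled", "out_degree_scaled"]] == 0).all().all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown network label"):
            eg.build_network(transfers_from_edges([]), "bogus")

    def test_partition_identity(self, small_world_linked):
        """all = ED->IP + IP->IP = with-op + without-op in total edge weight."""
        *_, transfers = small_world_linked
        totals = {
            label: sum(
                d["weight"] for _, _, d in eg.build_network(transfers, label).edges(data=True)
            )
            for label in NETWORK_LABELS
        }
        assert totals["all"] == totals["ed_to_ip"] + totals["ip_to_ip"]
        assert totals["all"] == totals["with_operation"] + totals["without_operation"]
        assert totals["all"] == len(transfers)


class TestDegreeCentrality:
    def test_worked_example(self):
        # edges A->B w=2, C->B w=1; n=3, W_max=2 -> in(B) = 3/(2*2) * 10000
        tf = transfers_from_edges([("A", "B", 2), ("C", "B", 1)])
        g = eg.build_network(tf, "all")
        cent = eg.degree_centralities(g).set_index("hospital_id")
        assert cent.loc["B", "in_degree_scaled"] == pytest.approx(7500.0)
        assert cent.loc["B", "out_degree_scaled"] == 0.0

    def test_isolated_node_has_zero_centralities(self):
        tf = transfers_from_edges([("A", "B", 1)])
        g = eg.build_network(tf, "all", nodes=["A", "B", "Z"])
        cent = eg.degree_centralities(g).set_index("hospital_id")
        assert cent.loc["Z", "in_degree_scaled"] == 0.0
        assert cent.loc["Z", "out_degree_scaled"] == 0.0

    def test_doubling_weights_leaves_centralities_unchanged(self):
        edges = [("A", "B", 2), ("B", "C", 5), ("C", "A", 1)]
        doubled = [(o, d, 2 * w) for o, d, w in edges]
        c1 = eg.degree_centralities(eg.build_network(transfers_from_edges(edges)))
        c2 = eg.degree_centralities(eg.build_network(transfers_from_edges(doubled)))
        pd.testing.assert_frame_equal(c1, c2)

    def test_degenerate_network_rejected(self):
        g = eg.build_network(transfers_from_edges([]), "all", nodes=["A"])
        with pytest.raises(ValueError, match="degenerate"):
            eg.degree_centralities(g)

    def test_conservation_of_total_weight(self, small_world_linked):
        *_, transfers = small_world_linked
        g = eg.build_network(transfers, "all")
        total = sum(d["weight"] for *_, d in g.edges(data=True))
        assert sum(g.in_degree(v, weight="weight") for v in g) == total
        assert sum(g.out_degree(v, weight="weight") for v in g) == total

    @given(
        edges=st.lists(
            st.tuples(
                st.integers(0, 9), st.integers(0, 9), st.integers(1, 50)
            ).filter(lambda e: e[0] != e[1]),
            max_size=25,
            unique_by=lambda e: (e[0], e[1]),
        ),
        convention=st.sampled_from(["weighted", "binary"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, edges, convention):
        nodes = [f"H{i}" for i in range(10)]
        edges = [(f"H{o}", f"H{d}", w) for o, d, w in edges]
        g = eg.build_network(transfers_from_edges(edges), "all", nodes=nodes)
        cent = eg.degree_centralities(g, convention).set_index("hospital_id")
        oracle = brute_force_centralities(edges, nodes, convention)
        for v, (i_exp, o_exp) in oracle.items():
            assert cent.loc[v, "in_degree_scaled"] == pytest.approx(i_exp, rel=1e-12, abs=1e-12)
            assert cent.loc[v, "out_degree_scaled"] == pytest.approx(o_exp, rel=1e-12, abs=1e-12)

    def test_label_permutation_equivariance(self):
        edges = [("A", "B", 3), ("B", "C", 1), ("A", "C", 2)]
        perm = {"A": "C", "B": "A", "C": "B"}
        permuted = [(perm[o], perm[d], w) for o, d, w in edges]
        c1 = eg.degree_centralities(eg.build_network(transfers_from_edges(edges))).set_index("hospital_id")
        c2 = eg.degree_centralities(eg.build_network(transfers_from_edges(permuted))).set_index("hospital_id")
        for v in "ABC":
            assert c1.loc[v, "in_degree_scaled"] == pytest.approx(c2.loc[perm[v], "in_degree_scaled"])
            assert c1.loc[v, "out_degree_scaled"] == pytest.approx(c2.loc[perm[v], "out_degree_scaled"])


class TestCentralityRatio:
    def test_ratio_equals_raw_weight_quotient(self):
        # incoming 36, outgoing 106 -> ratio 36/106 regardless of normalization
        tf = transfers_from_edges([("A", "B", 36), ("B", "C", 106)])
        cent = eg.degree_centralities(eg.build_network(tf)).set_index("hospital_id")
        assert cent.loc["B", "centrality_ratio"] == pytest.approx(36 / 106)

    def test_symmetric_in_out_gives_ratio_one_log_zero(self):
        tf = transfers_from_edges([("A", "B", 4), ("B", "A", 4)])
        cent, _ = eg.log_transform_ratios(
            eg.degree_centralities(eg.build_network(tf))
        )
        cent = cent.set_index("hospital_id")
        assert cent.loc["A", "centrality_ratio"] == pytest.approx(1.0)
        assert cent.loc["A", "log_centrality_ratio"] == pytest.approx(0.0)

    def test_zero_outdegree_is_undefined(self):
        tf = transfers_from_edges([("A", "B", 2)])
        cent = eg.degree_centralities(eg.build_network(tf)).set_index("hospital_id")
        assert math.isnan(cent.loc["B", "centrality_ratio"])

    def test_log_transform_exclusion_tally(self):
        # 6 hospitals: B receives only (undefined out at B? B sends nothing ->
        # undefined), A sends only (ratio 0); the rest have both directions
        edges = [("A", "B", 2), ("C", "D", 1), ("D", "C", 2), ("E", "F", 1), ("F", "E", 3)]
        cent = eg.degree_centralities(eg.build_network(transfers_from_edges(edges)))
        out, excl = eg.log_transform_ratios(cent)
        assert isinstance(excl, RatioExclusions)
        assert excl.n_hospitals == 6
        assert excl.n_undefined == 1  # B: no outgoing transfers
        assert excl.n_zero == 1  # A: no incoming transfers
        assert excl.n_analyzed == 4 == out["log_centrality_ratio"].notna().sum()

    def test_log_ratio_of_e_is_one(self):
        rec = pd.DataFrame(
            {
                "hospital_id": ["A"],
                "in_degree_scaled": [math.e],
                "out_degree_scaled": [1.0],
                "centrality_ratio": [math.e],
                "network_label": ["all"],
            }
        )
        out, _ = eg.log_transform_ratios(rec)
        assert out.loc[0, "log_centrality_ratio"] == pytest.approx(1.0)
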