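import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from teamperf import (
    ChatLog,
    CollaborationNetwork,
    Message,
    SparseNetwork,
    algebraic_connectivity,
    assemble_feature_table,
    log_features,
    mean_edge_reciprocity,
    sparse_topology_features,
    weighted_degree_features,
)
from teamperf.io import BaselineFeatures, BASELINE_FEATURE_NAMES
from teamperf.netfeat import NeutralSentimentScorer, apply_sentiment_scorer


def net(weights, members=None):
    if members is None:
        members = tuple(sorted({m for e in weights for m in e}))
    return CollaborationNetwork(members=tuple(members), weights=weights)


def sparse(edges, members):
    return SparseNetwork(members=tuple(members), edges=frozenset(edges))


def complete_unweighted(n):
    nodes = [f"v{i}" for i in range(n)]
    return net({(i, j): 1.0 for i in nodes for j in nodes if i != j}, nodes)


class TestDegreeFeatures:
    def test_symmetric_dyad(self):
        feats = weighted_degree_features(net({("a", "b"): 1.0, ("b", "a"): 1.0}))
        assert feats["degree_mean_out"] == 1.0
        assert feats["degree_std_out"] == 0.0
        assert feats["degree_mean_minus_std_out"] == 1.0

    def test_population_std_three_nodes(self):
        # out-strengths (2, 1, 0): mean 1, population std sqrt(2/3)
        feats = weighted_degree_features(
            net({("a", "b"): 2.0, ("b", "c"): 1.0}, members=("a", "b", "c"))
        )
        assert feats["degree_mean_out"] == pytest.approx(1.0)
        assert feats["degree_std_out"] == pytest.approx(math.sqrt(2 / 3))

    def test_edgeless_network_all_zero(self):
        feats = weighted_degree_features(net({}, members=("a", "b")))
        assert all(v == 0.0 for v in feats.values())


class TestReciprocity:
    def test_fully_symmetric(self):
        assert mean_edge_reciprocity(net({("a", "b"): 2.0, ("b", "a"): 2.0})) == 1.0

    def test_one_directional(self):
        assert mean_edge_reciprocity(net({("a", "b"): 2.0, ("a", "c"): 1.0})) == 0.0

    def test_ratio_definition(self):
        assert mean_edge_reciprocity(net({("a", "b"): 2.0, ("b", "a"): 1.0})) == 0.5

    def test_no_communicating_pair_missing(self):
        assert math.isnan(mean_edge_reciprocity(net({}, members=("a", "b"))))


class TestAlgebraicConnectivity:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_equals_n(self, n):
        assert algebraic_connectivity(complete_unweighted(n)) == pytest.approx(n, abs=1e-9)

    def test_path_p4(self):
        edges = {("a", "b"): 1.0, ("b", "a"): 1.0, ("b", "c"): 1.0, ("c", "b"): 1.0,
                 ("c", "d"): 1.0, ("d", "c"): 1.0}
        assert algebraic_connectivity(net(edges)) == pytest.approx(2 - math.sqrt(2), abs=1e-9)

    def test_two_disjoint_dyads(self):
        edges = {("a", "b"): 1.0, ("b", "a"): 1.0, ("c", "d"): 1.0, ("d", "c"): 1.0}
        # Laplacian eigenvalues {0, 0, 2, 2}: smallest positive is 2
        assert algebraic_connectivity(net(edges)) == pytest.approx(2.0, abs=1e-9)

    def test_all_zero_network_missing(self):
        assert math.isnan(algebraic_connectivity(net({}, members=("a", "b"))))

    def test_monotone_under_edge_addition_when_connected(self):
        # Fiedler monotonicity: for *connected* graphs the smallest positive
        # Laplacian eigenvalue never decreases when an undirected unit edge
        # is added (for disconnected graphs the smallest positive eigenvalue
        # is a different quantity and can drop when components get bridged)
        import networkx as nx

        rng = np.random.default_rng(4)
        nodes = [f"v{i}" for i in range(6)]
        checked = 0
        while checked < 20:
            weights = {}
            for i in nodes:
                for j in nodes:
                    if i < j and rng.random() < 0.6:
                        weights[(i, j)] = weights[(j, i)] = 1.0
            G = nx.Graph(list(weights))
            G.add_nodes_from(nodes)
            missing = [(i, j) for i in nodes for j in nodes if i < j and (i, j) not in weights]
            if not nx.is_connected(G) or not missing:
                continue
            before = algebraic_connectivity(net(weights, nodes))
            i, j = missing[int(rng.integers(len(missing)))]
            weights[(i, j)] = weights[(j, i)] = 1.0
            after = algebraic_connectivity(net(weights, nodes))
            assert after >= before - 1e-9
            checked += 1


class TestSparseTopology:
    def test_complete_digraph(self):
        nodes = ("a", "b", "c", "d")
        feats = sparse_topology_features(
            sparse([(i, j) for i in nodes for j in nodes if i != j], nodes)
        )
        assert feats["density"] == 1.0
        assert feats["diameter"] == 1.0
        assert feats["n_weak_components"] == 1.0
        assert feats["n_strong_components"] == 1.0
        assert feats["mean_clustering"] == 1.0

    def test_edgeless_graph(self):
        feats = sparse_topology_features(sparse([], ("a", "b", "c", "d")))
        assert feats["density"] == 0.0
        assert feats["n_weak_components"] == 4.0
        assert math.isnan(feats["diameter"])

    def test_directed_three_cycle(self):
        feats = sparse_topology_features(sparse([("a", "b"), ("b", "c"), ("c", "a")], "abc"))
        assert feats["density"] == pytest.approx(0.5)
        assert feats["n_strong_components"] == 1.0
        assert feats["diameter"] == 1.0  # undirected projection of a 3-cycle

    def test_density_and_reciprocity_bounded(self):
        rng = np.random.default_rng(8)
        nodes = tuple(f"v{i}" for i in range(5))
        for _ in range(20):
            edges = [(i, j) for i in nodes for j in nodes if i != j and rng.random() < 0.4]
            s = sparse(edges, nodes)
            feats = sparse_topology_features(s)
            assert 0.0 <= feats["density"] <= 1.0
            rec = mean_edge_reciprocity(s)
            assert math.isnan(rec) or 0.0 <= rec <= 1.0


class TestLogFeatures:
    def test_turns_run_length(self):
        msgs = [Message(sender=s, time=float(t), text="x")
                for t, s in enumerate(["a", "a", "b", "a"])]
        feats = log_features(ChatLog.from_messages("t", msgs))
        assert feats["turns"] == 3.0

    def test_delays(self):
        msgs = [Message(sender=s, time=t, text="") for s, t in
                [("a", 0.0), ("b", 10.0), ("a", 30.0)]]
        feats = log_features(ChatLog.from_messages("t", msgs))
        assert feats["delay_mean"] == 15.0
        assert feats["delay_median"] == 15.0

    def test_neutral_sentiment(self):
        msgs = [Message(sender="a", time=0.0, text="x", sentiment=0.0),
                Message(sender="b", time=5.0, text="y", sentiment=0.0)]
        feats = log_features(ChatLog.from_messages("t", msgs))
        assert feats["sentiment_mean"] == 0.0
        assert feats["sentiment_std"] == 0.0

    def test_single_message_delay_missing(self):
        log = ChatLog.from_messages("t", [Message(sender="a", time=0.0, text="hi")],
                                    members=["a", "b"])
        feats = log_features(log)
        assert math.isnan(feats["delay_mean"])

    def test_char_and_word_counts(self):
        msgs = [Message(sender="a", time=0.0, text="two words"),
                Message(sender="b", time=5.0, text="one")]
        feats = log_features(ChatLog.from_messages("t", msgs))
        assert feats["chars_total"] == len("two words") + len("one")
        assert feats["words_total"] == 3.0

    def test_neutral_scorer_fills_sentiment(self):
        msgs = [Message(sender="a", time=0.0, text="x"), Message(sender="b", time=2.0, text="y")]
        log = apply_sentiment_scorer(ChatLog.from_messages("t", msgs), NeutralSentimentScorer())
        assert all(m.sentiment == 0.0 for m in log.messages)


class TestAssembleFeatureTable:
    def _baseline(self, teams):
        data = {name: np.linspace(0.1, 0.9, len(teams)) for name in BASELINE_FEATURE_NAMES}
        return BaselineFeatures(table=pd.DataFrame(data, index=teams))

    def test_join_two_teams(self):
        teams = ["t1", "t2"]
        nets = {t: net({("a", "b"): 1.0, ("b", "a"): 0.5}) for t in teams}
        logs = {t: ChatLog.from_messages(t, [Message(sender="a", time=0.0, text="x"),
                                             Message(sender="b", time=3.0, text="y")])
                for t in teams}
        table = assemble_feature_table(teams, weighted=nets, logs=logs,
                                       baseline=self._baseline(teams))
        assert list(table.index) == teams
        assert "wn_degree_mean_out" in table.columns
        assert "log_turns" in table.columns
        assert "proportion_female" in table.columns

    def test_missing_log_keeps_row(self):
        teams = ["t1", "t2"]
        logs = {"t1": ChatLog.from_messages("t1", [Message(sender="a", time=0.0, text="x"),
                                                   Message(sender="b", time=2.0, text="y")])}
        table = assemble_feature_table(teams, logs=logs)
        assert np.isnan(table.loc["t2", "log_turns"])

    def test_sparse_prefixes(self):
        teams = ["t1"]
        w = net({("a", "b"): 1.0, ("b", "a"): 0.5, ("a", "c"): 0.1})
        from teamperf import sparsify
        sp = {0.25: {"t1": sparsify(w, 0.25)}, 0.50: {"t1": sparsify(w, 0.50)}}
        table = assemble_feature_table(teams, sparse=sp)
        assert "sn25_density" in table.columns and "sn50_density" in table.columns

    def test_duplicate_feature_name_rejected(self):
        teams = ["t1"]
        dyn = pd.DataFrame({"dyn_mean": [0.5]}, index=teams)
        collided = pd.concat([dyn, dyn.copy()], axis=1)  # two dyn_mean columns
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_table(teams, dynamics=collided)


def test_connectivity_tracks_degree_uniformity_across_density():
    """Denser random networks have both higher mean-minus-std out-degree and
    higher algebraic connectivity; the two should co-rank strongly."""
    rng = np.random.default_rng(12)
    nodes = tuple(f"v{i}" for i in range(6))
    ms_out, lam2 = [], []
    for density in np.linspace(0.15, 0.95, 40):
        weights = {}
        for i in nodes:
            for j in nodes:
                if i != j and rng.random() < density:
                    weights[(i, j)] = float(rng.uniform(0.5, 1.5))
        if not weights:
            continue
        network = net(weights, nodes)
        feats = weighted_degree_features(network)
        lam = algebraic_connectivity(network)
        if not math.isnan(lam):
            ms_out.append(feats["degree_mean_minus_std_out"])
            lam2.append(lam)
    rho = spearmanr(ms_out, lam2).statistic
    assert rho > 0.7
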