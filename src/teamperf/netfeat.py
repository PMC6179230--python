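"""Team features derived from collaboration networks and chat logs.

Three families, distinguished by name prefix in the assembled design matrix:

* ``wn_*``  — features of the dense weighted collaboration network;
* ``snX_*`` — features of the sparse unweighted network with X% of the
  lowest-weight edges dropped (X in {25, 50, 75});
* ``log_*`` — aggregate chat-log statistics (volume, turn taking, pacing,
  sentiment).

Degree statistics use the population (divide-by-n) convention: they are
descriptive summaries of one team's finite network, not estimates of a larger
population.  Missing values are explicit NaN, never silently zero.
"""

from __future__ import annotations

from typing import Mapping, Protocol, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import BaselineFeatures, ChatLog, Message
from .network import CollaborationNetwork, SparseNetwork

__all__ = [
    "weighted_degree_features",
    "mean_edge_reciprocity",
    "algebraic_connectivity",
    "sparse_topology_features",
    "network_feature_set",
    "log_features",
    "assemble_feature_table",
    "SentimentScorer",
    "NeutralSentimentScorer",
    "apply_sentiment_scorer",
]

_EIG_TOL = 1e-9


def _weight_matrix(network: CollaborationNetwork | SparseNetwork) -> tuple[list[str], np.ndarray]:
    members = list(network.members)
    idx = {m: k for k, m in enumerate(members)}
    W = np.zeros((len(members), len(members)))
    if isinstance(network, SparseNetwork):
        for i, j in network.edges:
            W[idx[i], idx[j]] = 1.0
    else:
        for (i, j), w in network.weights.items():
            W[idx[i], idx[j]] = w
    return members, W


def weighted_degree_features(network: CollaborationNetwork | SparseNetwork) -> dict[str, float]:
    """Mean/std of node in- and out-strengths, and their differences.

    The in-(out-)degree of a node is the sum of its incident in-(out-)edge
    weights; for unweighted sparse networks this is the plain degree.  The
    ``mean - std`` combinations capture uniformly-high connectivity: large
    when every member both sends and receives a lot.
    """
    _, W = _weight_matrix(network)
    if W.size == 0:
        zeros = 0.0
        return {k: zeros for k in (
            "degree_mean_in", "degree_std_in", "degree_mean_out", "degree_std_out",
            "degree_mean_minus_std_in", "degree_mean_minus_std_out")}
    in_deg = W.sum(axis=0)
    out_deg = W.sum(axis=1)
    return {
        "degree_mean_in": float(in_deg.mean()),
        "degree_std_in": float(in_deg.std()),  # population
        "degree_mean_out": float(out_deg.mean()),
        "degree_std_out": float(out_deg.std()),
        "degree_mean_minus_std_in": float(in_deg.mean() - in_deg.std()),
        "degree_mean_minus_std_out": float(out_deg.mean() - out_deg.std()),
    }


def mean_edge_reciprocity(network: CollaborationNetwork | SparseNetwork) -> float:
    """Mean over communicating pairs {i, j} of min(w_ij, w_ji)/max(w_ij, w_ji).

    1 means perfectly mutual interaction, 0 means strictly one-way.  Pairs
    that never communicate are excluded; with no communicating pair at all
    the feature is missing (NaN).
    """
    _, W = _weight_matrix(network)
    n = W.shape[0]
    ratios = []
    for i in range(n):
        for j in range(i + 1, n):
            hi = max(W[i, j], W[j, i])
            if hi > 0:
                ratios.append(min(W[i, j], W[j, i]) / hi)
    return float(np.mean(ratios)) if ratios else float("nan")


def algebraic_connectivity(network: CollaborationNetwork | SparseNetwork) -> float:
    """Smallest positive eigenvalue of the (symmetrized) graph Laplacian.

    The directed weight matrix is symmetrized as A = (W + Wᵀ)/2, then
    L = D - A with D the diagonal of row sums.  For a connected graph this is
    the Fiedler value; larger values mean a better-connected, perturbation-
    robust network where diffusive processes (consensus, random walks) mix
    fast.  Eigenvalues below 1e-9 count as zero; an all-zero network yields
    NaN.
    """
    _, W = _weight_matrix(network)
    if W.shape[0] < 2:
        raise ValueError("algebraic connectivity needs at least 2 nodes")
    A = (W + W.T) / 2.0
    if not A.any():
        return float("nan")
    L = np.diag(A.sum(axis=1)) - A
    eigvals = np.linalg.eigvalsh(L)
    positive = eigvals[eigvals > _EIG_TOL]
    return float(positive[0]) if positive.size else float("nan")


def sparse_topology_features(network: SparseNetwork) -> dict[str, float]:
    """Topology summaries of a sparse unweighted collaboration network.

    Density counts directed edges out of n(n-1) possible.  Strong components
    are computed on the digraph; diameter, mean shortest path length and
    clustering are computed on the undirected projection restricted to the
    largest weakly connected component (sparse digraphs are rarely strongly
    connected).  Betweenness is directed, normalized by 1/((n-1)(n-2)), and
    averaged over all nodes.
    """
    n = len(network.members)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    G = nx.DiGraph()
    G.add_nodes_from(network.members)
    G.add_edges_from(network.edges)
    density = len(network.edges) / (n * (n - 1))
    weak = list(nx.weakly_connected_components(G))
    strong_count = nx.number_strongly_connected_components(G)
    largest = max(weak, key=len)
    U = G.subgraph(largest).to_undirected()
    if U.number_of_nodes() >= 2:
        diameter = float(nx.diameter(U))
        mean_sp = float(nx.average_shortest_path_length(U))
        clustering = float(nx.average_clustering(U))
    else:
        diameter = mean_sp = clustering = float("nan")
    betweenness = float(np.mean(list(nx.betweenness_centrality(G, normalized=True).values())))
    return {
        "density": density,
        "diameter": diameter,
        "mean_shortest_path": mean_sp,
        "n_weak_components": float(len(weak)),
        "n_strong_components": float(strong_count),
        "mean_betweenness": betweenness,
        "mean_clustering": clustering,
    }


def network_feature_set(network: CollaborationNetwork | SparseNetwork) -> dict[str, float]:
    """All features applicable to the given network type (unprefixed names)."""
    out = dict(weighted_degree_features(network))
    out["mean_edge_reciprocity"] = mean_edge_reciprocity(network)
    out["algebraic_connectivity"] = algebraic_connectivity(network)
    if isinstance(network, SparseNetwork):
        out.update(sparse_topology_features(network))
    return out


def _population_std(values: Sequence[float]) -> float:
    return float(np.std(np.asarray(values, dtype=float)))


def log_features(log: ChatLog) -> dict[str, float]:
    """Aggregate chat-log statistics for one team.

    Characters count every character of the stored message text (whitespace
    included); words are whitespace tokens.  A *turn* is a maximal run of
    consecutive messages by one sender.  Delays are successive time gaps over
    the whole log (missing for single-message logs).  Sentiment statistics
    are taken over the messages that carry a sentiment value and are missing
    when none do.
    """
    if not log.messages:
        raise ValueError("empty chat log")
    per_member_chars = {m: 0 for m in log.members}
    per_member_words = {m: 0 for m in log.members}
    for msg in log.messages:
        per_member_chars[msg.sender] += len(msg.text)
        per_member_words[msg.sender] += len(msg.text.split())
    chars = list(per_member_chars.values())
    words = list(per_member_words.values())

    turns = 1
    for prev, cur in zip(log.messages, log.messages[1:]):
        if cur.sender != prev.sender:
            turns += 1

    times = np.array([m.time for m in log.messages])
    if len(times) >= 2:
        delays = np.diff(times)
        delay_mean, delay_median, delay_std = (
            float(delays.mean()), float(np.median(delays)), _population_std(delays))
    else:
        delay_mean = delay_median = delay_std = float("nan")

    sentiments = [m.sentiment for m in log.messages if m.sentiment is not None]
    if sentiments:
        sent_mean, sent_std = float(np.mean(sentiments)), _population_std(sentiments)
    else:
        sent_mean = sent_std = float("nan")

    return {
        "chars_total": float(sum(chars)),
        "words_total": float(sum(words)),
        "chars_per_member_mean": float(np.mean(chars)),
        "chars_per_member_std": _population_std(chars),
        "words_per_member_mean": float(np.mean(words)),
        "words_per_member_std": _population_std(words),
        "turns": float(turns),
        "delay_mean": delay_mean,
        "delay_median": delay_median,
        "delay_std": delay_std,
        "sentiment_mean": sent_mean,
        "sentiment_std": sent_std,
    }


def assemble_feature_table(
    team_ids: Sequence[str],
    *,
    weighted: Mapping[str, CollaborationNetwork] | None = None,
    sparse: Mapping[float, Mapping[str, SparseNetwork]] | None = None,
    logs: Mapping[str, ChatLog] | None = None,
    baseline: BaselineFeatures | None = None,
    dynamics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join all feature families into one design matrix (rows = teams).

    Column prefixes: ``wn_`` weighted network, ``snX_`` sparse network with
    X% dropped, ``log_`` chat-log summaries, ``dyn_`` performance-dynamics
    features, and bare names for the baseline features.  Teams missing a
    source keep their row with NaNs in that family.  A duplicate feature
    name raises.
    """
    blocks: list[pd.DataFrame] = []

    def add_block(prefix: str, rows: Mapping[str, dict[str, float]]) -> None:
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.columns = [f"{prefix}{c}" for c in frame.columns]
        blocks.append(frame)

    if weighted is not None:
        add_block("wn_", {t: network_feature_set(n) for t, n in weighted.items()})
    if sparse is not None:
        for frac, nets in sparse.items():
            pct = int(round(frac * 100))
            add_block(f"sn{pct}_", {t: network_feature_set(n) for t, n in nets.items()})
    if logs is not None:
        add_block("log_", {t: log_features(lg) for t, lg in logs.items()})
    if baseline is not None:
        blocks.append(baseline.table.copy())
    if dynamics is not None:
        frame = dynamics.copy()
        frame.columns = [c if str(c).startswith("dyn_") else f"dyn_{c}" for c in frame.columns]
        blocks.append(frame)

    table = pd.DataFrame(index=list(team_ids))
    for block in blocks:
        if block.columns.duplicated().any():
            dupes = block.columns[block.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        overlap = set(table.columns) & set(block.columns)
        if overlap:
            raise ValueError(f"duplicate feature names: {sorted(overlap)}")
        table = table.join(block, how="left")
    return table


class SentimentScorer(Protocol):
    """Pluggable message-text sentiment scorer: text -> real in [-1, 1]."""

    def __call__(self, text: str) -> float: ...


class NeutralSentimentScorer:
    """Stub scorer assigning neutral sentiment (0.0) to every message."""

    def __call__(self, text: str) -> float:
        return 0.0


def apply_sentiment_scorer(log: ChatLog, scorer: SentimentScorer) -> ChatLog:
    """Return a copy of ``log`` with sentiments filled in by ``scorer``."""
    scored = [
        Message(sender=m.sender, time=m.time, text=m.text, sentiment=float(scorer(m.text)))
        for m in log.messages
    ]
    return ChatLog(team_id=log.team_id, members=log.members, messages=tuple(scored))
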