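"""Gold-centric reconstruction comparison, scored in [0, 1].

An independent implementation of the scoring principles popularised by the
DIADEM challenge metric: the *critical* nodes of the gold-standard tree —
bifurcations and terminals — are matched one-to-one against test nodes under
lateral and axial position thresholds, a matched node must also reproduce the
path length to its nearest matched ancestor, and every critical node carries a
weight equal to its number of terminal descendants.  The score is the matched
weight divided by the total weight: 1 for a perfect reproduction of the gold
topology and geometry, 0 when nothing matches.  Excess test structure (false
positives) does not reduce the score; it is reported separately as unmatched
cable length.

This is not a port of the original Java tool and exact numeric agreement with
it is not claimed; the implementation is internally consistent and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .morpho import NeuronTree

__all__ = ["MetricParams", "MatchResult", "critical_nodes", "diadem_score", "excess_cable"]


@dataclass
class MetricParams:
    """Matching thresholds.

    xy_threshold: maximal lateral (x–y plane) node distance, μm.
    z_threshold: maximal axial (|Δz|) node distance, μm.
    path_length_tolerance: relative tolerance on the path length between a
        matched node and its nearest matched ancestor.
    path_length_slack: absolute slack (μm) added to the path-length band, so
        short paths are not rejected by discretisation jitter.
    """

    xy_threshold: float = 1.2
    z_threshold: float = 2.0
    path_length_tolerance: float = 0.05
    path_length_slack: float = 4.0

    def __post_init__(self):
        if self.xy_threshold <= 0 or self.z_threshold <= 0:
            raise ValueError("position thresholds must be positive")
        if not (0 < self.path_length_tolerance < 1):
            raise ValueError("path_length_tolerance must be in (0, 1)")


@dataclass
class MatchResult:
    score: float
    matched_gold_nodes: list[int]
    unmatched_gold_nodes: list[int]
    weight_total: float
    weight_matched: float
    rows: list[dict] = field(default_factory=list)  # per gold critical node

    def __post_init__(self):
        assert 0.0 <= self.score <= 1.0


def critical_nodes(tree: NeuronTree) -> list[int]:
    """Bifurcations/multifurcations and terminals, excluding the root."""
    cm = tree.child_map()
    return [
        nid
        for nid in tree.topological_order()
        if nid != tree.root_id and len(cm[nid]) != 1
    ]


def _terminal_weights(tree: NeuronTree) -> dict[int, int]:
    """Number of terminal descendants per node (a terminal counts itself)."""
    cm = tree.child_map()
    weights: dict[int, int] = {}
    for nid in reversed(tree.topological_order()):
        ch = cm[nid]
        weights[nid] = 1 if not ch else sum(weights[c] for c in ch)
    return weights


def _tree_graph(tree: NeuronTree) -> nx.Graph:
    g = nx.Graph()
    for n in tree.nodes:
        g.add_node(n.id)
        if n.parent_id != -1:
            g.add_edge(n.id, n.parent_id, weight=tree.edge_length(n.id))
    return g


def _critical_ancestors(tree: NeuronTree, crit: set[int]) -> dict[int, int | None]:
    """For each node: its nearest proper ancestor that is a critical node."""
    out: dict[int, int | None] = {}
    for nid in tree.topological_order():
        n = tree.node(nid)
        if n.parent_id == -1:
            out[nid] = None
        elif n.parent_id in crit:
            out[nid] = n.parent_id
        else:
            out[nid] = out[n.parent_id]
    return out


def diadem_score(
    test: NeuronTree, gold: NeuronTree, params: MetricParams | None = None
) -> MatchResult:
    """Score a test reconstruction against a gold standard.

    Gold critical nodes are visited root-to-leaf.  A node is matched when a
    previously unused test node lies within ``xy_threshold`` laterally and
    ``z_threshold`` axially (nearest candidate first) and — when the gold node
    has a matched critical ancestor — the test path length to that ancestor's
    matched test node agrees with the gold path length within
    ``path_length_tolerance`` (relative) plus ``path_length_slack`` (absolute).
    """
    params = params or MetricParams()
    crit = critical_nodes(gold)
    if not crit:
        raise ValueError("gold standard degenerate: no bifurcation or terminal nodes")
    crit_set = set(crit)
    weights = _terminal_weights(gold)
    anc = _critical_ancestors(gold, crit_set)

    test_pos = test.positions()
    test_ids = [n.id for n in test.nodes]
    gold_graph = _tree_graph(gold)
    test_graph = _tree_graph(test)

    used_test: set[int] = set()
    match_of: dict[int, int] = {}  # gold id -> test id
    rows: list[dict] = []
    matched, unmatched = [], []
    w_matched = 0.0
    w_total = float(sum(weights[g] for g in crit))

    for g in crit:
        gp = np.asarray(gold.node(g).position)
        d_lat = np.hypot(test_pos[:, 0] - gp[0], test_pos[:, 1] - gp[1])
        d_ax = np.abs(test_pos[:, 2] - gp[2])
        ok = (d_lat <= params.xy_threshold) & (d_ax <= params.z_threshold)
        d3 = np.linalg.norm(test_pos - gp, axis=1)
        order = np.argsort(d3, kind="stable")
        # nearest matched critical ancestor (walk up through matched ones)
        a = anc[g]
        while a is not None and a not in match_of:
            a = anc[a]
        chosen, chosen_d = None, math.nan
        for i in order:
            if not ok[i]:
                continue
            tid = test_ids[int(i)]
            if tid in used_test:
                continue
            if a is not None:
                lg = nx.shortest_path_length(gold_graph, g, a, weight="weight")
                try:
                    lt = nx.shortest_path_length(
                        test_graph, tid, match_of[a], weight="weight"
                    )
                except nx.NetworkXNoPath:
                    continue
                band = params.path_length_tolerance * lg + params.path_length_slack
                if abs(lt - lg) > band:
                    continue
            chosen, chosen_d = tid, float(d3[int(i)])
            break
        kind = "terminal" if weights[g] == 1 and not gold.children(g) else "branch"
        if chosen is not None:
            used_test.add(chosen)
            match_of[g] = chosen
            matched.append(g)
            w_matched += weights[g]
        else:
            unmatched.append(g)
        rows.append(
            {
                "gold_id": g,
                "kind": kind,
                "weight": weights[g],
                "matched": chosen is not None,
                "test_id": chosen if chosen is not None else -1,
                "distance_um": chosen_d,
            }
        )

    score = w_matched / w_total if w_total > 0 else 0.0
    return MatchResult(
        score=score,
        matched_gold_nodes=matched,
        unmatched_gold_nodes=unmatched,
        weight_total=w_total,
        weight_matched=w_matched,
        rows=rows,
    )


def excess_cable(test: NeuronTree, gold: NeuronTree, params: MetricParams | None = None) -> float:
    """Cable length (μm) of test edges whose child node matches no gold node.

    Exposes over-tracing that the gold-centric score ignores.
    """
    params = params or MetricParams()
    gold_pos = gold.positions()
    total = 0.0
    for n in test.nodes:
        if n.parent_id == -1:
            continue
        p = np.asarray(n.position)
        d_lat = np.hypot(gold_pos[:, 0] - p[0], gold_pos[:, 1] - p[1])
        d_ax = np.abs(gold_pos[:, 2] - p[2])
        if not np.any((d_lat <= params.xy_threshold) & (d_ax <= params.z_threshold)):
            total += test.edge_length(n.id)
    return total
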