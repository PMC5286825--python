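"""Class-conditional pathway activity networks (PANs).

A PAN summarizes one class's pathway-set markers as a graph: nodes are the
pathways appearing in the class's markers, sized by ``-log2(p)`` of a
two-sample test on the pathway's continuous activity and colored by the
majority discretized state under the class condition (up = red, down =
blue in the figures this export feeds); an edge joins two pathways with
weight equal to the fraction of the class's markers containing both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .activity import DiscretizedActivity, PathwayActivityProfile, discretize_activity
from .io_formats import CASE, CONTROL
from .rulemining import PathwaySetMarker

_P_FLOOR = 1e-300


@dataclass
class PAN:
    """Per-class pathway graph with significance-scaled nodes."""

    klass: str
    graph: nx.Graph

    @property
    def nodes(self) -> dict:
        return {n: dict(d) for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> dict:
        return {frozenset((u, v)): dict(d) for u, v, d in self.graph.edges(data=True)}

    def weighted_degree(self, pathway: str) -> float:
        if pathway not in self.graph:
            return 0.0
        return float(sum(d.get("weight", 0.0)
                         for _, _, d in self.graph.edges(pathway, data=True)))


def neg_log2(p: float) -> float:
    """Node-size transform -log2(p), with p floored at 1e-300."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    return float(-np.log2(max(p, _P_FLOOR)))


def node_significance(activity_row, labels: Mapping[str, str]) -> float:
    """-log2(p) of a Welch two-sample t-test on a pathway's activity."""
    if isinstance(activity_row, pd.Series):
        samples = list(activity_row.index)
        vals = activity_row.to_numpy(dtype=float)
    else:
        raise TypeError("activity_row must be a pandas Series indexed by sample")
    case = vals[[labels[s] == CASE for s in samples]]
    ctrl = vals[[labels[s] == CONTROL for s in samples]]
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each class needs >=2 samples for the node test")
    return neg_log2(significance_p(case, ctrl))


def significance_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    """Welch t-test p-value, with identical-group degenerate case -> p=1."""
    if np.var(case) == 0 and np.var(ctrl) == 0:
        return 1.0 if case.mean() == ctrl.mean() else _P_FLOOR
    return float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)


def edge_frequencies(markers: Iterable[PathwaySetMarker],
                     ) -> dict[frozenset, dict]:
    """Pairwise pathway co-membership counts over a class's markers.

    Item direction is ignored: any marker containing both pathways (in any
    up/down combination) contributes one count to the pair.  Weights are
    counts divided by the number of markers.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("need at least one marker")
    counts: dict[frozenset, int] = {}
    for m in markers:
        for a, b in combinations(sorted(set(m.pathways)), 2):
            key = frozenset((a, b))
            counts[key] = counts.get(key, 0) + 1
    total = len(markers)
    return {k: {"count": c, "weight": c / total} for k, c in counts.items()}


def build_pan(markers: Iterable[PathwaySetMarker],
              profile: PathwayActivityProfile, labels: Mapping[str, str],
              klass: str,
              states: DiscretizedActivity | None = None) -> PAN:
    """Aggregate one class's markers into a PAN.

    Node direction is the majority discretized state over the class's
    samples (ties go down); node significance is computed from the
    continuous activity row.
    """
    markers = [m for m in markers if m.klass == klass]
    if not markers:
        raise ValueError(f"no markers for class {klass!r}")
    if states is None:
        states = discretize_activity(profile)
    g = nx.Graph(klass=klass)
    pathways = sorted({p for m in markers for p in m.pathways})
    class_cols = [s for s in profile.samples if labels.get(s) == klass]
    for p in pathways:
        if p not in profile.activities.index:
            raise KeyError(f"no activity row for pathway {p!r}")
        sig = node_significance(profile.activities.loc[p], labels)
        state_sum = int(states.states.loc[p, class_cols].sum())
        direction = "up" if state_sum > 0 else "down"
        g.add_node(p, significance=sig, direction=direction)
    for pair, attrs in edge_frequencies(markers).items():
        a, b = sorted(pair)
        g.add_edge(a, b, **attrs)
    return PAN(klass, g)


# ---------------------------------------------------------------------------
# export / import


def export_pan(pan: PAN, path, fmt: str = "graphml") -> None:
    """Write a PAN as GraphML, SIF (+ ``.attrs.tsv`` sidecar) or JSON."""
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(pan.graph, path)
    elif fmt == "json":
        payload = {
            "class": pan.klass,
            "nodes": [{"id": n, **d} for n, d in pan.graph.nodes(data=True)],
            "edges": [{"source": u, "target": v, **d}
                      for u, v, d in pan.graph.edges(data=True)],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            isolated = set(pan.graph.nodes)
            for u, v in pan.graph.edges():
                fh.write(f"{u}\tassociated_with\t{v}\n")
                isolated.discard(u)
                isolated.discard(v)
            for n in sorted(isolated):
                fh.write(f"{n}\n")
        with open(path + ".attrs.tsv", "w") as fh:
            fh.write("type\tname\tsignificance\tdirection\tweight\tcount\n")
            for n, d in pan.graph.nodes(data=True):
                fh.write(f"node\t{n}\t{d['significance']:.12g}\t{d['direction']}\t\t\n")
            for u, v, d in pan.graph.edges(data=True):
                fh.write(f"edge\t{u}|{v}\t\t\t{d['weight']:.12g}\t{d['count']}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def plot_pan(pan: PAN, ax=None, seed: int = 0):
    """Basic matplotlib rendering: node size ~ significance, red = up /
    blue = down, edge width ~ co-occurrence weight."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = pan.graph
    pos = nx.spring_layout(g, seed=seed)
    sizes = [120 * (1 + d["significance"]) for _, d in g.nodes(data=True)]
    colors = ["tab:red" if d["direction"] == "up" else "tab:blue"
              for _, d in g.nodes(data=True)]
    widths = [6 * d["weight"] for _, _, d in g.edges(data=True)]
    nx.draw_networkx_nodes(g, pos, node_size=sizes, node_color=colors, ax=ax,
                           alpha=0.85)
    nx.draw_networkx_edges(g, pos, width=widths, ax=ax, alpha=0.5)
    nx.draw_networkx_labels(g, pos, font_size=8, ax=ax)
    ax.set_title(f"PAN ({pan.klass})")
    ax.axis("off")
    return ax


def load_pan(path, fmt: str = "graphml") -> PAN:
    path = str(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        klass = g.graph.get("klass", "")
        return PAN(klass, g)
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        g = nx.Graph(klass=payload["class"])
        for node in payload["nodes"]:
            node = dict(node)
            g.add_node(node.pop("id"), **node)
        for edge in payload["edges"]:
            edge = dict(edge)
            g.add_edge(edge.pop("source"), edge.pop("target"), **edge)
        return PAN(payload["class"], g)
    raise ValueError(f"unsupported import format {fmt!r}")
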