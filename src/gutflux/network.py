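"""Metabolite networks of inflammation-associated reactions.

Nodes are metabolites; every substrate-product pair of an included
reaction contributes an undirected edge (parallel edges from different
reactions are merged, their reaction ids pooled).  Edge lengths are
log(deg(a) + deg(b)) with degrees taken from the final simple graph —
a hub penalty that discourages shortcuts through currency metabolites
without removing them.  Path analysis uses Dijkstra with deterministic
lexicographic tie-breaking; pairs of labeled metabolites (hub /
microbial / metabolomics hits) whose shortest path falls below the
lower 5% percentile of all pairwise distances are "closely connected".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_bh, enrich_hypergeometric

__all__ = [
    "CategoryLabels",
    "PathResult",
    "build_metabolite_graph",
    "shortest_paths",
    "all_pairs_distances",
    "select_short_pairs",
    "compare_category_paths",
    "enrich_path_reactions",
]

log = logging.getLogger(__name__)


@dataclass
class CategoryLabels:
    """Metabolite category sets mapped into the graph namespace:
    hub (enrichment hits), mic (microbial associations), met
    (metabolomics associations)."""

    hub: set[str] = field(default_factory=set)
    mic: set[str] = field(default_factory=set)
    met: set[str] = field(default_factory=set)

    def restrict(self, nodes: set[str]) -> "CategoryLabels":
        unmapped = (self.hub | self.mic | self.met) - nodes
        if unmapped:
            log.info("category labels not in graph: %s", sorted(unmapped)[:10])
        return CategoryLabels(
            hub=self.hub & nodes, mic=self.mic & nodes, met=self.met & nodes
        )

    def pair_tag(self, a: str, b: str) -> str | None:
        tags = []
        for x, y in ((a, b), (b, a)):
            if x in self.hub and y in self.met:
                tags.append("Hub-Met")
            if x in self.hub and y in self.mic:
                tags.append("Hub-Mic")
            if x in self.mic and y in self.met:
                tags.append("Mic-Met")
        return tags[0] if tags else None


@dataclass
class PathResult:
    source: str
    target: str
    distance: float
    nodes: list[str]
    reactions: list[str]
    tag: str = "all"


def build_metabolite_graph(
    reaction_ids: set[str],
    model,
    currency_exclude: set[str] | None = None,
) -> nx.Graph:
    """Graph over the metabolites of the given reactions.

    Every substrate-product pair becomes an edge (substrate-substrate
    pairs do not); reversibility is ignored.  ``currency_exclude``
    removes metabolites before edge construction (off by default: the
    hub penalty handles currency metabolites, and top hubs are
    themselves of interest)."""
    if not reaction_ids:
        raise ValueError("empty reaction set: nothing to build")
    skip = currency_exclude or set()
    g = nx.Graph()
    for rid in sorted(reaction_ids):
        r = model.reaction(rid)
        subs = [m for m, c in r.stoichiometry.items() if c < 0 and m not in skip]
        prods = [m for m, c in r.stoichiometry.items() if c > 0 and m not in skip]
        for a in subs:
            for b in prods:
                if a == b:
                    continue
                if g.has_edge(a, b):
                    g.edges[a, b]["reactions"].add(rid)
                else:
                    g.add_edge(a, b, reactions={rid})
    for a, b in g.edges:
        g.edges[a, b]["length"] = math.log(g.degree[a] + g.degree[b])
    return g


def _lexicographic_path(g: nx.Graph, dist: dict[str, float], source: str, target: str) -> list[str]:
    """Reconstruct the lexicographically smallest shortest path by
    walking the predecessor DAG from the target backwards."""
    path = [target]
    node = target
    while node != source:
        preds = sorted(
            u for u in g.neighbors(node)
            if abs(dist.get(u, np.inf) + g.edges[u, node]["length"] - dist[node]) < 1e-9
        )
        node = preds[0]
        path.append(node)
    return path[::-1]


def shortest_paths(
    g: nx.Graph, pairs: list[tuple[str, str]], labels: CategoryLabels | None = None
) -> list[PathResult]:
    """Dijkstra distances and one deterministic shortest node/reaction
    sequence per requested pair; disconnected pairs are excluded."""
    by_source: dict[str, list[str]] = {}
    for a, b in pairs:
        by_source.setdefault(a, []).append(b)
    out: list[PathResult] = []
    for source, targets in by_source.items():
        dist = nx.single_source_dijkstra_path_length(g, source, weight="length")
        for t in targets:
            if t not in dist:
                continue
            if t == source:
                out.append(PathResult(source, t, 0.0, [source], []))
                continue
            nodes = _lexicographic_path(g, dist, source, t)
            rxns = [
                sorted(g.edges[u, v]["reactions"])[0]
                for u, v in zip(nodes, nodes[1:])
            ]
            tag = labels.pair_tag(source, t) if labels else None
            out.append(PathResult(source, t, float(dist[t]), nodes, rxns, tag or "all"))
    return out


def all_pairs_distances(g: nx.Graph) -> pd.DataFrame:
    """Finite pairwise shortest-path distances as a long frame."""
    rows = []
    for source, dist in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for target, d in dist.items():
            if source < target:
                rows.append((source, target, float(d)))
    return pd.DataFrame(rows, columns=["source", "target", "distance"])


def select_short_pairs(
    distances: pd.DataFrame,
    labels: CategoryLabels,
    pct: float = 5.0,
) -> pd.DataFrame:
    """Labeled category pairs whose distance is below the lower ``pct``
    percentile of ALL finite pairwise distances."""
    if distances.empty:
        return distances.assign(tag=[])
    cutoff = float(np.percentile(distances["distance"].to_numpy(), pct))
    tags = [
        labels.pair_tag(a, b)
        for a, b in zip(distances["source"], distances["target"])
    ]
    out = distances.assign(tag=tags)
    out = out[(out["tag"].notna()) & (out["distance"] < cutoff)]
    out.attrs["cutoff"] = cutoff
    return out.reset_index(drop=True)


def compare_category_paths(
    distances: pd.DataFrame, labels: CategoryLabels
) -> pd.DataFrame:
    """One-sided two-sample t-test (category pairs shorter than the
    rest) per category pair class, BH adjusted across the classes."""
    tags = np.array([
        labels.pair_tag(a, b) or "all"
        for a, b in zip(distances["source"], distances["target"])
    ])
    d = distances["distance"].to_numpy()
    rows = []
    for tag in ("Hub-Met", "Hub-Mic", "Mic-Met"):
        grp = d[tags == tag]
        rest = d[tags != tag]
        if len(grp) < 2 or len(rest) < 2:
            rows.append((tag, len(grp), np.nan, np.nan, np.nan))
            continue
        if np.std(grp, ddof=1) == 0 and np.std(rest, ddof=1) == 0:
            rows.append((tag, len(grp), float(grp.mean() - rest.mean()), np.nan, np.nan))
            continue
        t, p = sps.ttest_ind(grp, rest, equal_var=False, alternative="less")
        rows.append((tag, len(grp), float(grp.mean() - rest.mean()), float(t), float(p)))
    out = pd.DataFrame(
        rows, columns=["tag", "n", "mean_diff", "t", "p"]
    ).set_index("tag")
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def enrich_path_reactions(
    selected: list[PathResult] | pd.DataFrame,
    g: nx.Graph,
    subsystem_of: dict[str, str],
) -> pd.DataFrame:
    """Hypergeometric subsystem enrichment of the reactions lying on
    the selected short paths, against all reactions in the graph."""
    universe = {
        rid for _, _, data in g.edges(data=True) for rid in data["reactions"]
    }
    if isinstance(selected, pd.DataFrame):
        query: set[str] = set()
        for a, b in zip(selected["source"], selected["target"]):
            res = shortest_paths(g, [(a, b)])
            for pr in res:
                query |= set(pr.reactions)
    else:
        query = {rid for pr in selected for rid in pr.reactions}
    sets: dict[str, set[str]] = {}
    for rid in universe:
        sub = subsystem_of.get(rid, "")
        if sub:
            sets.setdefault(sub, set()).add(rid)
    return enrich_hypergeometric(query & universe, sets, universe)
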