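"""Attribute-group co-exposure networks and theme-prevalence tables.

Each demographic group (male, female, age 16, age 24, or the age x sex
conjunctions 16F/16M/24F/24M) is a node whose video set is the union of
unique video ids its profiles were shown; an edge between two groups is
weighted by the number of common videos (set intersection).  Weighted
degree centrality (sum of incident edge weights) summarizes how much a
group's exposure is shared with the rest of the design.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .synth import ProfileSpec, SearchResultSet, THEMES

Grouping = Callable[[ProfileSpec], str] | Mapping[str, str]


def by_sex(profile: ProfileSpec) -> str:
    return profile.sex


def by_age(profile: ProfileSpec) -> str:
    return f"age{profile.age}"


def by_age_sex(profile: ProfileSpec) -> str:
    return f"{profile.age}{'F' if profile.sex == 'female' else 'M'}"


def _group_of(profile: ProfileSpec, grouping: Grouping) -> str:
    if callable(grouping):
        g = grouping(profile)
    else:
        g = grouping.get(profile.profile_id)
    if g is None:
        raise ValueError(f"profile {profile.profile_id!r} has no group")
    return g


def group_videos(results: Iterable[SearchResultSet],
                 grouping: Grouping) -> dict[str, set[str]]:
    """Union of unique video ids over each group's result lists."""
    out: dict[str, set[str]] = {}
    for rs in results:
        g = _group_of(rs.profile, grouping)
        out.setdefault(g, set()).update(rs.results)
    return out


def common_videos(set_a: set[str], set_b: set[str]) -> int:
    """Number of videos two groups were both shown."""
    return len(set_a & set_b)


def build_attribute_network(results: Sequence[SearchResultSet],
                            mode: str = "age_by_sex") -> nx.Graph:
    """Weighted group network over search results.

    ``single_attribute`` mode uses the 4 marginal groups {male, female,
    age16, age24}; ``age_by_sex`` the 4 conjunction groups {16F, 16M,
    24F, 24M}.  Every group pair with a non-empty intersection gets an
    edge weighted by its common-video count; zero-weight edges are
    omitted.  Nodes carry their video-set size as ``n_videos``.
    """
    if not results:
        raise ValueError("results are empty")
    if mode == "single_attribute":
        sets = group_videos(results, by_sex)
        sets.update(group_videos(results, by_age))
    elif mode == "age_by_sex":
        sets = group_videos(results, by_age_sex)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    graph = nx.Graph(mode=mode)
    for g, vids in sorted(sets.items()):
        graph.add_node(g, n_videos=len(vids))
    groups = sorted(sets)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            w = common_videos(sets[a], sets[b])
            if w > 0:
                graph.add_edge(a, b, weight=w)
    graph.graph["node_videos"] = sets
    return graph


def degree_centrality(network: nx.Graph) -> pd.DataFrame:
    """Weighted (sum of incident edge weights) and unweighted degree."""
    if network.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    rows = {g: {"weighted_degree": float(wd), "degree": int(network.degree(g))}
            for g, wd in network.degree(weight="weight")}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def prevalence_by_group(predictions: Mapping[str, str],
                        results: Sequence[SearchResultSet],
                        grouping: Grouping,
                        labels: Sequence[str] = THEMES) -> pd.DataFrame:
    """Theme percentages over each group's unique videos (rows sum to 100).

    Every video surfaced to a group must have a predicted theme; missing
    predictions raise with the offending ids.
    """
    sets = group_videos(results, grouping)
    missing = sorted({v for vids in sets.values() for v in vids
                      if v not in predictions})
    if missing:
        raise ValueError(
            f"{len(missing)} videos lack predictions, e.g. {missing[:5]}")
    table = {}
    for g, vids in sorted(sets.items()):
        n = len(vids)
        counts = {c: 0 for c in labels}
        for v in vids:
            counts[predictions[v]] += 1
        table[g] = {c: round(100.0 * counts[c] / n, 1) for c in labels}
    return pd.DataFrame.from_dict(table, orient="index")[list(labels)]


def write_graphml(network: nx.Graph, path) -> None:
    export = nx.Graph()
    for g, data in network.nodes(data=True):
        export.add_node(g, group=g, n_videos=int(data.get("n_videos", 0)))
    for a, b, data in network.edges(data=True):
        export.add_edge(a, b, weight=int(data["weight"]))
    nx.write_graphml(export, path)


def write_edges_csv(network: nx.Graph, path) -> None:
    rows = [{"group_a": a, "group_b": b, "weight": int(d["weight"])}
            for a, b, d in sorted(network.edges(data=True))]
    pd.DataFrame(rows, columns=["group_a", "group_b", "weight"]).to_csv(
        path, index=False)
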