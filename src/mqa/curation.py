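"""Benchmark curation on precomputed similarity and identity tables.

Homology reduction of a structure set proceeds in three steps, all operating
on tables produced by external tools (MM-align scores, MMseqs2 identities):

1. cluster the MM-score similarity graph with the highly-connected-subgraphs
   (HCS) recursion at a score threshold (default 0.6, roughly "same fold"
   for a whole complex);
2. keep one representative per cluster — best resolution, ties broken by the
   smallest SEQRES-vs-ATOM length difference, then by id;
3. drop entries sharing >= 30% sequence identity (any chain, any hit)
   with a reference sequence set, e.g. a prediction method's training data.

The HCS recursion removes sub-threshold edges, then recursively splits each
connected component along a global minimum edge cut until every remaining
component G satisfies edge-connectivity(G) > |G|/2 (strict); singletons and
two-node components count as clusters.  To keep the procedure deterministic
the minimum cut is anchored at the lexicographically smallest node s: among
the sorted candidate sinks t achieving the global minimum cut value, the
first is used, and of all minimum s–t cuts the unique one with the minimal
source side (residual reachability) is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "EntryMeta",
    "build_similarity_graph",
    "hcs_cluster",
    "is_highly_connected",
    "select_representative",
    "identity_filter",
    "load_similarity_tsv",
    "load_identity_tsv",
    "load_meta_tsv",
]

HCS_MM_SCORE_THRESHOLD = 0.6
IDENTITY_THRESHOLD = 30.0


@dataclass(frozen=True)
class EntryMeta:
    id: str
    resolution: Optional[float] = None
    seqres_atom_diff: int = 0
    oligomeric_state: Optional[int] = None


# ---------------------------------------------------------------------------
# HCS clustering


def build_similarity_graph(
    edges: Iterable[Tuple[str, str, float]], nodes: Iterable[str] = ()
) -> nx.Graph:
    """Undirected similarity graph; self-loops dropped, scores validated."""
    G = nx.Graph()
    G.add_nodes_from(sorted(nodes))
    for a, b, score in edges:
        if a == b:
            continue
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"similarity score {score} outside [0, 1]")
        G.add_edge(a, b, mm_score=float(score))
    return G


def is_highly_connected(G: nx.Graph) -> bool:
    """Strict HCS condition: edge connectivity > n/2."""
    n = G.number_of_nodes()
    if n <= 2:
        return True
    return nx.edge_connectivity(G) > n / 2


def _min_cut_source_side(G: nx.Graph) -> Set:
    """Deterministic global minimum edge cut: the minimal source side.

    Anchored at s = min(G); for each sink t in sorted order a unit-capacity
    min s-t cut is computed, and the first t attaining the global minimum
    wins.  The returned source side is the set of nodes residual-reachable
    from s, which is the unique minimal source side among all minimum s-t
    cuts, so the result does not depend on max-flow internals.
    """
    nodes = sorted(G.nodes)
    s = nodes[0]
    D = nx.DiGraph()
    D.add_nodes_from(G.nodes)
    for u, v in G.edges:
        D.add_edge(u, v, capacity=1)
        D.add_edge(v, u, capacity=1)
    best_val: Optional[int] = None
    best_side: Optional[Set] = None
    for t in nodes[1:]:
        R = nx.algorithms.flow.edmonds_karp(D, s, t)
        val = R.graph["flow_value"]
        if best_val is None or val < best_val:
            # minimal source side = nodes residual-reachable from s
            side = {s}
            stack = [s]
            while stack:
                u = stack.pop()
                for v, data in R[u].items():
                    if v not in side and data["capacity"] - data["flow"] > 0:
                        side.add(v)
                        stack.append(v)
            best_val, best_side = val, side
    assert best_side is not None
    return best_side


def _hcs(G: nx.Graph) -> List[Set]:
    if G.number_of_nodes() <= 2:
        return [set(G.nodes)]
    if not nx.is_connected(G):
        out: List[Set] = []
        for comp in nx.connected_components(G):
            out.extend(_hcs(G.subgraph(comp).copy()))
        return out
    if is_highly_connected(G):
        return [set(G.nodes)]
    side = _min_cut_source_side(G)
    rest = set(G.nodes) - side
    return _hcs(G.subgraph(side).copy()) + _hcs(G.subgraph(rest).copy())


def hcs_cluster(
    graph: nx.Graph, threshold: float = HCS_MM_SCORE_THRESHOLD
) -> List[Set]:
    """Partition graph nodes into highly connected clusters.

    Edges scoring below *threshold* are removed first; each connected
    component then goes through the HCS recursion.  Clusters are returned
    sorted by (size desc, smallest member) for stable output.
    """
    H = nx.Graph()
    H.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        if data.get("mm_score", 1.0) >= threshold:
            H.add_edge(u, v)
    clusters: List[Set] = []
    for comp in nx.connected_components(H):
        clusters.extend(_hcs(H.subgraph(comp).copy()))
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# Representative selection


def select_representative(
    cluster: Iterable[str], meta: Mapping[str, EntryMeta]
) -> str:
    """Best-resolution member; ties by minimal SEQRES-vs-ATOM difference,
    then lexicographically.  Entries without a resolution lose to any entry
    that has one."""
    members = sorted(cluster)
    if not members:
        raise ValueError("empty cluster")
    missing = [m for m in members if m not in meta]
    if missing:
        raise KeyError(f"no metadata for cluster member(s) {missing}")

    def key(m: str):
        e = meta[m]
        res = e.resolution if e.resolution is not None else float("inf")
        return (res, e.seqres_atom_diff, m)

    return min(members, key=key)


# ---------------------------------------------------------------------------
# Identity filtering


def identity_filter(
    entries: Mapping[str, Sequence[str]],
    identity_table: pd.DataFrame,
    threshold: float = IDENTITY_THRESHOLD,
) -> Tuple[List[str], pd.DataFrame]:
    """Drop entries with any chain hitting the reference set at >= threshold.

    *entries* maps entry id -> its chain ids; *identity_table* needs columns
    (query_chain, target_chain, pct_identity).  Returns the retained entry
    ids (input order) and a removal ledger with the triggering hit per
    removed entry.
    """
    required = {"query_chain", "target_chain", "pct_identity"}
    if not required.issubset(identity_table.columns):
        raise ValueError(f"identity table needs columns {sorted(required)}")
    pct = identity_table["pct_identity"]
    if len(pct) and (pct.min() < 0 or pct.max() > 100):
        raise ValueError("pct_identity outside [0, 100]")

    hits = identity_table[pct >= threshold]
    best_hit = (
        hits.sort_values(["query_chain", "pct_identity"], ascending=[True, False])
        .groupby("query_chain", sort=False)
        .first()
        if len(hits)
        else pd.DataFrame(columns=["target_chain", "pct_identity"])
    )

    retained: List[str] = []
    removed_rows = []
    for entry_id, chains in entries.items():
        trigger = None
        for chain in chains:
            if chain in best_hit.index:
                row = best_hit.loc[chain]
                trigger = (chain, row["target_chain"], float(row["pct_identity"]))
                break
        if trigger is None:
            retained.append(entry_id)
        else:
            removed_rows.append(
                {
                    "entry": entry_id,
                    "chain": trigger[0],
                    "target": trigger[1],
                    "pct_identity": trigger[2],
                }
            )
    ledger = pd.DataFrame(
        removed_rows, columns=["entry", "chain", "target", "pct_identity"]
    )
    return retained, ledger


# ---------------------------------------------------------------------------
# TSV loaders


def load_similarity_tsv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    return build_similarity_graph(
        (str(r[cols[0]]), str(r[cols[1]]), float(r[cols[2]]))
        for _, r in df.iterrows()
    )


def load_identity_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["query_chain", "target_chain", "pct_identity"]))
    )
    return df


def load_meta_tsv(path: str | Path) -> Dict[str, EntryMeta]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, EntryMeta] = {}
    for _, row in df.iterrows():
        res = row.get("resolution")
        out[str(row["id"])] = EntryMeta(
            id=str(row["id"]),
            resolution=None if pd.isna(res) else float(res),
            seqres_atom_diff=int(row.get("seqres_atom_diff", 0)),
            oligomeric_state=(
                int(row["oligomeric_state"]) if "oligomeric_state" in row and not pd.isna(row["oligomeric_state"]) else None
            ),
        )
    return out
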