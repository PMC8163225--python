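"""Compound graph of a metabolic network and its topological operations.

The compound graph has metabolites as nodes, connected whenever they are
substrate and product of the same reaction (undirected; reversibility is
ignored for path mining).  The operations mirror the standard preparation
of a genome-scale network for path analysis:

* compartment collapse (one node per metabolite regardless of organelle),
* side-compound removal (H2O, CO2, NAD, ATP/ADP/AMP and their deoxy
  counterparts create biologically meaningless shortcuts),
* carbon-transfer filtering (edges whose reaction moves no carbon atom
  between the two metabolites are pruned; flags come from precomputed atom
  mappings),
* lightest paths minimizing the sum of squared node degrees — biasing the
  route away from residual hubs toward informative biochemical chains —
  plus subnetwork extraction and pairwise distance matrices built on them.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundGraph",
    "LightestPath",
    "PathDistanceMatrix",
    "NetworkParseError",
    "DEFAULT_SIDE_COMPOUNDS",
    "load_network",
    "load_sbml",
    "collapse_compartments",
    "remove_side_compounds",
    "carbon_filter",
    "lightest_path",
    "extract_subnetwork",
    "path_distance_matrix",
]

#: Ubiquitous auxiliary metabolites excluded from topological analysis by
#: default.  User-overridable: pass any list to :func:`remove_side_compounds`.
DEFAULT_SIDE_COMPOUNDS = [
    "h2o", "h", "co2", "o2", "pi", "ppi", "h2o2", "nh4",
    "nad", "nadh", "nadp", "nadph", "fad", "fadh2",
    "atp", "adp", "amp", "datp", "dadp", "damp",
    "gtp", "gdp", "gmp", "dgtp", "dgdp", "dgmp",
    "ctp", "cdp", "cmp", "dctp", "dcdp", "dcmp",
    "utp", "udp", "ump", "dutp", "dudp", "dump",
    "coa", "accoa", "so4", "cl", "na1", "k",
]


class NetworkParseError(ValueError):
    pass


@dataclass
class CompoundGraph:
    """Undirected metabolite graph with pathway annotations.

    Node attributes: ``name``, ``pathways`` (set of pathway ids),
    ``side_compound`` (bool), ``external_ids`` (dict), optional ``seed`` /
    ``intermediate`` flags on extracted subnetworks.
    Edge attributes: ``reactions`` (set of reaction ids), ``carbon_transfer``
    (bool; OR over the merged reactions).
    """

    g: nx.Graph = field(default_factory=nx.Graph)
    pathways: dict[str, str] = field(default_factory=dict)  # pathway id -> display name

    # -- construction -----------------------------------------------------
    def add_metabolite(
        self,
        node_id: str,
        name: str = "",
        pathways: set[str] | None = None,
        side_compound: bool = False,
        external_ids: dict[str, str] | None = None,
    ) -> None:
        self.g.add_node(
            node_id,
            name=name or node_id,
            pathways=set(pathways or ()),
            side_compound=bool(side_compound),
            external_ids=dict(external_ids or {}),
        )

    def add_reaction_edge(
        self, u: str, v: str, reaction: str, carbon_transfer: bool
    ) -> None:
        """Add one substrate-product link; parallel edges from distinct
        reactions are merged keeping carbon_transfer = OR."""
        if u == v:
            return  # no self-loops
        for n in (u, v):
            if n not in self.g:
                raise NetworkParseError(f"edge {u}-{v} (reaction {reaction}): unknown node {n!r}")
        if self.g.has_edge(u, v):
            data = self.g.edges[u, v]
            data["reactions"].add(reaction)
            data["carbon_transfer"] = bool(data["carbon_transfer"]) or bool(carbon_transfer)
        else:
            self.g.add_edge(u, v, reactions={reaction}, carbon_transfer=bool(carbon_transfer))

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    @property
    def n_reactions(self) -> int:
        return len({r for _, _, d in self.g.edges(data=True) for r in d["reactions"]})

    def node_pathways(self, node_id: str) -> set[str]:
        return self.g.nodes[node_id]["pathways"]

    def pathway_members(self) -> dict[str, set[str]]:
        """pathway id -> set of member node ids."""
        out: dict[str, set[str]] = {p: set() for p in self.pathways}
        for n, data in self.g.nodes(data=True):
            for p in data["pathways"]:
                out.setdefault(p, set()).add(n)
        return out

    def copy(self) -> "CompoundGraph":
        return CompoundGraph(g=self.g.copy(), pathways=dict(self.pathways))

    # -- I/O ---------------------------------------------------------------
    def export_tables(self, directory: str | Path) -> None:
        """Write node and edge tables (plus a plain edge list for graph viz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            [
                {
                    "id": n,
                    "name": d["name"],
                    "pathways": ";".join(sorted(d["pathways"])),
                    "side_compound": int(d["side_compound"]),
                    "external_ids": ";".join(f"{k}={v}" for k, v in sorted(d["external_ids"].items())),
                    "seed": int(d.get("seed", False)),
                }
                for n, d in sorted(self.g.nodes(data=True))
            ]
        )
        nodes.to_csv(directory / "nodes.tsv", sep="\t", index=False)
        edges = pd.DataFrame(
            [
                {
                    "u": u,
                    "v": v,
                    "reactions": ";".join(sorted(d["reactions"])),
                    "carbon_transfer": int(d["carbon_transfer"]),
                }
                for u, v, d in sorted(self.g.edges(data=True), key=lambda e: (e[0], e[1]))
            ]
        )
        edges.to_csv(directory / "edges.tsv", sep="\t", index=False)


@dataclass
class LightestPath:
    """A path and its cost = sum of squared degrees of its nodes (endpoints included)."""

    nodes: list[str]
    cost: float
    connected: bool = True

    @classmethod
    def disconnected(cls, source: str, target: str) -> "LightestPath":
        return cls(nodes=[], cost=float("inf"), connected=False)


@dataclass
class PathDistanceMatrix:
    """Symmetric lightest-path cost matrix over a metabolite subset.

    Disconnected pairs receive a sentinel distance (twice the largest finite
    entry, or a configured fallback when nothing is connected) and are
    listed in ``disconnected_pairs``.
    """

    matrix: pd.DataFrame
    disconnected_pairs: list[tuple[str, str]] = field(default_factory=list)
    sentinel: float | None = None


# ---------------------------------------------------------------------------
# loading


def load_network(
    nodes_file: str | Path, edges_file: str | Path, pathway_names: dict[str, str] | None = None
) -> CompoundGraph:
    """Load the native tabular schema.

    ``nodes_file``: delimited columns ``id``, ``name``, ``pathways``
    (semicolon-separated), ``side_compound`` (0/1), optional
    ``external_ids`` (``key=value`` pairs, semicolon-separated).
    ``edges_file``: columns ``u``, ``v``, ``reaction``, ``carbon_transfer``.
    """
    graph = CompoundGraph(pathways=dict(pathway_names or {}))
    nodes = pd.read_csv(nodes_file, sep="\t", dtype=str).fillna("")
    for col in ("id",):
        if col not in nodes.columns:
            raise NetworkParseError(f"nodes file lacks column {col!r}")
    for _, row in nodes.iterrows():
        ext = {}
        for pair in str(row.get("external_ids", "")).split(";"):
            if "=" in pair:
                k, v = pair.split("=", 1)
                ext[k.strip()] = v.strip()
        pw = {p for p in str(row.get("pathways", "")).split(";") if p}
        graph.add_metabolite(
            str(row["id"]),
            name=str(row.get("name", "")) or str(row["id"]),
            pathways=pw,
            side_compound=str(row.get("side_compound", "0")).strip() in {"1", "true", "True"},
            external_ids=ext,
        )
        for p in pw:
            graph.pathways.setdefault(p, p)
    edges = pd.read_csv(edges_file, sep="\t", dtype=str).fillna("")
    rxn_col = "reaction" if "reaction" in edges.columns else "reactions"
    if rxn_col not in edges.columns:
        raise NetworkParseError("edges file lacks a 'reaction' column")
    for i, row in edges.iterrows():
        flag = str(row.get("carbon_transfer", "")).strip()
        if flag not in {"0", "1", "true", "false", "True", "False"}:
            raise NetworkParseError(
                f"edges file record {i}: carbon_transfer flag missing or invalid ({flag!r})"
            )
        try:
            for rxn in str(row[rxn_col]).split(";"):
                graph.add_reaction_edge(
                    str(row["u"]), str(row["v"]), rxn, flag in {"1", "true", "True"}
                )
        except NetworkParseError as e:
            raise NetworkParseError(f"edges file record {i}: {e}") from None
    logger.info(
        "loaded network: %d pathways, %d metabolites, %d reactions",
        len(graph.pathways), graph.n_nodes, graph.n_reactions,
    )
    return graph


def load_sbml(path: str | Path) -> CompoundGraph:
    """Optional SBML ingestion: species become nodes, reactions become edges
    between every substrate-product pair.  Carbon-transfer flags are not part
    of SBML; edges default to True and should be overridden from atom-mapping
    data when available."""
    try:
        import libsbml
    except ImportError as e:  # pragma: no cover
        raise ImportError("SBML support requires python-libsbml") from e
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors() and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise NetworkParseError(f"SBML parse error: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise NetworkParseError("SBML file contains no model")
    graph = CompoundGraph()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        graph.add_metabolite(sp.getId(), name=sp.getName() or sp.getId())
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        subs = [rxn.getReactant(j).getSpecies() for j in range(rxn.getNumReactants())]
        prods = [rxn.getProduct(j).getSpecies() for j in range(rxn.getNumProducts())]
        for u in subs:
            for v in prods:
                if u in graph.g and v in graph.g:
                    graph.add_reaction_edge(u, v, rxn.getId(), carbon_transfer=True)
    return graph


# ---------------------------------------------------------------------------
# topological preparation


def collapse_compartments(
    graph: CompoundGraph, suffix_pattern: str = r"_[a-z0-9]{1,2}$"
) -> CompoundGraph:
    """Merge nodes that differ only by a compartment suffix.

    Transport reactions (edges between two compartments of the same
    metabolite) become self-loops and are deleted; pathway memberships and
    external ids are unioned; the carbon flag of merged parallel edges is
    the OR over the originals.
    """
    pattern = re.compile(suffix_pattern)

    def strip(node_id: str) -> str:
        stripped = pattern.sub("", node_id)
        if not stripped:
            raise NetworkParseError(
                f"compartment pattern {suffix_pattern!r} matches the whole id {node_id!r}"
            )
        return stripped

    out = CompoundGraph(pathways=dict(graph.pathways))
    for n, d in graph.g.nodes(data=True):
        s = strip(n)
        if s in out.g:
            data = out.g.nodes[s]
            data["pathways"] |= d["pathways"]
            data["side_compound"] = data["side_compound"] or d["side_compound"]
            for k, v in d["external_ids"].items():
                data["external_ids"].setdefault(k, v)
        else:
            out.add_metabolite(
                s,
                name=pattern.sub("", d["name"]) or d["name"],
                pathways=set(d["pathways"]),
                side_compound=d["side_compound"],
                external_ids=dict(d["external_ids"]),
            )
    for u, v, d in graph.g.edges(data=True):
        su, sv = strip(u), strip(v)
        if su == sv:
            continue  # transport self-loop
        for r in sorted(d["reactions"]):
            out.add_reaction_edge(su, sv, r, d["carbon_transfer"])
    return out


def remove_side_compounds(
    graph: CompoundGraph, side_list: list[str] | None = None
) -> CompoundGraph:
    """Delete side compounds (and their incident edges) from the graph.

    ``side_list`` defaults to nodes flagged ``side_compound`` plus the
    shipped :data:`DEFAULT_SIDE_COMPOUNDS`; unknown ids are ignored with a
    warning.
    """
    out = graph.copy()
    explicit = side_list is not None
    if side_list is None:
        side_list = list(DEFAULT_SIDE_COMPOUNDS) + [
            n for n, d in graph.g.nodes(data=True) if d["side_compound"]
        ]
    present = [n for n in dict.fromkeys(side_list) if n in out.g]
    unknown = [n for n in dict.fromkeys(side_list) if n not in out.g]
    if unknown and explicit:
        warnings.warn(
            f"{len(unknown)} side-compound id(s) not in the graph were ignored",
            UserWarning,
            stacklevel=2,
        )
    out.g.remove_nodes_from(present)
    return out


def carbon_filter(graph: CompoundGraph) -> CompoundGraph:
    """Remove edges that transfer no carbon atom; keep all nodes."""
    out = graph.copy()
    drop = []
    for u, v, d in out.g.edges(data=True):
        if "carbon_transfer" not in d:
            raise NetworkParseError(f"edge {u}-{v} lacks a carbon_transfer flag")
        if not d["carbon_transfer"]:
            drop.append((u, v))
    out.g.remove_edges_from(drop)
    return out


# ---------------------------------------------------------------------------
# lightest paths


def lightest_path(graph: CompoundGraph, source: str, target: str) -> LightestPath:
    """Lightest path: minimize the sum of squared node degrees along the path.

    Degrees are those of the *current* (already filtered) graph; endpoints
    are included in the sum and ``distance(u, u) = 0`` by convention.  Ties
    are broken by fewer nodes, then by lexicographically smallest node
    sequence, so results are reproducible.  A missing route yields an
    explicit disconnected result, not an exception.
    """
    g = graph.g
    for n in (source, target):
        if n not in g:
            raise KeyError(f"node {n!r} not in graph")
    if source == target:
        return LightestPath(nodes=[source], cost=0.0)
    deg = dict(g.degree())
    # Dijkstra where entering node v costs deg(v)^2; the source's own cost
    # is added at the end.  Heap entries carry (cost, n_nodes, path) so the
    # tie-break order is exactly (cost, length, lexicographic sequence).
    start = (0.0, 1, (source,))
    heap = [start]
    best: dict[str, tuple[float, int, tuple[str, ...]]] = {}
    while heap:
        cost, length, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (cost, length, path) > best[node]:
            continue
        if node == target:
            total = cost + deg[source] ** 2
            return LightestPath(nodes=list(path), cost=float(total))
        for nbr in g.neighbors(node):
            if nbr in path:
                continue
            cand = (cost + deg[nbr] ** 2, length + 1, path + (nbr,))
            if nbr not in best or cand < best[nbr]:
                best[nbr] = cand
                heapq.heappush(heap, cand)
    return LightestPath.disconnected(source, target)


def extract_subnetwork(graph: CompoundGraph, seeds: set[str]) -> CompoundGraph:
    """Union of pairwise lightest paths between seed nodes.

    Returns the subgraph restricted to nodes and edges used by at least one
    returned path; seeds are flagged ``seed=True`` and connecting nodes
    ``intermediate=True`` (the distinction the network figures draw in
    bold).  Disconnected seed pairs are skipped with a log entry.
    """
    if not seeds:
        raise ValueError("empty seed set")
    missing = sorted(s for s in seeds if s not in graph.g)
    if missing:
        raise KeyError(f"seed nodes not in graph: {', '.join(missing)}")
    used_nodes: set[str] = set(seeds)
    used_edges: set[tuple[str, str]] = set()
    for u, v in itertools.combinations(sorted(seeds), 2):
        lp = lightest_path(graph, u, v)
        if not lp.connected:
            logger.info("seed pair (%s, %s) is disconnected; skipped", u, v)
            continue
        used_nodes.update(lp.nodes)
        for a, b in zip(lp.nodes, lp.nodes[1:]):
            used_edges.add((min(a, b), max(a, b)))
    out = CompoundGraph(pathways=dict(graph.pathways))
    for n in sorted(used_nodes):
        d = graph.g.nodes[n]
        out.add_metabolite(n, d["name"], set(d["pathways"]), d["side_compound"], dict(d["external_ids"]))
        out.g.nodes[n]["seed"] = n in seeds
        out.g.nodes[n]["intermediate"] = n not in seeds
    for a, b in sorted(used_edges):
        d = graph.g.edges[a, b]
        for r in sorted(d["reactions"]):
            out.add_reaction_edge(a, b, r, d["carbon_transfer"])
    return out


def path_distance_matrix(
    graph: CompoundGraph, subset: list[str], fallback_sentinel: float = 1.0
) -> PathDistanceMatrix:
    """Pairwise lightest-path cost matrix over ``subset``.

    Entry (i, j) is the lightest-path cost between subset members in the
    supplied (already filtered) graph.  Disconnected pairs are set to twice
    the largest finite off-diagonal entry — under complete linkage this
    forces separate components to merge last — or to ``fallback_sentinel``
    when no pair is connected; all such pairs are flagged.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 nodes")
    if len(set(subset)) != len(subset):
        raise ValueError("subset contains duplicates")
    missing = [s for s in subset if s not in graph.g]
    if missing:
        raise KeyError(f"subset nodes not in graph: {', '.join(missing)}")
    import numpy as np

    n = len(subset)
    mat = np.zeros((n, n))
    disconnected: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            lp = lightest_path(graph, subset[i], subset[j])
            if lp.connected:
                mat[i, j] = mat[j, i] = lp.cost
            else:
                mat[i, j] = mat[j, i] = np.inf
                disconnected.append((subset[i], subset[j]))
    finite = mat[np.isfinite(mat)]
    sentinel = None
    if disconnected:
        finite_max = float(finite.max()) if finite.size and finite.max() > 0 else 0.0
        sentinel = 2.0 * finite_max if finite_max > 0 else float(fallback_sentinel)
        mat[~np.isfinite(mat)] = sentinel
    return PathDistanceMatrix(
        matrix=pd.DataFrame(mat, index=subset, columns=subset),
        disconnected_pairs=disconnected,
        sentinel=sentinel,
    )
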