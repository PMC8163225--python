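"""Identifier mapping and pathway over-representation analysis (ORA).

Markers selected from the chemometric model are mapped onto the metabolic
network by exact identifier matching (after normalization), and each
pathway is tested for over-representation of the mapped selection with the
right-tailed hypergeometric test (equivalently the one-sided Fisher exact
test on the 2x2 table), corrected with the Benjamini-Hochberg step-up FDR
procedure.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .metnet import CompoundGraph

__all__ = ["MappingResult", "OraResult", "map_identifiers", "ora", "neg_log10"]

#: identifier fields tried in order; first hit wins
DEFAULT_ID_PRIORITY = ("id", "name", "kegg", "hmdb", "chebi", "inchikey")

_COMPARTMENT_SUFFIX = re.compile(r"_[a-z0-9]{1,2}$")


def _normalize(ident: str) -> str:
    s = str(ident).strip().casefold()
    stripped = _COMPARTMENT_SUFFIX.sub("", s)
    return stripped if stripped else s


@dataclass
class MappingResult:
    mapped: list[tuple[str, str]]  # (query id, network node id)
    unmapped: list[str]

    @property
    def mapping_rate(self) -> float:
        """Percent of queries mapped."""
        total = len(self.mapped) + len(self.unmapped)
        return len(self.mapped) / total * 100.0

    @property
    def mapped_nodes(self) -> set[str]:
        return {node for _, node in self.mapped}


@dataclass
class OraResult:
    """Per-pathway enrichment table sorted by (q, p, pathway id)."""

    table: pd.DataFrame  # columns: pathway, K, k, p_value, q_value, neg_log10_q

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] <= alpha]

    def export(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def map_identifiers(
    queries: list[dict],
    graph: CompoundGraph,
    priority: tuple[str, ...] = DEFAULT_ID_PRIORITY,
) -> MappingResult:
    """Map query records onto network nodes by normalized exact match.

    Each query is a dict with a ``"query_id"`` key and one or more
    identifier fields (``name``, external database ids...).  Normalization
    case-folds, trims, and strips a trailing compartment suffix.  Identifier
    types are tried in ``priority`` order against the nodes' id, name and
    external ids; the first hit wins, so mapping is deterministic.
    """
    if not queries:
        raise ValueError("empty query list: mapping rate is undefined")
    qids = [str(q["query_id"]) for q in queries]
    if len(set(qids)) != len(qids):
        dupes = sorted({q for q in qids if qids.count(q) > 1})
        raise ValueError(f"duplicate query ids: {', '.join(dupes)}")

    # one lookup per identifier type so priority order is respected
    lookup: dict[str, dict[str, str]] = {}
    for node, data in sorted(graph.g.nodes(data=True)):
        keys = {"id": node, "name": data.get("name", "")}
        keys.update(data.get("external_ids", {}))
        for id_type, value in keys.items():
            if value:
                lookup.setdefault(id_type, {}).setdefault(_normalize(value), node)

    mapped: list[tuple[str, str]] = []
    unmapped: list[str] = []
    for q in queries:
        hit = None
        for id_type in priority:
            value = q.get(id_type)
            if not value:
                continue
            norm = _normalize(value)
            # same-type match first, then against node ids/names
            for t in (id_type, "id", "name"):
                if norm in lookup.get(t, {}):
                    hit = lookup[t][norm]
                    break
            if hit is not None:
                break
        if hit is None:
            unmapped.append(str(q["query_id"]))
        else:
            mapped.append((str(q["query_id"]), hit))
    return MappingResult(mapped=mapped, unmapped=unmapped)


def ora(
    selected: set[str],
    universe: set[str],
    pathways: dict[str, set[str]],
) -> OraResult:
    """Right-tailed hypergeometric over-representation test per pathway.

    With population N = |universe|, successes K = |pathway ∩ universe| and
    draws n = |selected|, the p-value is P(X >= k) for the observed overlap
    k.  Pathways with K = 0 are skipped (untestable sets would only dilute
    the FDR denominator); Benjamini-Hochberg q-values are computed across
    the tested pathways.
    """
    extra = selected - universe
    if extra:
        raise ValueError(
            f"selected ids outside the universe: {', '.join(sorted(extra)[:10])}"
        )
    N, n = len(universe), len(selected)
    rows = []
    for pid in sorted(pathways):
        members = pathways[pid] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": pid, "K": K, "k": k, "p_value": min(p, 1.0)})
    if not rows:
        return OraResult(pd.DataFrame(columns=["pathway", "K", "k", "p_value", "q_value", "neg_log10_q"]))
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
    df["q_value"] = q
    df["neg_log10_q"] = [neg_log10(v) for v in df["q_value"]]
    df = df.sort_values(["q_value", "p_value", "pathway"], kind="stable").reset_index(drop=True)
    return OraResult(df)


def neg_log10(p: float) -> float:
    """-log10 of a p-value or threshold, rounded to 3 decimals for display."""
    if not 0 < p <= 1:
        raise ValueError(f"input must be in (0, 1], got {p}")
    return round(-math.log10(p), 3) + 0.0  # normalize -0.0
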