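"""Bipartite miRNA->gene regulatory networks with PPI overlay and hub analysis.

Networks are undirected :class:`networkx.Graph` objects whose nodes carry a
``kind`` attribute (``mirna`` or ``gene``) and whose edges carry a ``kind``
of ``regulatory`` (always miRNA-gene) or ``ppi`` (always gene-gene).
Protein-protein interaction edges are only admitted between genes already
present in the regulatory network: the overlay illustrates interactions
among targets, it does not grow the node set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("neutronet")


def build_network(
    significant_pairs: list[tuple[str, str]],
    ppi_edges: list[tuple[str, str]] | None = None,
) -> nx.Graph:
    """Union of (miRNA, gene) pairs plus optional gene-gene PPI edges."""
    if not significant_pairs:
        raise ValueError("pair list must be non-empty")
    g = nx.Graph()
    mirnas = {m for m, _ in significant_pairs}
    genes = {t for _, t in significant_pairs}
    both = mirnas & genes
    if both:
        raise ValidationError(f"identifiers appear as both miRNA and gene: {sorted(both)[:5]}")
    for m in sorted(mirnas):
        g.add_node(m, kind="mirna")
    for t in sorted(genes):
        g.add_node(t, kind="gene")
    for m, t in significant_pairs:
        if m == t:
            raise ValidationError(f"self-edge: {m!r}")
        g.add_edge(m, t, kind="regulatory")
    if ppi_edges:
        skipped = 0
        for a, b in ppi_edges:
            if a in mirnas or b in mirnas:
                raise ValidationError(f"PPI edge names a miRNA: ({a!r}, {b!r})")
            if a == b:
                raise ValidationError(f"PPI self-edge: {a!r}")
            if a in genes and b in genes:
                if not g.has_edge(a, b):
                    g.add_edge(a, b, kind="ppi")
            else:
                skipped += 1
        if skipped:
            logger.info("%d PPI edges with endpoints outside the network were ignored", skipped)
    return g


def _direction(table: pd.DataFrame, node: str, p_max: float) -> str | None:
    """'up'/'down' for a significant node, None if missing or not significant."""
    if node not in table.index:
        return None
    row = table.loc[node]
    if row["p"] > p_max or row["mean_a"] == row["mean_b"]:
        return None
    return "up" if row["mean_a"] > row["mean_b"] else "down"


def filter_by_direction(
    network: nx.Graph,
    mirna_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    mode: str,
    p_max: float = 0.05,
) -> nx.Graph:
    """Keep regulatory edges whose endpoints move in opposite directions.

    ``mode`` is ``up_mirna_down_gene`` or ``down_mirna_up_gene``; both
    endpoints must be significant (p <= p_max) in their differential tables
    with the mode's signs.  Orphaned nodes are removed and PPI edges are
    kept only when both endpoints survive.  The output is always a subgraph
    of the input.
    """
    modes = {"up_mirna_down_gene": ("up", "down"), "down_mirna_up_gene": ("down", "up")}
    if mode not in modes:
        raise ValueError(f"unknown mode: {mode!r}")
    want_mirna, want_gene = modes[mode]
    missing = [n for n, d in network.nodes(data=True)
               if n not in (mirna_table.index if d["kind"] == "mirna" else gene_table.index)]
    if missing:
        logger.info("%d network nodes are absent from the differential tables and were dropped", len(missing))

    out = nx.Graph()
    for a, b, data in network.edges(data=True):
        if data["kind"] != "regulatory":
            continue
        m, t = (a, b) if network.nodes[a]["kind"] == "mirna" else (b, a)
        if (_direction(mirna_table, m, p_max) == want_mirna
                and _direction(gene_table, t, p_max) == want_gene):
            out.add_node(m, kind="mirna", direction=want_mirna)
            out.add_node(t, kind="gene", direction=want_gene)
            out.add_edge(m, t, kind="regulatory")
    for a, b, data in network.edges(data=True):
        if data["kind"] == "ppi" and out.has_node(a) and out.has_node(b):
            out.add_edge(a, b, kind="ppi")
    return out


def find_hubs(network: nx.Graph, fraction: float = 0.05) -> list[tuple[str, int]]:
    """Top-degree miRNA nodes; hub count = ceil(fraction x miRNA count).

    Sorted by degree descending then id ascending; ties beyond the count
    are excluded deterministically by id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    mirnas = [n for n, d in network.nodes(data=True) if d.get("kind") == "mirna"]
    if not mirnas:
        raise ValueError("network has no miRNA nodes")
    ranked = sorted(mirnas, key=lambda n: (-network.degree[n], n))
    k = math.ceil(fraction * len(mirnas))
    return [(n, network.degree[n]) for n in ranked[:k]]


def connected_components(network: nx.Graph) -> list[set[str]]:
    """Undirected components over all edge kinds, largest first.

    Deterministic ordering: size descending, then smallest member id.
    """
    comps = [set(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric upper-tail overlap between two sets in a universe."""

    k_observed: int
    size_a: int
    size_b: int
    universe: int
    p_value: float

    @property
    def frac_a(self) -> float:
        """Overlap as a fraction of |A| (e.g. shared / differentially expressed)."""
        return self.k_observed / self.size_a

    @property
    def frac_b(self) -> float:
        return self.k_observed / self.size_b


def overlap_test(set_a, set_b, universe_size: int) -> OverlapResult:
    """P(X >= k) for X ~ Hypergeometric(universe, |A|, |B|), k = |A ∩ B|.

    The universe size is always explicit — overlap p-values are meaningless
    without stating the population the two sets were drawn from.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError(f"universe ({universe_size}) smaller than |A ∪ B| ({len(a | b)})")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return OverlapResult(k, len(a), len(b), universe_size, min(p, 1.0))


_SIF_RELATION = {"regulatory": "represses", "ppi": "pp"}


def export_network(network: nx.Graph, format: str, path: str | Path) -> None:
    """Write SIF or GraphML with deterministic ordering.

    SIF lines are ``source<TAB>relation<TAB>target`` sorted lexicographically;
    isolated nodes cannot be represented in SIF (a documented limitation of
    the format) but are carried by GraphML along with node ``kind`` and
    ``direction`` attributes.
    """
    path = Path(path)
    if format == "SIF":
        lines = []
        for a, b, data in network.edges(data=True):
            src, dst = sorted((a, b))
            if data["kind"] == "regulatory" and network.nodes[a]["kind"] == "mirna":
                src, dst = a, b
            elif data["kind"] == "regulatory":
                src, dst = b, a
            lines.append(f"{src}\t{_SIF_RELATION[data['kind']]}\t{dst}")
        path.write_text("\n".join(sorted(lines)) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "GraphML":
        ordered = nx.Graph()
        for n in sorted(network.nodes):
            attrs = {k: v for k, v in network.nodes[n].items() if v is not None}
            ordered.add_node(n, **attrs)
        for a, b in sorted(map(tuple, map(sorted, network.edges))):
            ordered.add_edge(a, b, **network.edges[a, b])
        nx.write_graphml(ordered, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")
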