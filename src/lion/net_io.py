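"""Read, validate and assemble the three interaction layers.

The multi-level network has three node classes — lncRNAs, proteins and
diseases — and three edge layers: lncRNA–protein attachments, protein–protein
interactions (PPI), and disease–protein (disease gene) associations.  Edges
arrive as 2+-column tab-separated files; identifiers are normalized to
uppercase with surrounding whitespace stripped, because gene symbols and
lncRNA names are case-inconsistent across the source databases.  PPI edges
are undirected and unweighted; reversed duplicates collapse to a single
canonical (sorted) pair and self-loops are dropped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from statistics import median
from typing import Iterable

import pandas as pd

from .exceptions import InputError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeKind",
    "Node",
    "EdgeLayer",
    "TripartiteNetwork",
    "NetworkSummary",
    "normalize_id",
    "layer_from_pairs",
    "read_edge_list",
    "write_edge_list",
    "build_tripartite",
    "summarize",
]


class NodeKind(str, Enum):
    PROTEIN = "PROTEIN"
    LNCRNA = "LNCRNA"
    DISEASE = "DISEASE"


@dataclass(frozen=True, order=True)
class Node:
    kind: NodeKind
    identifier: str


def normalize_id(raw: str) -> str:
    """Uppercase + strip normalization applied to every identifier."""
    return raw.strip().upper()


def _canonical(source_kind: NodeKind, target_kind: NodeKind,
               src: str, tgt: str) -> tuple[str, str]:
    if source_kind == target_kind:
        return (src, tgt) if src <= tgt else (tgt, src)
    return (src, tgt)


@dataclass(frozen=True)
class EdgeLayer:
    """One edge layer of the tripartite network.

    ``edges`` holds canonicalized identifier pairs: sorted for same-kind
    (PPI) layers, (source, target) for cross-kind layers.  Self-loops are
    only meaningful for same-kind layers — for cross-kind layers equal
    identifiers denote two distinct nodes of different kinds.
    """

    source_kind: NodeKind
    target_kind: NodeKind
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def source_nodes(self) -> set[str]:
        if self.source_kind == self.target_kind:
            return {n for e in self.edges for n in e}
        return {e[0] for e in self.edges}

    def target_nodes(self) -> set[str]:
        if self.source_kind == self.target_kind:
            return {n for e in self.edges for n in e}
        return {e[1] for e in self.edges}


def layer_from_pairs(source_kind: NodeKind, target_kind: NodeKind,
                     pairs: Iterable[tuple[str, str]]) -> EdgeLayer:
    """Build a canonicalized, deduplicated layer from (normalized) id pairs."""
    canon = {_canonical(source_kind, target_kind, s, t)
             for s, t in pairs
             if not (source_kind == target_kind and s == t)}
    return EdgeLayer(source_kind, target_kind, frozenset(canon))


def read_edge_list(path: str | Path, source_kind: NodeKind,
                   target_kind: NodeKind) -> EdgeLayer:
    """Parse a tab-separated edge list into a deduplicated :class:`EdgeLayer`.

    Column 1 is the source identifier, column 2 the target; extra columns
    are ignored.  Lines starting with ``#`` are comments.  Duplicate lines
    (including reversed PPI duplicates) collapse silently; dropped duplicate
    and self-loop counts are logged.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge list not found: {path}")
    edges: set[tuple[str, str]] = set()
    n_dupes = 0
    n_self = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated fields, "
                    f"got {len(fields)}")
            src = normalize_id(fields[0])
            tgt = normalize_id(fields[1])
            if not src or not tgt:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            if source_kind == target_kind and src == tgt:
                n_self += 1
                continue
            edge = _canonical(source_kind, target_kind, src, tgt)
            if edge in edges:
                n_dupes += 1
            else:
                edges.add(edge)
    if n_dupes or n_self:
        logger.info("%s: dropped %d duplicate and %d self-loop lines",
                    path, n_dupes, n_self)
    return EdgeLayer(source_kind, target_kind, frozenset(edges))


def write_edge_list(layer: EdgeLayer, path: str | Path) -> None:
    """Write a layer back to the TSV dialect :func:`read_edge_list` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {layer.source_kind.value}\t{layer.target_kind.value}\n")
        for src, tgt in sorted(layer.edges):
            fh.write(f"{src}\t{tgt}\n")


@dataclass(frozen=True)
class TripartiteNetwork:
    """Three node classes joined by three edge layers.

    The node set is the union of all layer endpoints; the same identifier
    string may exist under different kinds without collision.
    """

    nodes: frozenset[Node]
    lnc_protein: EdgeLayer
    ppi: EdgeLayer
    disease_protein: EdgeLayer

    @property
    def lncrnas(self) -> set[str]:
        return {n.identifier for n in self.nodes if n.kind is NodeKind.LNCRNA}

    @property
    def proteins(self) -> set[str]:
        return {n.identifier for n in self.nodes if n.kind is NodeKind.PROTEIN}

    @property
    def diseases(self) -> set[str]:
        return {n.identifier for n in self.nodes if n.kind is NodeKind.DISEASE}

    def disease_genes(self, disease_id: str) -> set[str]:
        """Proteins associated with ``disease_id`` in the disease layer."""
        return {p for d, p in self.disease_protein.edges if d == disease_id}


def build_tripartite(lnc_protein: EdgeLayer, ppi: EdgeLayer,
                     disease_protein: EdgeLayer) -> TripartiteNetwork:
    """Assemble the three layers into a :class:`TripartiteNetwork`.

    Emits warnings (never errors) for empty layers and for identifiers that
    appear both as a protein and as a lncRNA.
    """
    expected = {
        "lnc_protein": (lnc_protein, NodeKind.LNCRNA, NodeKind.PROTEIN),
        "ppi": (ppi, NodeKind.PROTEIN, NodeKind.PROTEIN),
        "disease_protein": (disease_protein, NodeKind.DISEASE, NodeKind.PROTEIN),
    }
    for name, (layer, skind, tkind) in expected.items():
        if (layer.source_kind, layer.target_kind) != (skind, tkind):
            raise InputError(
                f"layer {name} declares kinds "
                f"({layer.source_kind.value}, {layer.target_kind.value}), "
                f"expected ({skind.value}, {tkind.value})")
        if layer.n_edges == 0:
            logger.warning("layer %s is empty", name)

    nodes: set[Node] = set()
    for lnc, prot in lnc_protein.edges:
        nodes.add(Node(NodeKind.LNCRNA, lnc))
        nodes.add(Node(NodeKind.PROTEIN, prot))
    for a, b in ppi.edges:
        nodes.add(Node(NodeKind.PROTEIN, a))
        nodes.add(Node(NodeKind.PROTEIN, b))
    for dis, prot in disease_protein.edges:
        nodes.add(Node(NodeKind.DISEASE, dis))
        nodes.add(Node(NodeKind.PROTEIN, prot))

    net = TripartiteNetwork(frozenset(nodes), lnc_protein, ppi, disease_protein)
    overlap = net.proteins & net.lncrnas
    if overlap:
        logger.warning(
            "%d identifiers appear as both PROTEIN and LNCRNA (kept as "
            "distinct nodes): %s", len(overlap),
            ", ".join(sorted(overlap)[:5]))
    return net


@dataclass(frozen=True)
class NetworkSummary:
    n_lncrnas: int
    n_proteins: int
    n_diseases: int
    n_lnc_protein_edges: int
    n_ppi_edges: int
    n_disease_protein_edges: int
    degree_summary: dict  # kind value -> (min, median, max) total degree

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, count in (("LNCRNA", self.n_lncrnas),
                            ("PROTEIN", self.n_proteins),
                            ("DISEASE", self.n_diseases)):
            dmin, dmed, dmax = self.degree_summary.get(kind, (0, 0, 0))
            rows.append({"kind": kind, "n_nodes": count,
                         "degree_min": dmin, "degree_median": dmed,
                         "degree_max": dmax})
        frame = pd.DataFrame(rows)
        frame.attrs["edges"] = {
            "lnc_protein": self.n_lnc_protein_edges,
            "ppi": self.n_ppi_edges,
            "disease_protein": self.n_disease_protein_edges,
        }
        return frame


def summarize(net: TripartiteNetwork) -> NetworkSummary:
    """Node counts per kind, edge counts per layer and degree summaries."""
    degrees: dict[Node, int] = {n: 0 for n in net.nodes}

    def bump(kind: NodeKind, ident: str) -> None:
        degrees[Node(kind, ident)] += 1

    for lnc, prot in net.lnc_protein.edges:
        bump(NodeKind.LNCRNA, lnc)
        bump(NodeKind.PROTEIN, prot)
    for a, b in net.ppi.edges:
        bump(NodeKind.PROTEIN, a)
        bump(NodeKind.PROTEIN, b)
    for dis, prot in net.disease_protein.edges:
        bump(NodeKind.DISEASE, dis)
        bump(NodeKind.PROTEIN, prot)

    degree_summary = {}
    for kind in NodeKind:
        vals = [d for n, d in degrees.items() if n.kind is kind]
        if vals:
            degree_summary[kind.value] = (min(vals), median(vals), max(vals))
        else:
            degree_summary[kind.value] = (0, 0, 0)

    return NetworkSummary(
        n_lncrnas=len(net.lncrnas),
        n_proteins=len(net.proteins),
        n_diseases=len(net.diseases),
        n_lnc_protein_edges=net.lnc_protein.n_edges,
        n_ppi_edges=net.ppi.n_edges,
        n_disease_protein_edges=net.disease_protein.n_edges,
        degree_summary=degree_summary,
    )
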