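"""Per-disease walk-graph extraction and eligibility checks.

Network propagation is run locally: for each disease, the walk graph is
built from the disease's seed genes, their nearest PPI neighbors, and the
lncRNAs attached to any of those proteins.  This restricts the ranking to
the disease's network neighborhood, following the local-impact hypothesis
that molecules involved in the same disease concentrate in a common region
of the interactome.

The disease node itself is not part of the walk graph — the disease enters
only through the seed set that the walker restarts on.

Two rules decide which PPI edges enter the walk graph:

``induced``
    every PPI edge with both endpoints in the member protein set
    (seed–seed, seed–neighbor and neighbor–neighbor edges); default,
    because it preserves the local topology the walker can exploit.
``star``
    only PPI edges incident to at least one seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .exceptions import ExtractionError, LookupError_
from .net_io import NodeKind, TripartiteNetwork

logger = logging.getLogger(__name__)

__all__ = ["DiseaseSubnetwork", "EligibilityReport",
           "extract_subnetwork", "check_eligibility"]

EDGE_RULES = ("induced", "star")


@dataclass(frozen=True)
class DiseaseSubnetwork:
    """The walk graph for one disease.

    ``node_order`` is the fixed total ordering (lexicographic by
    (kind, identifier), so lncRNAs sort before proteins) that the diffusion
    matrices and vectors are indexed by.
    """

    disease_id: str
    seeds: frozenset[str]
    proteins: frozenset[str]
    lncrnas: frozenset[str]
    walk_edges: frozenset[tuple[str, str]]
    node_order: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_edges(self) -> int:
        return len(self.walk_edges)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_order)}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_order)
        g.add_edges_from(self.walk_edges)
        return g


@dataclass(frozen=True)
class EligibilityReport:
    disease_id: str
    eligible: bool
    connected: bool
    bipartite: bool
    n_nodes: int
    n_edges: int
    reason: str


def extract_subnetwork(net: TripartiteNetwork, disease_id: str,
                       edge_rule: str = "induced") -> DiseaseSubnetwork:
    """Extract the walk graph for ``disease_id``.

    Seeds are the disease's genes that appear in the PPI layer; seed genes
    absent from the PPI are dropped with a warning.  Member proteins are
    the seeds plus their first PPI neighbors; lncRNAs are those with at
    least one attachment to a member protein.

    Raises
    ------
    LookupError_
        if the disease is not in the disease-protein layer.
    ExtractionError
        if no seed gene is present in the PPI layer.
    """
    if edge_rule not in EDGE_RULES:
        raise ValueError(f"edge_rule must be one of {EDGE_RULES}")
    if disease_id not in {d for d, _ in net.disease_protein.edges}:
        raise LookupError_(f"unknown disease: {disease_id}")

    genes = net.disease_genes(disease_id)

    adjacency: dict[str, set[str]] = {}
    for a, b in net.ppi.edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    seeds = {g for g in genes if g in adjacency}
    dropped = genes - seeds
    if dropped:
        logger.warning("%s: %d seed gene(s) absent from the PPI dropped: %s",
                       disease_id, len(dropped), ", ".join(sorted(dropped)[:5]))
    if not seeds:
        raise ExtractionError(
            f"{disease_id}: none of its {len(genes)} disease genes are in "
            f"the PPI layer")

    proteins = set(seeds)
    for s in seeds:
        proteins |= adjacency[s]

    if edge_rule == "induced":
        ppi_walk = {(a, b) for a, b in net.ppi.edges
                    if a in proteins and b in proteins}
    else:  # star
        ppi_walk = {(a, b) for a, b in net.ppi.edges
                    if a in seeds or b in seeds}

    lnc_walk = {(l, p) for l, p in net.lnc_protein.edges if p in proteins}
    lncrnas = {l for l, _ in lnc_walk}

    collision = lncrnas & proteins
    if collision:
        # identifier shared between a member protein and a lncRNA would be
        # ambiguous in the walk graph; the lncRNA copy is dropped
        logger.warning("%s: dropping %d lncRNA id(s) colliding with member "
                       "proteins: %s", disease_id, len(collision),
                       ", ".join(sorted(collision)[:5]))
        lncrnas -= collision
        lnc_walk = {(l, p) for l, p in lnc_walk if l in lncrnas}

    order = tuple(sorted(lncrnas) + sorted(proteins))
    return DiseaseSubnetwork(
        disease_id=disease_id,
        seeds=frozenset(seeds),
        proteins=frozenset(proteins),
        lncrnas=frozenset(lncrnas),
        walk_edges=frozenset(ppi_walk | lnc_walk),
        node_order=order,
    )


def check_eligibility(sub: DiseaseSubnetwork) -> EligibilityReport:
    """Decide whether a subnetwork supports the diffusion.

    Eligible iff the walk graph is connected, non-bipartite (contains an
    odd cycle) and the seed set is non-empty.  This mirrors the classical
    condition for a plain random walk to have a unique limiting
    distribution; with restart the iteration converges on any graph, but
    the filter is applied as stated.
    """
    g = sub.to_graph()
    if g.number_of_nodes() == 0:
        connected = False
        bipartite = True
    else:
        connected = nx.is_connected(g)
        bipartite = nx.is_bipartite(g)
    eligible = connected and not bipartite and len(sub.seeds) > 0
    if not sub.seeds:
        reason = "no_seeds"
    elif not connected:
        reason = "disconnected"
    elif bipartite:
        reason = "bipartite"
    else:
        reason = "eligible"
    return EligibilityReport(
        disease_id=sub.disease_id,
        eligible=eligible,
        connected=connected,
        bipartite=bipartite,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        reason=reason,
    )
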