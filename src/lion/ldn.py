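"""Assemble the weighted bipartite lncRNA-disease network (LDN).

One diffusion per eligible disease; every ranked lncRNA contributes one
weighted edge (disease, lncRNA, steady-state probability, per-disease rank).
Ineligible diseases are skipped and recorded in a machine-readable skip
report with one of the reasons: no_seeds, disconnected, bipartite,
not_converged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .diffusion import (DiffusionParams, column_normalize, diffuse,
                        rank_lncrnas, uniform_restart)
from .exceptions import ConvergenceError, ExtractionError, ParseError
from .net_io import TripartiteNetwork
from .subnet import check_eligibility, extract_subnetwork

logger = logging.getLogger(__name__)

__all__ = ["LdnEdge", "LncRNADiseaseNetwork", "LdnSummary",
           "predict_all", "ldn_summary", "write_ldn", "read_ldn"]

LDN_HEADER = ("disease_id", "lncrna_id", "weight", "rank")


class LdnEdge(NamedTuple):
    disease_id: str
    lncrna_id: str
    weight: float
    rank: int


@dataclass(frozen=True)
class LncRNADiseaseNetwork:
    """Weighted bipartite predictions, at most one edge per (disease, lncRNA)."""

    edges: tuple[LdnEdge, ...]
    skip_report: tuple[tuple[str, str], ...] = field(default=())

    @property
    def diseases(self) -> set[str]:
        return {e.disease_id for e in self.edges}

    @property
    def lncrnas(self) -> set[str]:
        return {e.lncrna_id for e in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=LDN_HEADER)


@dataclass(frozen=True)
class LdnSummary:
    n_edges: int
    n_diseases: int
    n_lncrnas: int
    median_lncrnas_per_disease: float
    median_diseases_per_lncrna: float


def predict_all(net: TripartiteNetwork,
                params: DiffusionParams | None = None,
                edge_rule: str = "induced") -> LncRNADiseaseNetwork:
    """Run the full pipeline for every disease in the disease-protein layer.

    Diseases are processed in lexicographic order and independently (each
    subnetwork is recomputed from scratch), so the result is deterministic
    given the inputs and parameters.  Per-disease failures are skips, never
    fatal.
    """
    if params is None:
        params = DiffusionParams()
    diseases = sorted({d for d, _ in net.disease_protein.edges})
    if not diseases:
        logger.warning("disease-protein layer is empty; LDN will be empty")

    edges: list[LdnEdge] = []
    skips: list[tuple[str, str]] = []
    for disease in diseases:
        try:
            sub = extract_subnetwork(net, disease, edge_rule=edge_rule)
        except ExtractionError:
            skips.append((disease, "no_seeds"))
            continue
        report = check_eligibility(sub)
        if not report.eligible:
            skips.append((disease, report.reason))
            continue
        W = column_normalize(sub.walk_edges, sub.node_order)
        p0 = uniform_restart(sub.seeds, sub.node_order)
        try:
            scores = diffuse(W, p0, params)
        except ConvergenceError:
            skips.append((disease, "not_converged"))
            continue
        for lnc, score, rank in rank_lncrnas(scores, sub):
            edges.append(LdnEdge(disease, lnc, score, rank))
    if skips:
        logger.info("skipped %d/%d diseases: %s", len(skips), len(diseases),
                    {r: sum(1 for _, x in skips if x == r)
                     for r in {x for _, x in skips}})
    return LncRNADiseaseNetwork(edges=tuple(edges), skip_report=tuple(skips))


def ldn_summary(ldn: LncRNADiseaseNetwork) -> LdnSummary:
    """Counts plus median lncRNAs/disease and diseases/lncRNA.

    Medians of even-sized multisets are the mean of the two central values
    (numpy convention); an empty LDN yields NaN medians.
    """
    per_disease: dict[str, int] = {}
    per_lncrna: dict[str, int] = {}
    for e in ldn.edges:
        per_disease[e.disease_id] = per_disease.get(e.disease_id, 0) + 1
        per_lncrna[e.lncrna_id] = per_lncrna.get(e.lncrna_id, 0) + 1
    med_d = float(np.median(list(per_disease.values()))) if per_disease else float("nan")
    med_l = float(np.median(list(per_lncrna.values()))) if per_lncrna else float("nan")
    return LdnSummary(
        n_edges=ldn.n_edges,
        n_diseases=len(per_disease),
        n_lncrnas=len(per_lncrna),
        median_lncrnas_per_disease=med_d,
        median_diseases_per_lncrna=med_l,
    )


def write_ldn(ldn: LncRNADiseaseNetwork, path: str | Path) -> None:
    """4-column TSV with header; weights as shortest round-trip decimals."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(LDN_HEADER) + "\n")
        for e in ldn.edges:
            fh.write(f"{e.disease_id}\t{e.lncrna_id}\t{e.weight!r}\t{e.rank}\n")


def read_ldn(path: str | Path) -> LncRNADiseaseNetwork:
    """Inverse of :func:`write_ldn`; weights round-trip bit-identically."""
    path = Path(path)
    edges: list[LdnEdge] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LDN_HEADER:
            raise ParseError(f"{path}:1: expected header {LDN_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                edges.append(LdnEdge(fields[0], fields[1],
                                     float(fields[2]), int(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return LncRNADiseaseNetwork(edges=tuple(edges))
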