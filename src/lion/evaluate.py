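"""ROC/AUC validation of LDN predictions and the shuffled-label null model.

Predicted edge weights are used as the ROC thresholds, so the evaluation
sweeps the whole predicted edge set: positives are predicted edges present
in the ground-truth association set, negatives are all remaining predicted
edges.  The negative control permutes node labels within each class
(lncRNA labels among lncRNA nodes, disease labels among disease nodes) of
the bipartite network, preserving the unlabeled connectivity structure;
on a correctly shuffled network the AUC drops to about 0.5.  Differences
between weight distributions are tested with the two-sided
Wilcoxon/Mann-Whitney rank-sum test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .exceptions import EvaluationError, InputError, ParseError
from .ldn import LdnEdge, LncRNADiseaseNetwork
from .net_io import normalize_id

logger = logging.getLogger(__name__)

__all__ = ["GroundTruth", "RocResult", "RankSumResult",
           "read_ground_truth", "read_disease_groups",
           "label_edges", "roc_auc", "macro_average_auc",
           "shuffle_labels", "rank_sum"]

# exact rank-sum enumeration is used while C(n1+n2, n1) stays below this
_MAX_EXACT_COMBINATIONS = 20_000


@dataclass(frozen=True)
class GroundTruth:
    """Experimentally validated (disease, lncRNA) pairs, plus optional
    disease -> group labels (e.g. cancer, cardiovascular)."""

    pairs: frozenset[tuple[str, str]]
    disease_groups: dict | None = None


@dataclass(frozen=True)
class RocResult:
    thresholds: tuple[float, ...]
    points: tuple[tuple[float, float], ...]  # (fpr, tpr)
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Two-column TSV (disease_id, lncrna_id); '#' comments; deduplicated."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"ground-truth file not found: {path}")
    pairs: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 fields")
            d, l = normalize_id(fields[0]), normalize_id(fields[1])
            if not d or not l:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            pairs.add((d, l))
    return GroundTruth(pairs=frozenset(pairs))


def read_disease_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping disease_id -> group label."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"group file not found: {path}")
    groups: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 fields")
            groups[normalize_id(fields[0])] = fields[1].strip()
    return groups


def label_edges(ldn: LncRNADiseaseNetwork, truth: GroundTruth,
                group: str | None = None) -> list[tuple[float, int]]:
    """Score/label pairs for the ROC: label 1 iff the edge is a known
    association.

    With ``group`` given, only edges of diseases carrying that group label
    are kept (diseases with zero truth pairs still contribute negatives).
    Truth pairs with no predicted edge are logged as unscored positives.
    """
    if group is not None:
        groups = truth.disease_groups or {}
        member = {d for d, g in groups.items() if g == group}
        edges = [e for e in ldn.edges if e.disease_id in member]
    else:
        edges = list(ldn.edges)
    labeled = [(e.weight, 1 if (e.disease_id, e.lncrna_id) in truth.pairs else 0)
               for e in edges]
    n_pos = sum(lab for _, lab in labeled)
    n_neg = len(labeled) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"AUC undefined: {n_pos} positives and {n_neg} negatives "
            f"after restriction" + (f" to group {group!r}" if group else ""))
    scored = {(e.disease_id, e.lncrna_id) for e in edges}
    relevant = truth.pairs if group is None else {
        (d, l) for d, l in truth.pairs if d in member}
    unscored = relevant - scored
    if unscored:
        logger.info("%d ground-truth pair(s) have no predicted edge "
                    "(unscored positives)", len(unscored))
    return labeled


def roc_auc(labeled: list[tuple[float, int]]) -> RocResult:
    """ROC by threshold sweep over the distinct scores, AUC by trapezoid.

    With every operating point kept, the trapezoidal area equals the
    tie-corrected rank statistic (concordant + half-tied over
    n_pos * n_neg).
    """
    scores = np.array([s for s, _ in labeled], dtype=float)
    labels = np.array([l for _, l in labeled], dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives")
    fpr, tpr, thresholds = _roc_curve(labels, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    # first threshold is the +inf sentinel for the (0, 0) point
    return RocResult(
        thresholds=tuple(float(t) for t in thresholds[1:]),
        points=tuple((float(f), float(t)) for f, t in zip(fpr, tpr)),
        auc=area,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def macro_average_auc(ldn: LncRNADiseaseNetwork, truth: GroundTruth,
                      group: str | None = None) -> tuple[float, int]:
    """Mean of per-disease AUCs over diseases with both classes.

    Alternative to pooling all edges of a group into one ROC; returns the
    macro-averaged AUC and the number of diseases it averages over.
    """
    if group is not None:
        groups = truth.disease_groups or {}
        member = {d for d, g in groups.items() if g == group}
        diseases = sorted(ldn.diseases & member)
    else:
        diseases = sorted(ldn.diseases)
    aucs = []
    for d in diseases:
        labeled = [(e.weight, 1 if (e.disease_id, e.lncrna_id) in truth.pairs else 0)
                   for e in ldn.edges if e.disease_id == d]
        pos = sum(lab for _, lab in labeled)
        if pos == 0 or pos == len(labeled):
            continue
        aucs.append(roc_auc(labeled).auc)
    if not aucs:
        raise EvaluationError("no disease has both positive and negative edges")
    return float(np.mean(aucs)), len(aucs)


def shuffle_labels(ldn: LncRNADiseaseNetwork,
                   rng_seed: int) -> LncRNADiseaseNetwork:
    """Node-label-shuffled null model of the bipartite network.

    One uniform permutation of the lncRNA labels and one of the disease
    labels, applied globally, so degree sequences and the weight multiset
    attached to graph positions are unchanged.  Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(rng_seed)
    lnc_labels = sorted(ldn.lncrnas)
    dis_labels = sorted(ldn.diseases)
    lnc_map = dict(zip(lnc_labels, (lnc_labels[i] for i in
                                    rng.permutation(len(lnc_labels)))))
    dis_map = dict(zip(dis_labels, (dis_labels[i] for i in
                                    rng.permutation(len(dis_labels)))))
    edges = tuple(LdnEdge(dis_map[e.disease_id], lnc_map[e.lncrna_id],
                          e.weight, e.rank)
                  for e in ldn.edges)
    return LncRNADiseaseNetwork(edges=edges)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a: #(x > y) + 0.5 * #(x == y)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum(a, b) -> RankSumResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Small samples (both <= 20) are tested exactly: the classical exact
    distribution when there are no ties, full enumeration of the
    C(n1+n2, n1) group assignments when there are.  Larger samples use the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("rank-sum test requires two non-empty samples")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = n1 <= 20 and n2 <= 20

    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return RankSumResult(float(res.statistic), float(res.pvalue), "exact")

    if small and comb(n1 + n2, n1) <= _MAX_EXACT_COMBINATIONS:
        u_obs = _u_statistic(a, b)
        total = comb(n1 + n2, n1)
        le = ge = 0
        idx = np.arange(n1 + n2)
        for chosen in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u <= u_obs:
                le += 1
            if u >= u_obs:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return RankSumResult(u_obs, p, "exact")

    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         "normal-approximation")
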