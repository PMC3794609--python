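"""Benchmarking tissue rankings against a gold standard.

Rankings are turned into binary classifiers by thresholding the rank:
every (association, category) pair contributes a label (is the category a
gold positive for that association?) and a score (minus the category's
predicted rank).  Sweeping the threshold over all ranks yields a ROC
curve whose trapezoidal area, with midpoint tie handling, equals the
Mann-Whitney statistic: the probability that a random positive outranks a
random negative.

Two controls accompany the main evaluation: a single-protein baseline
that ranks tissues by the Welch t statistic of the hub's own expression
(tissue vs all other tissues pooled), and a randomization null that
shuffles each tissue's gene-to-expression-row assignment and re-runs the
whole pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .coordination import TissueRanking, coordination_matrix, rank_tissues
from .expression import ExpressionCompendium, TissueCategoryMap
from .network import ProteinComplex

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "RocResult",
    "read_gold_standard",
    "categorize_ranking",
    "roc_from_rankings",
    "per_tissue_auc",
    "per_complex_auc",
    "topk_overlap",
    "single_protein_ranking",
    "randomized_null",
]


@dataclass(frozen=True)
class GoldStandard:
    """(gene, disease) -> ordered positive tissue categories.

    A gene may recur under different diseases with different positives;
    the (gene, disease) pair itself is unique.  List order matters only
    for top-k overlap; ROC labels treat all listed categories as positive.
    """

    associations: tuple[tuple[str, str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        keys = [(g, d) for g, d, _ in self.associations]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (gene, disease) association")
        for g, d, cats in self.associations:
            if not cats:
                raise ValueError(f"association ({g!r}, {d!r}) has no positive category")

    def __iter__(self):
        return iter(self.associations)

    def __len__(self) -> int:
        return len(self.associations)


@dataclass(frozen=True)
class RocResult:
    """ROC points (FPR, TPR) from (0,0) to (1,1) plus trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float
    n_pos: int
    n_neg: int


def read_gold_standard(path) -> GoldStandard:
    """Read a TSV with columns gene, disease, tissue_categories.

    ``tissue_categories`` is a semicolon-separated list in gold rank
    order.  Duplicate (gene, disease) rows and empty category lists are
    errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "disease", "tissue_categories"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    assocs = []
    for _, row in df.iterrows():
        raw = row["tissue_categories"]
        cats = tuple(c.strip() for c in str(raw).split(";") if c.strip()) if pd.notna(raw) else ()
        if not cats:
            raise ValueError(
                f"{path}: empty tissue category list for ({row['gene']!r}, {row['disease']!r})"
            )
        assocs.append((row["gene"], row["disease"], cats))
    return GoldStandard(tuple(assocs))


def categorize_ranking(r: TissueRanking, cmap: TissueCategoryMap) -> TissueRanking:
    """Collapse a tissue ranking to a category ranking.

    A category scores the maximum over its member tissues (it is hit as
    soon as any member tissue is), then categories are re-ranked
    descending with the same deterministic tie rule.
    """
    best: dict[str, float] = {}
    for tissue, score in r.entries:
        cat = cmap[tissue]  # raises KeyError naming the tissue if unmapped
        if cat not in best or _better(score, best[cat]):
            best[cat] = score
    order = sorted(
        best.items(),
        key=lambda kv: (math.isnan(kv[1]), -kv[1] if not math.isnan(kv[1]) else 0.0, kv[0]),
    )
    return TissueRanking(r.complex_id, tuple(order))


def _better(a: float, b: float) -> bool:
    """Is score a better than b, treating NaN as worst?"""
    if math.isnan(a):
        return False
    if math.isnan(b):
        return True
    return a > b


def _pool_pairs(rankings, gs: GoldStandard):
    """Pooled (score, label, category) triples over all associations."""
    triples = []
    n_skipped = 0
    for gene, disease, positives in gs:
        ranking = rankings.get((gene, disease))
        if ranking is None:
            n_skipped += 1
            continue
        pos = set(positives)
        for rank, (cat, _) in enumerate(ranking.entries, start=1):
            triples.append((-float(rank), cat in pos, cat))
    if n_skipped:
        logger.info("skipped %d gold association(s) without a ranking", n_skipped)
    return triples


def _roc_result(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(
        points=tuple(zip(fpr.tolist(), tpr.tolist())),
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc_from_rankings(rankings, gs: GoldStandard) -> RocResult:
    """Pooled rank-threshold ROC over all (association, category) pairs.

    ``rankings`` maps (gene, disease) -> category-level TissueRanking.
    The score of a pair is minus the category's rank; the trapezoidal AUC
    with tied ranks grouped equals the Mann-Whitney statistic.
    """
    triples = _pool_pairs(rankings, gs)
    scores = np.array([s for s, _, _ in triples])
    labels = np.array([l for _, l, _ in triples])
    return _roc_result(scores, labels)


def per_tissue_auc(rankings, gs: GoldStandard, category: str) -> RocResult:
    """ROC restricted to one category's (association, category) pairs."""
    triples = [t for t in _pool_pairs(rankings, gs) if t[2] == category]
    scores = np.array([s for s, _, _ in triples])
    labels = np.array([l for _, l, _ in triples])
    try:
        return _roc_result(scores, labels)
    except ValueError:
        raise ValueError(
            f"category {category!r} is never positive or never negative in the gold standard"
        ) from None


def per_complex_auc(ranking: TissueRanking, positives: set[str]) -> float:
    """Mann-Whitney AUC of positive vs negative categories in one ranking."""
    cats = ranking.tissues
    labels = np.array([c in positives for c in cats])
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(cats):
        raise ValueError("positives must be a proper non-empty subset of the categories")
    scores = -np.arange(1, len(cats) + 1, dtype=float)
    return _roc_result(scores, labels).auc


def topk_overlap(pred: TissueRanking, gold_positives, k: int = 3) -> int:
    """Size of the intersection of the top-k predicted and top-k gold categories."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return len(set(pred.top(k)) & set(list(gold_positives)[:k]))


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t statistic; NaN when both groups are constant."""
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    denom = math.sqrt(va / na + vb / nb)
    if denom == 0.0:
        return float("nan") if diff == 0.0 else math.copysign(math.inf, diff)
    return float(diff / denom)


def single_protein_ranking(gene: str, c: ExpressionCompendium) -> TissueRanking:
    """Baseline ranking from the gene's own expression only.

    Each tissue is scored by the Welch t statistic of that tissue's
    expression values against all other tissues' values pooled, and
    tissues are ranked by decreasing t.  Tissues where both groups are
    constant get a missing score and rank last.
    """
    if gene not in c.values.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    row = c.values.loc[gene]
    tissues = c.tissues
    scores = {}
    for t in tissues:
        in_t = row[c.samples_of_tissue(t)].to_numpy()
        rest = row[[s for s in c.samples if c.tissue_of[s] != t]].to_numpy()
        if in_t.size < 2 or rest.size < 2:
            raise ValueError(f"tissue {t!r} or its complement has fewer than 2 samples")
        scores[t] = _welch_t(in_t, rest)
    order = sorted(
        scores.items(),
        key=lambda kv: (math.isnan(kv[1]), -kv[1] if not math.isnan(kv[1]) else 0.0, kv[0]),
    )
    return TissueRanking(gene, tuple(order))


def shuffle_within_tissues(c: ExpressionCompendium, rng: np.random.Generator) -> ExpressionCompendium:
    """Permute, independently per tissue, which gene owns which value row.

    The shuffle unit is a gene's whole within-tissue row: sample-level
    structure inside the tissue is preserved while gene identity (and so
    any real co-expression) is destroyed.
    """
    values = c.values.to_numpy().copy()
    cols = {s: i for i, s in enumerate(c.samples)}
    for t in c.tissues:
        idx = [cols[s] for s in c.samples_of_tissue(t)]
        perm = rng.permutation(values.shape[0])
        values[:, idx] = values[np.ix_(perm, idx)]
    shuffled = pd.DataFrame(values, index=c.values.index, columns=c.values.columns)
    return ExpressionCompendium(shuffled, dict(c.tissue_of), dict(c.condition_of))


def randomized_null(
    c: ExpressionCompendium,
    cxs: list[ProteinComplex],
    gs: GoldStandard,
    cmap: TissueCategoryMap,
    reps: int = 100,
    seed: int = 0,
    mode: str = "analytic",
) -> list[float]:
    """Chance-level AUC distribution from within-tissue expression shuffles.

    Per replicate the gene-to-row assignment is permuted independently in
    each tissue, the coordination matrix and category rankings are
    recomputed, and the overall pooled AUC against the gold standard is
    recorded.  Child seeds are spawned deterministically from ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    aucs = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        shuffled = shuffle_within_tissues(c, rng)
        m = coordination_matrix(cxs, shuffled, mode=mode)
        rankings = {}
        for gene, disease, _ in gs:
            if gene in m.raw.index:
                rankings[(gene, disease)] = categorize_ranking(rank_tissues(m, gene), cmap)
        aucs.append(roc_from_rankings(rankings, gs).auc)
    return aucs
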