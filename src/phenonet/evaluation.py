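"""Independent evaluation statistics: GO- and expression-based phenotype
similarity references, and the binned correlation methodology.

A network-based phenotype similarity is judged by how well it tracks two
independent references computed from the phenotypes' gene sets:

* GO functional similarity — Sim_pro(g_i, g_j) = 2/n_t, where n_t is the
  annotation count of the most specific GO term shared by the two genes
  (after up-propagation), averaged over the G_1 × G_2 cross product;
* co-expression similarity — the mean absolute Spearman correlation of
  expression profiles over the cross product.

Method scores and reference scores are then compared after sorting the pairs
by method score and summarising equal-count bins: the Pearson correlation and
the R² of the least-squares line through (bin mean method score, bin
median/mean reference score).
"""
from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix
from .ontology import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationRecord:
    """One phenotype pair: the method's score and an independent reference score."""

    term_a: str
    term_b: str
    method_score: float
    reference_score: float


class GoGeneSimilarity:
    """Pairwise gene functional similarity 2/n_t from a propagated GO table.

    Precomputes gene → annotated-term and term → annotation-count indices, so
    per-pair lookups are set intersections.
    """

    def __init__(self, table: AnnotationTable) -> None:
        if not table.propagated:
            raise ValueError("GO similarity requires a propagated annotation table")
        self._term_size = {t: len(gs) for t, gs in table.term_to_genes.items()}
        gene_terms: dict[str, set[str]] = defaultdict(set)
        for t, gs in table.term_to_genes.items():
            for g in gs:
                gene_terms[g].add(t)
        self._gene_terms = {g: frozenset(ts) for g, ts in gene_terms.items()}

    def __call__(self, g_i: str, g_j: str) -> float:
        shared = self._gene_terms.get(g_i, frozenset()) & self._gene_terms.get(
            g_j, frozenset()
        )
        if not shared:
            return 0.0
        n_t = min(self._term_size[t] for t in shared)
        # n_t == 1 only for an identical-gene pair under a singleton term;
        # the score is capped so references stay in [0, 1]
        return min(1.0, 2.0 / n_t)


def go_pair_similarity(g_i: str, g_j: str, go_table: AnnotationTable) -> float:
    """Sim_pro(g_i, g_j) = 2/n_t for the most specific shared GO term; 0 if none."""
    return GoGeneSimilarity(go_table)(g_i, g_j)


def go_phenotype_similarity(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    go_table: AnnotationTable,
    _sim: GoGeneSimilarity | None = None,
) -> float:
    """Mean of Sim_pro over the full G_1 × G_2 cross product (identical genes included)."""
    genes_a = sorted(set(genes_a))
    genes_b = sorted(set(genes_b))
    if not genes_a or not genes_b:
        raise ValueError("both gene sets must be nonempty")
    sim = GoGeneSimilarity(go_table) if _sim is None else _sim
    total = 0.0
    for gi in genes_a:
        for gj in genes_b:
            total += sim(gi, gj)
    return total / (len(genes_a) * len(genes_b))


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks (ties share their mean rank)."""
    return stats.rankdata(values, axis=1)


def expression_phenotype_similarity(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    expr: ExpressionMatrix,
) -> float:
    """Mean |Spearman rho| of expression profiles over the G_1 × G_2 cross product.

    Genes absent from the matrix are dropped (counts logged).  Pairs with an
    undefined correlation (a constant profile) contribute 0, except
    identical-gene pairs, which contribute 1.
    """
    if expr.n_conditions < 3:
        raise ValueError("expression similarity needs >= 3 conditions")
    genes_a = sorted(set(genes_a))
    genes_b = sorted(set(genes_b))
    present_a = [g for g in genes_a if g in expr]
    present_b = [g for g in genes_b if g in expr]
    n_dropped = (len(genes_a) - len(present_a)) + (len(genes_b) - len(present_b))
    if n_dropped:
        logger.debug(
            "expression_phenotype_similarity: %d genes without expression dropped",
            n_dropped,
        )
    if not present_a or not present_b:
        raise ValueError("no overlap between gene sets and expression matrix")

    ra = _rank_rows(np.array([expr.row(g) for g in present_a]))
    rb = _rank_rows(np.array([expr.row(g) for g in present_b]))

    def _normalise(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centred = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((centred**2).sum(axis=1))
        ok = norm > 0
        centred[ok] /= norm[ok, None]
        return centred, ok

    na, ok_a = _normalise(ra)
    nb, ok_b = _normalise(rb)
    rho = na @ nb.T  # Pearson of ranks == Spearman with average ranks
    abs_rho = np.abs(rho)
    # undefined correlations (constant profile): 0, but identical genes count 1
    abs_rho[~ok_a, :] = 0.0
    abs_rho[:, ~ok_b] = 0.0
    for ia, g in enumerate(present_a):
        if g in present_b:
            abs_rho[ia, present_b.index(g)] = 1.0
    return float(abs_rho.mean())


def binned_correlation(
    records: Sequence[EvaluationRecord], n_bins: int = 10
) -> dict[str, float]:
    """Binned correlation between method scores and reference scores.

    Pairs are sorted by method score and split into ``n_bins`` equal-count
    bins; per bin the mean method score and the median and mean reference
    score are taken.  Returned keys: ``pcc_median``, ``pcc_mean`` (Pearson
    correlation of the binned points) and ``r2_median``, ``r2_mean`` (R² of
    the least-squares line through the same points).  ``n_bins=0`` skips
    binning and correlates the raw pairs.
    """
    m = np.array([r.method_score for r in records], dtype=float)
    ref = np.array([r.reference_score for r in records], dtype=float)
    finite = np.isfinite(m) & np.isfinite(ref)
    m, ref = m[finite], ref[finite]

    def _pcc_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("degenerate (constant) scores: correlation reported as 0")
            return 0.0, 0.0
        res = stats.linregress(x, y)
        return float(res.rvalue), float(res.rvalue**2)

    if n_bins == 0:
        pcc, r2 = _pcc_r2(m, ref)
        return {"pcc_median": pcc, "pcc_mean": pcc, "r2_median": r2, "r2_mean": r2}

    if len(m) < n_bins:
        raise ValueError(f"{len(m)} records cannot fill {n_bins} bins")
    order = np.argsort(m, kind="stable")
    bin_method, bin_median, bin_mean = [], [], []
    for idx in np.array_split(order, n_bins):
        bin_method.append(m[idx].mean())
        bin_median.append(float(np.median(ref[idx])))
        bin_mean.append(ref[idx].mean())
    x = np.array(bin_method)
    pcc_median, r2_median = _pcc_r2(x, np.array(bin_median))
    pcc_mean, r2_mean = _pcc_r2(x, np.array(bin_mean))
    return {
        "pcc_median": pcc_median,
        "pcc_mean": pcc_mean,
        "r2_median": r2_median,
        "r2_mean": r2_mean,
    }
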