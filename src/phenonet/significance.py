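"""Random-pair significance model for similar / dissimilar phenotype pairs.

An empirical null is built by sampling many random phenotype pairs and
scoring them; a pair whose score falls in the upper alpha tail of the null is
classified *similar*, in the lower alpha tail *dissimilar*, otherwise
*neither*.  The two classes can then be compared on independent reference
similarities with a Mann-Whitney U test.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .localization import PhenotypeModule
from .network import InteractionNetwork
from .similarity import SimilarityEngine


@dataclass(frozen=True)
class PairClassification:
    term_a: str
    term_b: str
    sim: float
    empirical_quantile: float
    label: str  # "similar" | "dissimilar" | "neither"


def null_pair_distribution(
    network: InteractionNetwork,
    modules: Sequence[PhenotypeModule],
    n_pairs: int = 100_000,
    rng=None,
) -> np.ndarray:
    """Scores of ``n_pairs`` uniformly sampled distinct module pairs, sorted.

    Pairs are drawn with replacement across draws; each distinct unordered
    pair's score is computed once and cached, so the cost is bounded by the
    number of distinct pairs actually sampled.
    """
    if len(modules) < 2:
        raise ValueError("need at least 2 modules to sample pairs")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    engine = SimilarityEngine(network)
    m = len(modules)
    pair_index = [(i, j) for i in range(m) for j in range(i + 1, m)]
    draws = rng.integers(0, len(pair_index), size=n_pairs)
    cache: dict[int, float] = {}
    values = np.empty(n_pairs, dtype=float)
    for k, idx in enumerate(draws):
        idx = int(idx)
        v = cache.get(idx)
        if v is None:
            i, j = pair_index[idx]
            v = engine.score(modules[i], modules[j]).sim
            cache[idx] = v
        values[k] = v
    values.sort()
    return values


def classify_pair(
    sim: float,
    null: np.ndarray,
    alpha: float = 0.05,
    term_a: str = "",
    term_b: str = "",
) -> PairClassification:
    """Classify one pair against a sorted empirical null distribution.

    The empirical quantile is the fraction of null scores <= sim; labels are
    assigned per tail at level ``alpha`` (the "two red lines" of the score
    distribution).
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    q = float(np.searchsorted(null, sim, side="right")) / null.size
    if q >= 1.0 - alpha:
        label = "similar"
    elif q <= alpha:
        label = "dissimilar"
    else:
        label = "neither"
    return PairClassification(
        term_a=term_a, term_b=term_b, sim=float(sim), empirical_quantile=q, label=label
    )


def compare_groups(
    similar_scores: Sequence[float], dissimilar_scores: Sequence[float]
) -> dict[str, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected) plus group means."""
    similar = np.asarray(similar_scores, dtype=float)
    dissimilar = np.asarray(dissimilar_scores, dtype=float)
    if similar.size == 0 or dissimilar.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(
        similar, dissimilar, alternative="two-sided", method="asymptotic"
    )
    return {
        "u_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_similar": float(similar.mean()),
        "mean_dissimilar": float(dissimilar.mean()),
    }
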