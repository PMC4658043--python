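"""Term enrichment: hypergeometric SEA with FDR control and signed
rank-sum z-scores per functional category.

Singular Enrichment Analysis tests a flat study list against each term's
gene set with the hypergeometric upper tail and controls the FDR across
terms (Benjamini-Hochberg step-up by default).  The category z-score
summarises whether a functional bin's log2 fold changes are shifted
relative to the background via a two-sided Wilcoxon rank-sum test; the
z-score is zeroed whenever the p-value exceeds alpha, so only significant
category shifts are displayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for a hypergeometric draw of n from N with K
    successes, summed exactly in rational arithmetic.

    Parameters follow the enrichment convention: k study hits, K term size
    in the background, n study size, N background size.
    """
    if K > N or n > N or k > K or k > n or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(min(acc, Fraction(1)))


def bh_fdr(p_values: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving.

    ``method`` may be ``"fdr_bh"`` (default) or ``"fdr_by"`` for the
    Benjamini-Yekutieli variant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method=method)[1])


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study hits
    n: int  # study size
    K: int  # term size in background
    N: int  # background size
    p_value: float
    q_value: float
    enriched: bool


def sea_enrich(
    study: set,
    background: set,
    genesets: Mapping[str, Sequence[str]],
    fdr_threshold: float = 0.05,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of the study set in every term, with FDR
    control across all tested terms."""
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    N, n = len(background), len(study)
    terms = list(genesets)
    counts = []
    for term in terms:
        members = set(genesets[term]) & background
        counts.append((len(study & members), len(members)))
    pvals = [hypergeom_pvalue(k, K, n, N) for k, K in counts]
    qvals = bh_fdr(pvals, method=method)
    return [
        EnrichmentResult(
            term=term,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            q_value=q,
            enriched=q <= fdr_threshold,
        )
        for term, (k, K), p, q in zip(terms, counts, pvals, qvals)
    ]


@dataclass(frozen=True)
class CategoryZScore:
    category: str
    wilcoxon_p: float
    z: float
    direction: str  # "up", "down" or "none"


EXACT_MAX_PRODUCT = 5000  # n_bin * n_background bound for the exact null


def _ranksum_pvalue(bin_values: np.ndarray, background: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for tieless samples of modest
    size, normal approximation with continuity correction otherwise."""
    combined = np.concatenate([bin_values, background])
    tieless = len(np.unique(combined)) == combined.size
    exact = tieless and bin_values.size * background.size <= EXACT_MAX_PRODUCT
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        bin_values, background, alternative="two-sided", method=method
    )
    return float(res.pvalue)


def pageman_z(
    bin_values: Sequence[float],
    background_values: Sequence[float],
    alpha: float = 0.05,
    min_size: int = 3,
    category: str = "",
) -> CategoryZScore:
    """Signed category z-score from a Wilcoxon rank-sum test.

    z = sign(median(bin) - median(background)) * |Phi^-1(p/2)|, forced to 0
    when p > alpha or the bin is smaller than ``min_size`` — only
    significantly shifted categories carry a signal.
    """
    bg = np.asarray(background_values, dtype=float)
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    b = np.asarray(bin_values, dtype=float)
    if b.size < min_size:
        return CategoryZScore(category, 1.0, 0.0, "none")
    p = _ranksum_pvalue(b, bg)
    if p > alpha:
        return CategoryZScore(category, p, 0.0, "none")
    shift = float(np.median(b) - np.median(bg))
    sign = 1.0 if shift > 0 else (-1.0 if shift < 0 else 0.0)
    z = sign * abs(stats.norm.isf(p / 2.0))
    direction = "up" if z > 0 else ("down" if z < 0 else "none")
    return CategoryZScore(category, p, float(z), direction)
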