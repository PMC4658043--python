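"""Weighted co-expression network and pathway-level co-expression Z-scores.

Transcripts are filtered to those expressed (FPKM > 0.1) in all six
tissue-by-condition observations, pairwise weights are the unsigned
soft-threshold adjacency |r|^beta over those observations, and each
pathway is summarised by

    Z = (Sm - mu) * m / delta

where Sm is the mean weight of regulator-DEG pairs above the cutoff
(default 0.2), m the number of distinct regulators appearing in those
pairs, and mu/delta the mean and standard deviation of the weights over
all regulator-gene candidate pairs in the network background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


def filter_expressed(matrix: ExpressionMatrix, min_fpkm: float = 0.1,
                     require_all: bool = True) -> ExpressionMatrix:
    """Keep genes with FPKM above the floor in the tissue-by-condition means.

    Replicates are averaged first; with ``require_all`` (default) a gene
    must pass the floor in every one of the six observation columns,
    otherwise in at least one.
    """
    means = matrix.condition_means()
    mask = (means > min_fpkm).all(axis=1) if require_all else (means > min_fpkm).any(axis=1)
    return matrix.subset(means.index[mask])


def coexpr_weight(x, y, beta: int = 6) -> float:
    """Unsigned soft-threshold adjacency |pearson r|^beta between profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant profiles")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(abs(r), 1.0) ** beta)


@dataclass
class CoexpressionNetwork:
    """Symmetric gene-pair weights over the filtered transcript set."""

    genes: list[str]
    weights: np.ndarray  # symmetric, unit diagonal
    beta: int = 6

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    def weight(self, g1: str, g2: str) -> float:
        return float(self.weights[self._index[g1], self._index[g2]])


def build_network(matrix: ExpressionMatrix, beta: int = 6) -> CoexpressionNetwork:
    """All unordered pair weights over the tissue-by-condition mean profiles.

    Correlation is computed on log2 FPKM: on the raw scale the log-normal
    heavy tail lets single extreme observations dominate r.  The matrix
    must already be expression-filtered (FPKM > 0.1 everywhere), which
    guarantees positivity.
    """
    means = matrix.condition_means()
    if len(means) < 2:
        raise ValueError("need at least 2 genes")
    raw = means.to_numpy(dtype=float)
    if (raw <= 0).any():
        raise ValueError("non-positive FPKM; apply filter_expressed first")
    profiles = np.log2(raw)
    if (np.ptp(profiles, axis=1) == 0).any():
        raise ValueError("constant expression profile; filter before networking")
    r = np.corrcoef(profiles)
    w = np.minimum(np.abs(r), 1.0) ** beta
    np.fill_diagonal(w, 1.0)
    return CoexpressionNetwork(genes=list(means.index), weights=w, beta=beta)


@dataclass(frozen=True)
class PathwayZScore:
    pathway: str
    s_m: float  # mean weight of selected pairs
    mu: float  # background mean weight
    delta: float  # background weight SD
    m: int  # distinct regulators in selected pairs
    z: float
    cutoff: float


def _background_weights(
    network: CoexpressionNetwork, regulators: set
) -> np.ndarray:
    reg_idx = [network._index[r] for r in sorted(regulators)]
    other_idx = [i for i, g in enumerate(network.genes) if g not in regulators]
    return network.weights[np.ix_(other_idx, reg_idx)].ravel()


def pathway_zscore(
    network: CoexpressionNetwork,
    pathway_degs: set,
    regulators: set,
    cutoff: float = 0.2,
    pathway: str = "",
) -> PathwayZScore:
    """Z = (Sm - mu) * m / delta for one pathway's DEGs against regulators.

    mu and delta are taken over all regulator x non-regulator gene pairs in
    the network (the population the selected pairs are drawn from).  With
    no pair above the cutoff, m = 0 and Z = 0.
    """
    missing = (pathway_degs | regulators) - set(network.genes)
    if missing:
        raise ValueError(f"ids not in network: {sorted(missing)[:5]}")
    if pathway_degs & regulators:
        raise ValueError("pathway DEGs and regulators must be disjoint")
    bg = _background_weights(network, regulators)
    mu = float(bg.mean())
    delta = float(bg.std(ddof=0))
    if delta == 0:
        raise ValueError("degenerate background: zero weight variance")
    selected = [
        (d, r, network.weight(d, r))
        for d in sorted(pathway_degs)
        for r in sorted(regulators)
        if network.weight(d, r) > cutoff
    ]
    if not selected:
        return PathwayZScore(pathway, float("nan"), mu, delta, 0, 0.0, cutoff)
    s_m = float(np.mean([w for _, _, w in selected]))
    m = len({r for _, r, _ in selected})
    z = (s_m - mu) * m / delta
    return PathwayZScore(pathway, s_m, mu, delta, m, float(z), cutoff)


def pathway_zscore_table(
    network: CoexpressionNetwork,
    pathways: Mapping[str, Sequence[str]],
    degs: set,
    regulators: set,
    cutoff: float = 0.2,
) -> pd.DataFrame:
    """Z-score summary for each pathway, restricted to its DEG members."""
    rows = []
    net_genes = set(network.genes)
    regulators = regulators & net_genes
    for name, members in pathways.items():
        pdegs = (set(members) & degs & net_genes) - regulators
        if not pdegs:
            continue
        zs = pathway_zscore(network, pdegs, regulators, cutoff, pathway=name)
        rows.append(
            {
                "pathway": name,
                "m": zs.m,
                "Sm": zs.s_m,
                "mu": zs.mu,
                "delta": zs.delta,
                "Z": zs.z,
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "m", "Sm", "mu", "delta", "Z"])


def high_coexpr_pairs(
    network: CoexpressionNetwork, regulators: set, cutoff: float = 0.2
) -> list[tuple[str, str, float]]:
    """(regulator, gene, weight) for every pair above the cutoff, sorted by
    descending weight then lexical ids."""
    missing = regulators - set(network.genes)
    if missing:
        raise ValueError(f"regulators not in network: {sorted(missing)[:5]}")
    pairs = [
        (r, g, network.weight(r, g))
        for r in sorted(regulators)
        for g in network.genes
        # unordered pairs: list regulator-regulator pairs once
        if g != r and not (g in regulators and g < r) and network.weight(r, g) > cutoff
    ]
    return sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))
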