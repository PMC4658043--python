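"""Differential-expression calling between drought and control FPKM replicates.

A gene is differentially expressed in a tissue when its drought/control
fold change exceeds 2 (or is below 1/2) strictly, and the replicate test
p-value is at most 0.05.  The replicate test is a two-sided Welch t on
log2(FPKM + 1) with a per-group variance floor so that identical replicate
vectors give p = 1 instead of a 0/0 statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

VARIANCE_FLOOR = 1e-8


def fold_change(mean_drought: float, mean_control: float, pseudocount: float = 0.1) -> float:
    """Pseudocounted expression ratio (drought + eps) / (control + eps)."""
    if mean_drought < 0 or mean_control < 0:
        raise ValueError("FPKM means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (mean_drought + pseudocount) / (mean_control + pseudocount)


def deg_test(drought_reps, control_reps) -> float:
    """Two-sided Welch t-test p-value on log2(FPKM + 1) replicate values.

    Per-group variances are floored at 1e-8 so constant groups are handled;
    degrees of freedom follow Welch-Satterthwaite.
    """
    d = np.log2(np.asarray(drought_reps, dtype=float) + 1.0)
    c = np.log2(np.asarray(control_reps, dtype=float) + 1.0)
    if d.size < 2 or c.size < 2:
        raise ValueError("need at least 2 replicates per condition")
    vd = max(d.var(ddof=1), VARIANCE_FLOOR)
    vc = max(c.var(ddof=1), VARIANCE_FLOOR)
    se2 = vd / d.size + vc / c.size
    t = (d.mean() - c.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vd / d.size) ** 2 / (d.size - 1) + (vc / c.size) ** 2 / (c.size - 1)
    )
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    tissue: str
    fold_change: float
    p_value: float
    direction: str  # "up" or "down"


def call_degs(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    pseudocount: float = 0.1,
    drought: str = "drought",
    control: str = "control",
) -> dict[str, list[DEGRecord]]:
    """Call DEGs per tissue: fold change strictly beyond the threshold in
    either direction AND p-value at most ``p_threshold``."""
    out: dict[str, list[DEGRecord]] = {}
    for tissue in matrix.tissues:
        dcols = matrix.replicate_columns(tissue, drought)
        ccols = matrix.replicate_columns(tissue, control)
        if not dcols or not ccols:
            continue
        dvals = matrix.values[dcols].to_numpy(dtype=float)
        cvals = matrix.values[ccols].to_numpy(dtype=float)
        records = []
        for i, gene in enumerate(matrix.genes):
            fc = fold_change(dvals[i].mean(), cvals[i].mean(), pseudocount)
            if not (fc > fc_threshold or fc < 1.0 / fc_threshold):
                continue
            p = deg_test(dvals[i], cvals[i])
            if p <= p_threshold:
                records.append(
                    DEGRecord(
                        gene_id=gene,
                        tissue=tissue,
                        fold_change=fc,
                        p_value=p,
                        direction="up" if fc > fc_threshold else "down",
                    )
                )
        out[tissue] = records
    return out


@dataclass
class OverlapSummary:
    """Seven-region partition of three DEG id sets plus the common genes."""

    leaf_only: int
    stem_only: int
    root_only: int
    leaf_stem: int
    leaf_root: int
    stem_root: int
    common: int
    common_genes: set[str]

    def region_counts(self) -> dict[str, int]:
        return {
            "leaf_only": self.leaf_only,
            "stem_only": self.stem_only,
            "root_only": self.root_only,
            "leaf_stem": self.leaf_stem,
            "leaf_root": self.leaf_root,
            "stem_root": self.stem_root,
            "common": self.common,
        }

    @property
    def total(self) -> int:
        return sum(self.region_counts().values())


def overlap_partition(leaf: set, stem: set, root: set) -> OverlapSummary:
    """Exact counts for the 7 regions of the three-set Venn partition."""
    common = leaf & stem & root
    return OverlapSummary(
        leaf_only=len(leaf - stem - root),
        stem_only=len(stem - leaf - root),
        root_only=len(root - leaf - stem),
        leaf_stem=len((leaf & stem) - root),
        leaf_root=len((leaf & root) - stem),
        stem_root=len((stem & root) - leaf),
        common=len(common),
        common_genes=set(common),
    )


def direction_concordance(
    records_by_tissue: dict[str, list[DEGRecord]], common_genes: set[str]
) -> float:
    """Fraction of common genes whose up/down direction differs between
    tissues.  Every common gene must have a record in every tissue."""
    if not common_genes:
        return 0.0
    directions: dict[str, dict[str, str]] = {}
    for tissue, records in records_by_tissue.items():
        directions[tissue] = {r.gene_id: r.direction for r in records}
    discordant = 0
    for gene in common_genes:
        dirs = set()
        for tissue, dmap in directions.items():
            if gene not in dmap:
                raise ValueError(f"gene {gene!r} has no record in tissue {tissue!r}")
            dirs.add(dmap[gene])
        if len(dirs) > 1:
            discordant += 1
    return discordant / len(common_genes)


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue,
            "log2FC": np.log2(r.fold_change),
            "FC": r.fold_change,
            "p": r.p_value,
            "direction": r.direction,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "log2FC", "FC", "p", "direction"]
    )
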