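"""qPCR relative expression, drought-tolerance indices, and their correlation.

Relative expression is computed by the delta-delta Ct method with a
reference gene (zSSIIb in the maize panel) and perfect-doubling
amplification: RQ = 2^(-ddCt).  The drought tolerance index (DTI) of an
inbred line is the drought/control biomass ratio (fresh or dry).  Each
gene's relative-expression vector across lines is correlated with the DTI
vector by Pearson's r, with the two-sided p-value from the t transform
t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; the significance
star uses strict p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def ddct_relative_expression(
    treat_target: Sequence[float],
    treat_reference: Sequence[float],
    calib_target: Sequence[float],
    calib_reference: Sequence[float],
) -> float:
    """2^(-ddCt) relative expression of treatment vs calibrator.

    Replicate Ct values are averaged within each condition; dCt is target
    minus reference, ddCt is treatment dCt minus calibrator dCt.
    """
    arrays = [
        np.asarray(a, dtype=float)
        for a in (treat_target, treat_reference, calib_target, calib_reference)
    ]
    for a in arrays:
        if a.size == 0:
            raise ValueError("missing Ct measurements")
        if not np.all(np.isfinite(a)) or (a <= 0).any():
            raise ValueError("Ct values must be positive and finite")
    tt, tr, ct, cr = (a.mean() for a in arrays)
    ddct = (tt - tr) - (ct - cr)
    return float(2.0 ** (-ddct))


def compute_dti(drought_biomass: float, control_biomass: float) -> float:
    """Drought tolerance index: drought/control biomass ratio."""
    if drought_biomass <= 0 or control_biomass <= 0:
        raise ValueError("biomass must be positive")
    return drought_biomass / control_biomass


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    trait: str  # "fresh" or "dry"
    r: float
    n: int
    p_value: float
    significant: bool


def pearson_with_p(x, y, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Sample Pearson r with the two-sided t-based p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(p < alpha)


def correlation_table(
    expr: pd.DataFrame, dti: pd.DataFrame, alpha: float = 0.05
) -> list[CorrelationResult]:
    """Correlate every gene's per-line relative expression with each DTI trait.

    Parameters
    ----------
    expr
        Lines x genes relative-expression table (index = line ids).
    dti
        Lines x traits table with ``fresh`` and/or ``dry`` DTI columns.
    """
    shared = [ln for ln in expr.index if ln in dti.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared lines")
    e = expr.loc[shared]
    d = dti.loc[shared]
    results = []
    for trait in d.columns:
        for gene in e.columns:
            r, p, sig = pearson_with_p(e[gene], d[trait], alpha=alpha)
            results.append(
                CorrelationResult(
                    gene_id=gene,
                    trait=trait,
                    r=r,
                    n=len(shared),
                    p_value=p,
                    significant=sig,
                )
            )
    return results


def relative_expression_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Lines x genes relative expression from a long-format Ct table.

    Expects columns line/gene/condition/ct_target/ct_reference (and
    optionally rep); drought is the treatment, control the calibrator.
    """
    out: dict[str, dict[str, float]] = {}
    for (line, gene), grp in ct.groupby(["line", "gene"], sort=True):
        treat = grp[grp["condition"] == "drought"]
        calib = grp[grp["condition"] == "control"]
        if treat.empty or calib.empty:
            raise ValueError(f"missing condition for line {line!r}, gene {gene!r}")
        out.setdefault(line, {})[gene] = ddct_relative_expression(
            treat["ct_target"],
            treat["ct_reference"],
            calib["ct_target"],
            calib["ct_reference"],
        )
    frame = pd.DataFrame(out).T.sort_index()
    frame.index.name = "line"
    return frame


def dti_table(biomass: pd.DataFrame) -> pd.DataFrame:
    """Lines x {fresh, dry} DTI from a long-format biomass table.

    Expects columns line/condition/fresh_g/dry_g with one drought and one
    control row per line (replicates, if any, averaged first).
    """
    rows = {}
    for line, grp in biomass.groupby("line", sort=True):
        drought = grp[grp["condition"] == "drought"]
        control = grp[grp["condition"] == "control"]
        if drought.empty or control.empty:
            raise ValueError(f"missing condition for line {line!r}")
        rows[line] = {
            "fresh": compute_dti(
                drought["fresh_g"].mean(), control["fresh_g"].mean()
            ),
            "dry": compute_dti(drought["dry_g"].mean(), control["dry_g"].mean()),
        }
    frame = pd.DataFrame(rows).T
    frame.index.name = "line"
    return frame


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Panel-style report: one row per (trait, gene) with a star column."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "gene_id": r.gene_id,
                "n": r.n,
                "r": r.r,
                "p": r.p_value,
                "star": "*" if r.significant else "",
            }
            for r in results
        ]
    )
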