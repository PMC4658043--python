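"""Synthetic input generators with planted, recoverable ground truth.

Every downstream stage of the pipeline (family identification, DEG
calling, enrichment, co-expression scoring, qPCR-phenotype correlation)
can be exercised without external data: these generators produce
proteomes with planted subfamily motifs and homolog structure, FPKM
matrices with planted fold changes, gene sets with one packed term,
expression matrices with planted co-expressed pathway blocks, and
Ct/biomass tables with a specified true expression-DTI correlation.

All generators are pure functions of their integer seed and parameters;
zero-noise settings reduce each one to an exactly computable closed form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .family import CANONICAL_RESIDUES, SUBFAMILY_PATTERNS, MotifPattern, scan_motif

RESIDUES = sorted(CANONICAL_RESIDUES)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying each generated artifact."""

    family_members: set[str] = field(default_factory=set)
    subfamily_of: dict[str, str] = field(default_factory=dict)
    deg_ids: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    coexpressed_pairs: set[tuple[str, str]] = field(default_factory=set)
    true_rho: float | None = None
    # extra planted detail useful for round-trip tests
    planted_expression: dict[str, float] = field(default_factory=dict)
    planted_dti: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.subfamily_of) <= self.family_members:
            raise ValueError("subfamily labels must cover family members only")
        if self.true_rho is not None and not -1 <= self.true_rho <= 1:
            raise ValueError("true_rho must lie in [-1, 1]")

    def to_sidecar(self, path) -> None:
        """Serialize as a plain-text key=value sidecar."""
        with open(path, "w") as fh:
            for m in sorted(self.family_members):
                fh.write(f"family_member={m}\n")
            for k, v in sorted(self.subfamily_of.items()):
                fh.write(f"subfamily\t{k}={v}\n")
            for tissue, pairs in sorted(self.deg_ids.items()):
                for gene, direction in sorted(pairs):
                    fh.write(f"deg\t{tissue}\t{gene}={direction}\n")
            for t in sorted(self.enriched_terms):
                fh.write(f"enriched_term={t}\n")
            for pw, reg in sorted(self.coexpressed_pairs):
                fh.write(f"coexpressed\t{pw}={reg}\n")
            if self.true_rho is not None:
                fh.write(f"true_rho={self.true_rho}\n")


# ------------------------------------------------------------- proteins


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RESIDUES, size=length))


def _instantiate_motif(rng: np.random.Generator, pattern: MotifPattern) -> str:
    out = []
    for el in pattern.elements:
        if el is None:
            out.append(rng.choice(RESIDUES))
        else:
            out.append(rng.choice(sorted(el)))
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n_mut = int(round(rate * len(chars)))
    for i in rng.choice(len(chars), size=n_mut, replace=False):
        choices = [r for r in RESIDUES if r != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _motif_hits(seq: str, patterns) -> dict[str, int]:
    return {p.label: len(scan_motif(seq, p)) for p in patterns}


def gen_proteins(
    seed: int,
    n_per_subfamily: int = 5,
    n_background: int = 20,
    length: int = 300,
    n_queries_per_subfamily: int = 6,
    member_mutation: float = 0.30,
    query_mutation: float = 0.20,
    patterns=SUBFAMILY_PATTERNS,
) -> tuple[dict[str, str], dict[str, str], SyntheticTruth]:
    """Synthetic proteome with planted family structure.

    Each subfamily derives from its own random ancestor; queries (the
    reference-species homolog panel) and family members are mutated copies
    of that ancestor, so members share well over 40% identity with every
    query of their subfamily.  Each member carries exactly one instance of
    its subfamily's signature motif; background sequences are uniform
    random and motif-free.

    Returns (candidates, queries, truth).
    """
    if n_per_subfamily < 0 or n_background < 0:
        raise ValueError("counts must be non-negative")
    longest = max(len(p) for p in patterns)
    if length < max(30, longest):
        raise ValueError(f"length must be at least {max(30, longest)}")
    rng = np.random.default_rng(seed)
    candidates: dict[str, str] = {}
    queries: dict[str, str] = {}
    truth = SyntheticTruth()

    def clean(seq: str, want_label: str | None, want_count: int) -> bool:
        hits = _motif_hits(seq, patterns)
        for label, count in hits.items():
            expect = want_count if label == want_label else 0
            if count != expect:
                return False
        return True

    for pattern in patterns:
        ancestor = _random_sequence(rng, length)
        for q in range(n_queries_per_subfamily):
            queries[f"query_{pattern.label}_{q + 1}"] = _mutate(
                rng, ancestor, query_mutation
            )
        made = 0
        while made < n_per_subfamily:
            seq = _mutate(rng, ancestor, member_mutation)
            motif = _instantiate_motif(rng, pattern)
            offset = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:offset] + motif + seq[offset + len(motif) :]
            if not clean(seq, pattern.label, 1):
                continue
            made += 1
            sid = f"member_{pattern.label}_{made}"
            candidates[sid] = seq
            truth.family_members.add(sid)
            truth.subfamily_of[sid] = pattern.label
    made = 0
    while made < n_background:
        seq = _random_sequence(rng, length)
        if not clean(seq, None, 0):
            continue
        made += 1
        candidates[f"background_{made}"] = seq
    return candidates, queries, truth


# ----------------------------------------------------------- expression

TISSUE_NAMES = ("leaf", "stem", "root")


def gen_expression(
    seed: int,
    n_genes: int = 2000,
    tissues: int = 3,
    conditions: int = 2,
    reps: int = 2,
    deg_fraction: float = 0.1,
    lfc_mean: float = 3.0,
    noise_sd: float = 0.1,
    baseline_log2_mean: float = 3.0,
    baseline_log2_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """FPKM matrix with planted per-tissue differential expression.

    Baseline log2 FPKM is normal (log-normal FPKM); a fraction of genes per
    tissue receives a multiplicative drought effect of at least 2-fold in a
    random direction, with log2 magnitude centred on ``lfc_mean`` (clipped
    at 1 so every planted DEG is recoverable in principle); replicate noise
    is multiplicative log-normal with log2 sd ``noise_sd``.
    """
    if not 0 <= deg_fraction <= 1:
        raise ValueError("deg_fraction must be in [0, 1]")
    if reps < 2:
        raise ValueError("need at least 2 replicates for the replicate test")
    if conditions != 2:
        raise ValueError("only the drought/control two-condition design is supported")
    rng = np.random.default_rng(seed)
    tissue_names = [
        TISSUE_NAMES[i] if i < len(TISSUE_NAMES) else f"tissue{i + 1}"
        for i in range(tissues)
    ]
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)

    truth = SyntheticTruth()
    n_deg = int(round(deg_fraction * n_genes))
    effects: dict[str, np.ndarray] = {}
    for tissue in tissue_names:
        idx = rng.choice(n_genes, size=n_deg, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_deg)
        mags = np.maximum(1.0, rng.normal(lfc_mean, 0.5, size=n_deg))
        eff = np.zeros(n_genes)
        eff[idx] = signs * mags
        effects[tissue] = eff
        truth.deg_ids[tissue] = {
            (genes[i], "up" if s > 0 else "down") for i, s in zip(idx, signs)
        }

    columns = {}
    for tissue, condition, rep in itertools.product(
        tissue_names, ("drought", "control"), range(1, reps + 1)
    ):
        log2 = baseline.copy()
        if condition == "drought":
            log2 = log2 + effects[tissue]
        if noise_sd > 0:
            log2 = log2 + rng.normal(0.0, noise_sd, size=n_genes)
        columns[f"{tissue}_{condition}_{rep}"] = 2.0**log2
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    return matrix, truth


# ------------------------------------------------------------ gene sets


def gen_genesets(
    seed: int,
    n_terms: int,
    genes: list[str],
    enriched_term_size: int,
    deg_overlap: int,
    study: list[str] | None = None,
) -> tuple[dict[str, list[str]], SyntheticTruth]:
    """Term -> gene-list map with one designated packed term.

    The first term is packed with ``deg_overlap`` ids from the study list
    (defaulting to the first ``deg_overlap`` genes) and topped up with
    non-study genes; remaining terms sample genes uniformly.
    """
    if enriched_term_size > len(genes):
        raise ValueError("enriched_term_size exceeds number of genes")
    if deg_overlap > enriched_term_size:
        raise ValueError("deg_overlap cannot exceed enriched_term_size")
    rng = np.random.default_rng(seed)
    if study is None:
        study = genes[:deg_overlap]
    if deg_overlap > len(study):
        raise ValueError("deg_overlap exceeds study size")
    study_arr = sorted(study)
    non_study = [g for g in genes if g not in set(study)]
    genesets: dict[str, list[str]] = {}
    truth = SyntheticTruth()
    for t in range(n_terms):
        term = f"T{t + 1:03d}"
        if t == 0:
            packed = list(rng.choice(study_arr, size=deg_overlap, replace=False))
            filler = list(
                rng.choice(non_study, size=enriched_term_size - deg_overlap, replace=False)
            )
            genesets[term] = sorted(packed + filler)
            truth.enriched_terms.add(term)
        else:
            genesets[term] = sorted(
                rng.choice(genes, size=enriched_term_size, replace=False)
            )
    return genesets, truth


# --------------------------------------------------------- co-expression


def gen_coexpression(
    seed: int,
    n_genes: int = 60,
    n_pathways: int = 5,
    pathway_size: int = 8,
    n_regulators: int = 5,
    n_coexpr_regulators: int = 3,
    planted_rho: float = 0.95,
    noise_sd: float = 0.0,
    reps: int = 2,
) -> tuple[ExpressionMatrix, dict[str, list[str]], list[str], SyntheticTruth]:
    """Expression matrix with one pathway block co-expressed with regulators.

    Pathway ``P001`` is split round-robin into sub-blocks, one per planted
    regulator; each planted regulator carries its own latent
    six-observation profile (latents mutually sample-orthogonal) and every
    gene of its sub-block mixes that latent with an orthogonalised private
    component, so the sample correlation between a planted pathway gene
    and its regulator is exactly ``planted_rho``, while different
    sub-blocks and the remaining genes are uncorrelated by construction.
    ``noise_sd`` is replicate-level log2 noise (0 gives identical
    replicates and hence exactly computable weights).

    Returns (matrix, pathway gene-set map, regulator ids, truth).
    """
    if not 0 <= planted_rho <= 1:
        raise ValueError("planted_rho must be in [0, 1]")
    if n_pathways * pathway_size + n_regulators > n_genes:
        raise ValueError("n_genes too small for the requested design")
    rng = np.random.default_rng(seed)
    n_obs = 6  # three tissues x two conditions
    if n_coexpr_regulators + 1 >= n_obs:
        raise ValueError("too many co-expressed regulators for six observations")

    def standardize(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    def residual_unit(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
        """Standardized residual of v on [1, basis...] (sample-orthogonal)."""
        e = v - v.mean()
        for b in basis:
            e = e - (e @ b) / (b @ b) * b
        return e / e.std()

    latents: list[np.ndarray] = []
    for _ in range(n_coexpr_regulators):
        latents.append(
            standardize(residual_unit(rng.normal(0.0, 1.0, size=n_obs), latents))
        )

    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    regulators = [f"reg{i + 1:02d}" for i in range(n_regulators)]
    pathways = {
        f"P{p + 1:03d}": genes[p * pathway_size : (p + 1) * pathway_size]
        for p in range(n_pathways)
    }
    planted_regs = regulators[:n_coexpr_regulators]
    latent_of = {r: latents[i] for i, r in enumerate(planted_regs)}
    for k, g in enumerate(pathways["P001"]):
        latent_of[g] = latents[k % n_coexpr_regulators]

    profiles = {}
    for g in genes + regulators:
        own = rng.normal(0.0, 1.0, size=n_obs)
        if g in planted_regs:
            profiles[g] = 3.0 + 2.0 * latent_of[g]
        elif g in latent_of:
            lat = latent_of[g]
            profiles[g] = 3.0 + 2.0 * (
                planted_rho * lat
                + np.sqrt(1 - planted_rho**2) * residual_unit(own, [lat])
            )
        else:
            profiles[g] = 3.0 + 2.0 * own

    columns = {}
    order = genes + regulators
    for tissue, condition in itertools.product(TISSUE_NAMES, ("drought", "control")):
        obs = TISSUE_NAMES.index(tissue) * 2 + (0 if condition == "drought" else 1)
        for rep in range(1, reps + 1):
            vals = np.array([profiles[g][obs] for g in order])
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=len(order))
            columns[f"{tissue}_{condition}_{rep}"] = 2.0**vals
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=order))
    truth = SyntheticTruth(
        coexpressed_pairs={("P001", r) for r in planted_regs}
    )
    return matrix, pathways, regulators, truth


# ------------------------------------------------------------- qPCR/DTI

CT_REFERENCE = 20.0
CT_CONTROL_TARGET = 28.0


def gen_qpcr_biomass(
    seed: int,
    n_lines: int = 8,
    true_rho: float = 0.8,
    reps: int = 3,
    ct_sd: float = 0.1,
    gene_id: str = "GENE1",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Ct and biomass tables with a planted expression-DTI correlation.

    Per-line relative-expression targets and fresh-biomass DTI values are
    drawn from a bivariate normal with correlation ``true_rho`` (expression
    N(5, 1.5), DTI N(0.6, 0.1), both clipped positive); Ct values are
    back-computed so that delta-delta Ct analysis returns the planted
    relative expression exactly in the noise-free limit.  Ct noise is
    additive normal per replicate (sd ``ct_sd`` cycles).

    Returns (ct table, biomass table, truth); the Ct table has columns
    line/gene/condition/ct_target/ct_reference/rep, the biomass table
    line/condition/fresh_g/dry_g.
    """
    if n_lines < 3:
        raise ValueError("need at least 3 lines")
    if not -1 <= true_rho <= 1:
        raise ValueError("|true_rho| must be at most 1")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, true_rho], [true_rho, 1.0]])
    uv = rng.multivariate_normal([0.0, 0.0], cov, size=n_lines)
    expr = np.clip(5.0 + 1.5 * uv[:, 0], 0.05, None)
    dti_fresh = np.clip(0.6 + 0.1 * uv[:, 1], 0.05, None)
    dti_dry = np.clip(dti_fresh + 0.07 + 0.01 * rng.normal(size=n_lines), 0.05, None)

    lines = [f"line{i + 1:02d}" for i in range(n_lines)]
    truth = SyntheticTruth(true_rho=true_rho)
    ct_rows = []
    biomass_rows = []
    for i, line in enumerate(lines):
        truth.planted_expression[line] = float(expr[i])
        truth.planted_dti[line] = (float(dti_fresh[i]), float(dti_dry[i]))
        drought_ct = CT_CONTROL_TARGET - np.log2(expr[i])
        for condition, target_ct in (
            ("drought", drought_ct),
            ("control", CT_CONTROL_TARGET),
        ):
            for rep in range(1, reps + 1):
                noise = rng.normal(0.0, ct_sd, size=2) if ct_sd > 0 else np.zeros(2)
                ct_rows.append(
                    {
                        "line": line,
                        "gene": gene_id,
                        "condition": condition,
                        "ct_target": target_ct + noise[0],
                        "ct_reference": CT_REFERENCE + noise[1],
                        "rep": rep,
                    }
                )
        control_fresh = max(float(rng.normal(10.0, 1.0)), 0.5)
        control_dry = control_fresh * 0.12
        biomass_rows.append(
            {
                "line": line,
                "condition": "control",
                "fresh_g": control_fresh,
                "dry_g": control_dry,
            }
        )
        biomass_rows.append(
            {
                "line": line,
                "condition": "drought",
                "fresh_g": control_fresh * dti_fresh[i],
                "dry_g": control_dry * dti_dry[i],
            }
        )
    return pd.DataFrame(ct_rows), pd.DataFrame(biomass_rows), truth
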