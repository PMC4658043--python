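# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical decisions made where the design was genuinely open.

## Family identification

Candidates are compared to a panel of query proteins (known MAPKKKs from
reference species) by local alignment: Smith–Waterman with BLOSUM62,
affine gaps costing 11 for the first residue and 1 for each further
residue (`Bio.Align.PairwiseAligner` in local mode). Identity is the
number of identical residue pairs divided by the alignment length with
gap columns included in the denominator; when no positive-scoring local
alignment exists the empty alignment is optimal and identity is 0. The
two sequences are ordered canonically before alignment so the value is
symmetric even when co-optimal alignments differ.

A query *qualifies* when identity exceeds `identity_threshold`
(default 0.25, strict) **and** the alignment covers at least
`min_coverage` (default 0.5) of the shorter sequence; a candidate is a
family member when at least `min_hits` (default 5, inclusive) distinct
queries qualify. The coverage requirement is essential, not cosmetic:
the best local alignment between two *unrelated* proteins is typically a
short segment of 10–50 residues at 25–60 % identity — span identity alone
cannot separate homologs from noise. Requiring half-length coverage
emulates the near-full-length homology blocks that genome-scale aligners
such as BLAT report, and on synthetic proteomes it separates planted
members (near-global alignments at ≈ 50–60 % identity) from uniform-random
background (long alignments plateau near 18–20 % identity) with no errors.

Subfamily calls are independent of membership strength: a sequence
receives every subfamily label whose degenerate signature motif (fixed
residues, `x` wildcards, `(A/B)` alternative sets) matches at least once.
Multiple labels are reported as a set — no priority order is imposed.

## DEG calling

The replicate test is a two-sided Welch *t* on log2(FPKM + 1) with each
group variance floored at 1e-8; the floor makes identical replicate
vectors return p = 1 rather than 0/0, and is far below any real replicate
variance. Welch–Satterthwaite degrees of freedom are used. Negative
binomial count models are deliberately out of scope — the selection rule,
not the test, is the analysis' substance, and the Welch form is
closed-form checkable.

Fold change is computed on replicate means with a pseudocount
ε = 0.1 FPKM in numerator and denominator, bounding behaviour at zero
expression. The call rule is *strict* on fold change (> 2 or < 1/2) and
*inclusive* on p (≤ 0.05); no multiple-testing correction is applied at
this stage (FDR control enters only in enrichment). Up and down calls
are mutually exclusive by construction and sum to the per-tissue total.

## Enrichment

`hypergeom_pvalue` sums the hypergeometric pmf in exact rational
arithmetic (`fractions.Fraction` over binomial coefficients), so the tail
is correct to the last bit even for extreme counts; the test suite
cross-checks it against `scipy.stats.hypergeom` and against exhaustive
draw enumeration. FDR control is Benjamini–Hochberg step-up
(`statsmodels`), switchable to Benjamini–Yekutieli. Terms are flat gene
sets: no GO DAG propagation is performed, so enrichment of a parent term
must be encoded explicitly in the input sets if desired.

Category z-scores use the two-sided Wilcoxon rank-sum test: exact null
distribution for tieless samples when n_bin × n_background ≤ 5000, else
the normal approximation with continuity correction. The z-score is
sign(median(bin) − median(background)) · |Φ⁻¹(p/2)|, set to 0 whenever
p > α (default 0.05) or the bin holds fewer than `min_size` = 3 values —
tiny bins are treated as uninformative rather than as errors. Signing by
medians (not means) keeps the statistic fully rank-based: its magnitude
is invariant under any strictly monotone transform of the values.

## Co-expression

Replicates are averaged within each tissue×condition, giving six
observation columns; genes must exceed FPKM 0.1 in *all six* (the
at-least-one reading is available via `require_all=False`). Network
weights are the unsigned soft-threshold adjacency |r|^β with β = 6, the
conventional unsigned default. Correlation is computed on log2 FPKM:
on the raw scale the log-normal heavy tail lets one extreme observation
dominate r and produces spurious near-1 weights between unrelated genes.

The pathway statistic is implemented exactly as printed,
Z = (Sm − μ) × m / δ, with the selection cutoff 0.2 applied to weights
(weight > 0.2 corresponds to |r| > 0.765 at β = 6). The background
(μ, δ) is taken over all regulator × non-regulator gene weights — the
population from which selected pairs are drawn. Two properties of this
statistic deserve note. First, the ×m factor (not ×√m, which would be
the conventional standardisation) makes Z grow linearly with the number
of regulators attached to a pathway, so pathways with several
weakly-selected links can outscore pathways with one strong link.
Second, with only six observations the null sampling distribution of r
is heavy-tailed (P(|r| > 0.765) ≈ 7.6 % for independent profiles), so
chance selections are common; the observation count is therefore a
property of the input, not a constant, and more observations sharpen the
statistic considerably.

## qPCR and phenotype correlation

Relative expression is 2^(−ΔΔCt) with amplification efficiency fixed at
perfect doubling; replicate Cts are averaged within condition before
differencing. DTI is the drought/control biomass ratio. Pearson
correlations use the two-sided t transform, t = r√((n−2)/(1−r²)) with
df = n − 2, and a strict P < 0.05 star.

The bundled 8-gene × 8-line drought panel reproduces its published
correlation values at two decimals for the entire dry-biomass row and
five of eight fresh-biomass cells; the remaining three fresh cells
(MAPKKK19, MAPKKK20, MAPKKK22) recompute from the panel's own printed
inputs to 0.65, 0.70 and 0.22 — each 0.01 below the published 0.66, 0.71
and 0.23. Since the dry row reproduces exactly from the same inputs, the
likely cause is that the original fresh-trait values were computed from
higher-precision biomass measurements than were printed. The package
reports the recomputed values; the tests assert them and document the
discrepancy. The significance tier is a single α parameter (default
0.05) rather than a hard-coded second "slight correlation" tier.

## Synthetic data

The generators are pure functions of one integer seed (numpy
`default_rng`; no global state) and encode the statistical structure the
analyses assume:

* **Proteomes** — each subfamily descends from a random ancestor; queries
  mutate 20 % of positions, members 30 %, so member–query identity sits
  near 55–60 % over near-global alignments, comfortably above the 40 %
  floor the construction guarantees. Each member carries exactly one
  instance of its subfamily signature (re-drawn if a second instance
  arises by chance); backgrounds are uniform over the 20 canonical
  residues — no compositional bias is modelled.
* **Expression** — baseline log2 FPKM ~ N(3, 2) (a heavy-tailed FPKM
  range typical of RNA-seq summaries); a fraction of genes per tissue
  receives a drought effect with log2 magnitude ~ N(lfc_mean, 0.5)
  clipped at 1, so every planted DEG is at least two-fold; replicate
  noise is multiplicative log-normal (log2 sd `noise_sd`, default 0.1).
  Default sizes (2 000 genes, 10 % DEGs, two replicates) keep recovery
  experiments fast while leaving hundreds of planted positives.
* **Gene sets** — one designated term is packed with study ids; all other
  terms sample uniformly, so the packed term is the unique enrichable
  signal.
* **Co-expressed pathways** — each of the (default 3) planted regulators
  carries its own latent six-observation profile, latents mutually
  sample-orthogonal by Gram–Schmidt; the planted pathway's genes are
  assigned round-robin to regulators and mix the regulator's latent with
  an orthogonalised private component so the *sample* correlation to
  their regulator is exactly `planted_rho` (default 0.95). Exactness
  matters at six observations: with merely "true" correlations the
  planted weights fluctuate as heavily as the background's chance
  correlations. Distinct latents per regulator also prevent a single
  chance correlation from spuriously attaching a background gene to every
  regulator at once.
* **Ct/biomass tables** — per-line relative-expression targets
  (N(5, 1.5)) and fresh DTIs (N(0.6, 0.1), the range of real inbred-line
  panels) are drawn bivariate-normal with the requested correlation;
  dry DTI is fresh + 0.07 + N(0, 0.01). Ct values are back-computed
  (reference fixed at 20 cycles, control target at 28) so ΔΔCt returns
  the planted expression exactly at zero noise; noise is additive normal
  on the Ct scale (default sd 0.1 cycles, typical technical scatter),
  where ΔΔCt is linear.

What the generators do **not** emulate: read-level sampling (generation
starts at FPKM summaries), gene–gene correlation in the DEG matrices
(genes are independent), tissue-driven global covariance in the
co-expression background, library-size artefacts, and qPCR efficiency
deviations from perfect doubling. Passing recovery tests therefore show
that the selection rules and statistics behave as specified under their
own assumptions — not that those thresholds are optimal for any
particular real data set.

With planted rho = 0.8 and n = 8 lines, the mean recovered Pearson r over
many seeds sits near 0.75: small-sample bias of r (≈ −0.02 at n = 8) and
Ct-noise attenuation both pull the estimate down. This is a property of
the estimator at the study's sample size, not of the generator.

## Problem sizes

The recovery experiments use 2 000-gene matrices over 10 seeds (DEGs),
5 000-gene backgrounds with 20 terms over 10 seeds (enrichment),
60-gene/5-pathway networks over 10 seeds (co-expression), 35-candidate
proteomes over 5 seeds (family), and 500 seeds of 8-line panels (qPCR
recovery) — sizes at which every planted-truth experiment completes in
seconds while keeping hundreds of decision events per run.
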