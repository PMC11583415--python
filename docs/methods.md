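# Methods

`ginet` implements an in-silico genetic-network analysis around a query
gene — typically a tumour suppressor whose loss-of-function (LOF)
alterations are common but not directly druggable — using gene-level
outputs of genome-wide CRISPR knockout screens across cancer cell lines.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Input model

Two lines × genes matrices drive everything:

* **gene effect** — a CERES/Chronos-style fitness score per (cell line,
  knockout); more negative means stronger dependency; entries may be
  missing.
* **lethality probability** — a probability in [0, 1] that the knockout
  is lethal in that line.  The two matrices are treated as independent
  inputs; no transform between them is assumed.

Side tables: MAF-like somatic mutations (`Hugo_Symbol`,
`Variant_Classification`, `Tumor_Sample_Barcode`), discretised gene-level
copy number, and cell-line annotations (disease, subtype, MSI status).

## Genotyping

LOF variant classes are nonsense mutations, frameshift
insertions/deletions, and nonstop mutations; missense and silent variants
are not LOF, and lines carrying *only* such variants are excluded from
both screen arms rather than treated as wild type.  Zygosity is
approximated by alteration counts: one LOF mutation on neutral copy
number is heterozygous; ≥ 2 LOF mutations, or one plus copy-number loss,
is *trans-heterozygous* (two hits, likely protein-deficient).  True
homozygosity is never inferred from DepMap-style data — it enters only
through an explicit flag column.  For patient cohorts (no paired control
arm), a deep copy-number loss alone may count as LOF via
`deep_loss_alone_is_lof`; this cohort convention is off for cell-line
screens.

A cancer context is eligible for a context-specific screen when ≥ 10 % of
cohort samples carry any mutation of the query gene, ≥ 25 % of those
mutations are LOF, and ≥ 10 screened cell lines exist.  All thresholds
are inclusive ("at least").

## Co-essentiality mapping

The query's fitness profile is Pearson-correlated against every screened
gene on the complete-case line set (lines missing either score dropped;
genes left with < 3 usable lines or zero variance are dropped with a
diagnostic).  Significance comes from an empirical pooled null: each of
`n_perm` draws (default 100,000) picks a random gene column, permutes its
values across lines, and correlates it with the query profile; the
two-sided p-value is the add-one fraction of null |r| at or above the
observed |r|, so p ∈ [1/(n_perm+1), 1] and ties in |r| share p.

Coefficients are ranked in descending order and a knee ("inflection
point") is located on each sign segment: the rank maximising the
perpendicular distance between the (rank, r) curve and the chord joining
the segment's endpoints (kneedle-style; ties break to the smallest rank;
a segment needs ≥ 3 values).  A gene is called **co-essential** when
p < α (default 0.05) *and* r is strictly above the positive knee;
**anti-essential** symmetrically below the negative knee.  The knee is a
geometric definition chosen because "inflection point of the ranked
curve" has no canonical computational meaning; on a two-segment
piecewise-linear curve it recovers the constructed vertex exactly.

## Differential-lethality GI screen

Per screened gene, knockout lethality probabilities are compared between
the query-LOF group and wild-type controls with a two-sided Mann–Whitney
U test — exact enumeration when both groups have ≤ 8 values and no ties,
tie-corrected normal approximation with continuity correction otherwise.

Multiplicity is handled by permutation.  The group labels are shuffled
`n_perm` times (default 10,000) over the pooled lines; the default null
statistic per shuffle is the **minimum p across all screened genes**
(Westfall–Young single-step min-p), and

    adj_p(g) = (1 + #{min-p_null ≤ p_obs(g)}) / (1 + n_perm).

This controls the family-wise error over the genome-wide screen, which is
what makes a ~2,000–18,000-gene screen yield a usable candidate list: a
marginal pooled null (one random gene's shuffled p per draw, available as
`strategy='pooled_marginal'`) merely calibrates the per-gene p and would
leave ~5 % of null genes "significant" — hundreds of false candidates per
screen.  A `per_gene` strategy (each gene against its own shuffled null)
is also provided.  All strategies share the add-one formula, are monotone
in the observed p, and are deterministic given the seed.

Candidates with adj p < α are direction-labelled: **SL**
(synthetic-lethal) when the mutant-group median lethality exceeds the
control median, **AL** (alleviating) when below.  The interaction score
summarises strength and direction:

    score = −log10(adj p) × log2(mutant median / control median)

with medians floored at 1e−4 before the ratio (lethality probabilities
can be exactly 0; the floor caps |log2 ratio| at ≈ 13.3).  Equal medians
give exactly 0 regardless of p.

## Prioritisation

GI tiers from screen statistics (all comparisons strict, as printed):

| tier | adj p | abs log2 FC of medians | median condition |
|------|-------|------------------------|------------------|
| I    | < 0.01 | > 2 | max(group medians) > 0.5 |
| II   | < 0.05 | > 2 | max(group medians) > 0.5 |
| III  | < 0.05 | > 2 | none |

"Minimum lethality probability of 0.5 in at least one group" is read as a
condition on the *group medians* (the screen's summary statistic); a
config switch can change this to any-line.  Drug tractability groups come
from the minimal Open-Targets-style bucket: 1–3 → group I (clinical
precedence), 4–6 → II, 7–9 → III; an explicit per-gene override wins and
is logged.  Priority classes: A = (tier I, group I); B = (I, II);
C = (I, III or untracked); D = any tier II/III candidate; no tier → none.

## Enriched-term clustering

Over-representation is the upper-tail hypergeometric test (term sets
intersected with the universe) with Benjamini–Hochberg correction across
terms.  Enriched terms are grouped by similarity: pairwise Jaccard index
J = |A∩B| / |A∪B|, complete-linkage hierarchical clustering on distance
1 − J (1 − J is a metric), and the number of clusters chosen by the gap
statistic: within-cluster dispersion W_k = Σ_r Σ_{i,i'∈r} d_{ii'} / (2 n_r),
Gap(k) = mean_b[log W_k(ref_b)] − log W_k(obs) over `n_boot` reference
collections (default 1,000), se carrying the √(1+1/B) factor.

Two open choices were fixed as follows:

* **Reference scheme** — random gene sets drawn from the collection's own
  universe preserving each term's set size (keeps the null comparable in
  set-size structure).  `gap_statistic_k` accepts any reference generator;
  the default for a bare distance matrix shuffles its off-diagonal
  entries.
* **Selection rule** — `firstSEmax`: the smallest k whose gap is within
  one se of the global gap maximum, as in common `cluster::clusGap`
  workflows.  The original sequential rule (smallest k with
  Gap(k) ≥ Gap(k+1) − se(k+1); available as `rule='tibshirani'`) stops at
  the k = 1 plateau on exactly the structures of interest here: when a
  k−1 cut forces two well-separated term families into one cluster the
  gap dips before peaking at the true k, and the sequential rule never
  sees the peak.  On planted 2–5-family structures the firstSEmax rule
  recovers the true count ≥ 99 % of the time; the sequential rule ~25 %.
  Keep k_max well below the number of terms (the analyses here use
  k_max = 6 with 16–40 terms); as k_max approaches the term count the
  observed dispersion collapses toward zero and the log floor (1e−12)
  distorts the high-k tail of the curve.

## Cohort markers

* **TMB** = somatic mutation count / footprint in Mb.  Whole-genome
  footprint default 2934.876451 Mb; panel studies pass their own exonic
  coverage.
* **MSI** from scores: MSI iff MSIsensor ≥ 10 *and* MANTIS ≥ 0.4
  (inclusive; conjunctive when both present).  With one score missing the
  call falls back to the present score — callers should flag such calls.
  On gene panels, MSI is inferred from any LOF alteration in the
  mismatch-repair genes MLH1, MLH3, PMS2, MSH2, MSH3, MSH6.
* **Cytolytic activity** = √(GZMA × PRF1) FPKM, no pseudocount by default
  (either gene at 0 gives 0; a pseudocount is available but off).
  **M1/M2** and **IFNγ** scores are arithmetic means over their fixed
  10-gene lists; a missing gene is an error naming it, never silently
  dropped.
* **Statistics**: Welch's t per marker with BH across the marker family
  (groups < 3 samples reported not-analysed, never as p-values); one-way
  ANOVA + Tukey HSD beyond two groups; Fisher's exact test with the
  probability-mass two-sided rule (on the 10/0/0/3 sensitivity table this
  gives 1/286 ≈ 0.0035; the sample odds ratio is reported, conditional
  MLE optional); chi-square equality of proportions with Yates correction
  by default; log-rank across survival groups with groups < 10 cases
  dropped as not-analysed.  Survival machinery is limited to log-rank and
  Kaplan–Meier-style inputs; no Cox models.

Standard machinery (Mann–Whitney, Fisher, hypergeometric, Welch/ANOVA/
Tukey, BH, chi-square, log-rank, linkage/dendrogram cutting) is delegated
to scipy, statsmodels and lifelines; the tests check each against
independent brute-force enumeration or hand-computed oracles.

## Synthetic data: what it emulates, what it does not

The generator produces a DepMap-shaped panel with planted, recorded
truth.  Background gene effects are standard normal per gene plus a small
shared line offset (sd 0.1, emulating per-line screen-quality variation);
planted co-essential pairs are built from a shared latent factor so the
population correlation equals the target rho exactly (planted genes skip
the line offset to keep the calibration exact).  Lethality probabilities
are Beta-distributed with concentration 10 around per-gene baseline means
drawn uniformly from [0.05, 0.5]; a planted GI sets the partner's mean to
`lof_mean` in LOF lines and `wt_mean` elsewhere.  LOF lines carry two LOF
mutation records for the query gene (trans-heterozygous under the
genotyping rules); missingness is injected completely at random into the
gene-effect matrix only.  Expression cohorts use log-normal baseline
FPKM, multiplicative planted fold changes, exponential survival with
uniform censoring, and group-separated MSIsensor/MANTIS scores.

Defaults are the study conditions exercised throughout: 200 lines ×
2,000 genes, 40 LOF vs 160 WT lines, planted SL means 0.8 vs 0.2,
planted co-essential rho 0.9, 2 % missingness.

None of these distributional choices is a claim about DepMap: real gene
effects are heavy-tailed and correlated through screen batch and lineage;
real lethality probabilities are bimodal (essential vs non-essential
genes); real mutation tables carry germline leakage and subclonality.
Passing the planted-recovery studies therefore shows the *inference
machinery* is correct and calibrated under the stated model, not that the
thresholds transfer to real DepMap releases.

## Operating characteristics (computed by `analysis/08` and the acceptance script)

At the study conditions, over 100 seeded replicates: planted-SL
sensitivity 1.00 with pooled empirical FDR ≈ 0.05 (1,000 permutations);
null screens (mutated query, no planted effect) flag 0 % of genes at
adj p < 0.05; the planted co-essential partner is recovered in 100 % of
replicates with ~4 % of unplanted genes receiving any call (α = 0.05,
two-sided, knee-thresholded); gap-statistic recovery of planted 2–5 term
families is ≥ 0.99 at 200 bootstrap references.  The recovery studies use
1,000 screen permutations, 2,000 correlation permutations and 200
bootstraps — smaller than the per-run defaults (10,000 / 100,000 / 1,000)
because they repeat the whole pipeline 100 times; the add-one p floors
scale accordingly.

## Determinism and reproducibility

Every stochastic step takes a seed; per-stage seeds derive from the
master seed by hashing (master, stage-name), so adding a stage never
perturbs earlier stages.  Pipeline runs write a manifest with per-stage
seeds and sha256 checksums of every output; identical config + seed gives
byte-identical tables.

## Known limitations

* The min-p adjustment is single-step, not step-down; it is slightly
  conservative for all but the best-ranked gene.
* The knee threshold depends on the raw (rank, r) scale; it is invariant
  for two-segment convex curves but not for arbitrary monotone
  reparameterisations.
* Complete-case correlation can use different line subsets per gene, so
  coefficients are not jointly estimated on one panel.
* The marginal Beta lethality model cannot represent the
  essential/non-essential bimodality of real screens; effect sizes
  planted on the mean scale do not map directly onto real DepMap effect
  sizes.
* Panel MSI inference ignores epigenetic MMR silencing (e.g. MLH1
  promoter methylation), which real cohorts require expression data to
  catch.
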