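# Methods

## The similarity model

For a disease gene list D and an ordered collection of n functional
gene sets over a universe U, the semantic profile of D is the vector of
one-sided Fisher exact p-values

    p_i = P(X >= k_i),   X ~ Hypergeometric(|U|, |S_i|, |D|),
    k_i = |D ∩ S_i|,     i = 1 … n,

i.e. the upper hypergeometric tail of the 2×2 in-list/in-set table. Only
over-representation is tested: a two-sided test would reward depletion,
which carries no evidence that two diseases engage the same biology.
Disease genes outside U are removed before testing because they cannot
appear in any margin of the table.

The comorbidity score of a pair (A, B) is the Pearson correlation of
the two transformed profiles built on the *same* collection, so index i
always refers to the same functional set. Three monotone transforms are
supported and the choice is recorded in every output:

- `exp` (default): elementwise e^p. The default follows the convention
  of exponentiating the p-value vector before correlating.
- `identity`: raw p.
- `neglog10`: −log10(max(p, 1e−320)), the usual significance scale;
  recommended when p-values span hundreds of orders of magnitude, as
  they do for large disease gene lists, because on the raw or exp scale
  all strongly enriched sets collapse onto the same endpoint.

All three transforms are strictly monotone, so they leave the rank
order of a single profile unchanged; they differ in how they weight the
extremes, which is exactly what a linear correlation is sensitive to.
The correlation is undefined for a constant profile (a disease hitting
nothing, or everything, identically); the score is then defined as 0
with a `zero_variance` flag rather than NaN, because a ranking pipeline
over thousands of pairs needs a total order and a flat profile carries
no similarity evidence either way.

No multiple-testing correction is applied inside profiles: the score
consumes the raw p-value vector. Bonferroni corrections appear only
where a binary significance decision is made (comorbidity labels,
core-subset significance marks), with the threshold alpha/m over the m
tests actually performed.

### Numerical handling of extreme p-values

The hypergeometric tail is evaluated by `scipy.stats.hypergeom.sf`,
which works in log space internally; the reported p is clamped to
[1e−320, 1]. The floor prevents exact zeros (which would break the
neglog10 transform) while staying far below any plausible decision
threshold.

## Benchmark measures

Jaccard index |A∩B|/|A∪B| and overlap coefficient |A∩B|/min(|A|,|B|)
operate on raw gene sets. Both raise on an empty input set.

Network separation on a PPI graph follows the
distance-to-nearest-counterpart convention:

    d_AB = mean over all mapped genes g of both sets of the shortest
           hop distance from g to the nearest mapped gene of the other
           set (0 if g belongs to both sets),
    d_AA, d_BB = the same within one set, excluding g itself; a
           singleton set has within-distance 0,
    s_ab = d_AB − (d_AA + d_BB) / 2.

Negative s_ab means the two disease modules interpenetrate on the
network. Genes absent from the graph, or unreachable from every
relevant counterpart (disconnected components), are dropped from the
corresponding mean and reported as counts instead of being assigned an
infinite distance; this keeps s_ab finite and mirrors the common
practice of working on the network's giant component.

## Core gene-set extraction

Given the two transformed profiles x = f(P_A), y = f(P_B), the paired
points (x_i, y_i) are modelled as a two-component mixture of Gaussian
linear regressions, fit by EM:

- E-step: responsibilities proportional to
  π_k · N(y_i; β0_k + β1_k x_i, σ²_k).
- M-step: responsibility-weighted least squares per component,
  responsibility-weighted variance update with a floor of 1e−10 to
  prevent component collapse, mixing weights = mean responsibilities.
- Initialisation: per-point responsibilities drawn from a symmetric
  Dirichlet(1, 1); 5 restarts, best log-likelihood kept. Mixture
  regressions are multimodal and a cheap random-responsibility start
  with restarts is the standard remedy.
- Convergence: |Δ log-likelihood| < 1e−6 or 500 iterations. The
  log-likelihood trace is stored and is non-decreasing within a run (EM
  guarantee; tested to 1e−9).

The number of components is fixed at two — a "core" of functional sets
whose paired p-values co-vary tightly, versus everything else — and no
model selection over k is attempted. If the input is exactly collinear
a mixture is unidentifiable; the fit falls back to a single line with
every point in component 0 and a `degenerate` flag.

The core is the component whose members give the larger
within-component Pearson correlation; a component with fewer than 3
members cannot carry a correlation and automatically loses (flagged).
By this argmax construction core similarity ≥ rest similarity on every
run. Core members are additionally labelled by whether either disease's
raw p-value passes Bonferroni alpha/n.

Orientation: the mixture regresses y on x, i.e. disease B on disease A,
and is not exactly symmetric under swapping the pair. The fitting
orientation is recorded in the CLI metadata, and `--symmetrize` fits
both orientations and intersects the two cores. The default is the
single A-on-x orientation. The recommended input scale for extraction
is `neglog10` (see above); the transform tag is recorded.

## Split-simulation validation

If the score captures shared biology, splitting one disease's gene list
into two disjoint parts must produce two pseudo-diseases that profile
alike, while splitting an equally sized uniform random draw from the
universe must not. For each split ratio r ∈ {0.3, 0.35, 0.4, 0.45, 0.5}
(parts of size round(r·m) and m − round(r·m)) and each replicate, both
settings are scored, and replicate i of the real setting is paired with
replicate i of the null at the same ratio; a two-sided paired t-test
summarises the contrast. The default is 200 replicates per ratio; the
test suite runs 20 per ratio, which is already decisive on planted-
coherence inputs. All randomness flows from one seeded generator, so a
config + seed reproduces the result bit for bit.

A caveat established while validating the null: when the "disease" is
itself one *fixed* random gene draw, its idiosyncratic profile is
inherited by both halves in every replicate, so real-split scores are
mutually correlated and the paired t-test is anticonservative — it can
flag a fixed random set in either direction. The correct null statement
is exchangeability: when the random parent is redrawn each replicate,
the real-split and null-split processes coincide and the test fires at
its nominal rate. The test suite asserts that form.

## Relative-risk gold standards and evaluation

From a binary sample × disease diagnosis matrix, the 2×2 table of a
pair (A, B) gives RR = P(B|A=1)/P(B|A=0), a Wald 95% CI
exp(ln RR ± 1.96·SE) with SE² = 1/a − 1/(a+b) + 1/c − 1/(c+d), and a
Pearson chi-square p-value without continuity correction. A zero
outcome count in either arm adds 0.5 to all four cells for the RR and
CI only (flagged); the chi-square always uses raw counts. A pair is
labelled comorbid at threshold t ∈ {1, 5, 10} when p ≤ alpha/M
(Bonferroni over the M tested pairs, non-strict — boundary cases are
measure-zero) and RR > t (strict).

AUC is the rank-based Mann–Whitney statistic with average ranks, so
ties contribute half credit; it satisfies AUC(s) + AUC(−s) = 1 exactly
and is checked against an O(n²) pair-enumeration oracle. Measure
combination fits an unregularised maximum-likelihood logistic model per
candidate measure subset (missing scores set to 0) and selects the
subset with the highest AUC of the fitted linear predictor, evaluated
in-sample on the same pairs; this matches the combination protocol
being emulated, and no cross-validation is applied by default. Note
that best-of-subsets in-sample selection is optimistic under the null —
only single-model AUCs should be read as unbiased. Under perfect
separation the ML estimate diverges; the model is flagged and scored by
the standardized class-mean-difference direction, which reproduces the
separating ranking.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *statistical structure* the pipeline
consumes, not any real database:

- Functional collections: `n_functional_sets` = 50 sets of 150–300
  genes sampled independently from a 5,000-gene universe. Defaults are
  sized so that every pair design is feasible (two gene-disjoint
  diseases must fit inside their shared driver pool) while ORA profiles
  stay cheap; real GO-style collections are larger, hierarchical, and
  heavily nested, none of which is modelled.
- Diseases: 30–300 genes (the typical spread of curated disease gene
  sets), drawn from `n_driver_sets` = 5 driver functional sets plus a
  `background_fraction` = 0.2 of universe noise. Pair designs:
  `shared_drivers_overlapping_genes` (same drivers, planted gene
  sharing), `shared_drivers_disjoint_genes` (same drivers, disjoint
  genes — comorbidity invisible to overlap measures), and `independent`
  (disjoint drivers; the second disease also avoids the first's literal
  genes, so overlap scores are exactly 0 and the no-overlap benchmark
  stratum is clean).
- Cohorts: per pair, disease A ~ Bernoulli(p_a) and B given A with
  P(B|A=0) = q = p_b/(p_a·r + 1 − p_a) and P(B|A=1) = r·q, which plants
  relative risk r while honouring B's marginal prevalence p_b exactly;
  prevalences are drawn from 0.05–0.15 per disease, default r = 5,
  n = 50,000 samples. Real claims data have correlated comorbidity
  networks, age/sex structure, and coding noise; none is modelled.

Consequently, passing tests demonstrate that the implementation is
correct and that the score behaves as designed *when the planted
functional-coherence assumption holds*; they say nothing about how
strongly that assumption holds in any real disease-gene resource.

## Reference quantities

`scripts/acceptance.py` recomputes, from scratch at run time: the
Bonferroni thresholds 0.05/3828 and 0.05/7658, and the Jaccard AUC on a
freshly generated 60-pair gene-disjoint benchmark (20 comorbid), where
every Jaccard score is 0 and the rank AUC is therefore exactly 0.5. The
benchmark seed derives from `--seed`; the threshold arithmetic is
deterministic.

## Known limitations

- GS.sim inherits Pearson's sensitivity to extreme values; on the exp
  or identity scale a handful of near-zero p-values dominate, on the
  neglog10 scale the largest exponents do. There is no single right
  scale; the transform tag keeps results comparable.
- The EM extractor finds a local optimum per restart; 5 restarts are
  usually enough on well-separated structure but pathological inputs
  may need more (`n_restarts`).
- Network separation depends on the completeness of the input PPI
  network; dropped/unreachable gene counts should be inspected before
  interpreting s_ab.
- The universe defaults to the union of the functional collection's
  genes. An explicit, larger universe (all protein-coding genes) makes
  every ORA p-value smaller; comparisons are only meaningful within one
  universe policy, which is why the policy is recorded in CLI metadata.
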