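# Methods

This note documents the statistical models implemented in emslink, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducibility.

## The association problem in indexed EMS populations

An EMS population is a set of mutant lines derived from one reference
background, each carrying thousands of independent point mutations. Two
properties set it apart from natural diversity panels: there is essentially
no population structure (no kinship correction is applied anywhere in the
toolkit, deliberately), and per-site minor allele frequencies are far too
low for site-level association. The toolkit therefore works at the gene
level throughout: the unit of association is "line carries ≥1 (or a
weighted burden of) mutation(s) in gene g".

## Genotype filtering

**Quality floor.** Records with QUAL < 50 or depth < 5 are removed;
missing values fail the filter. Both cutoffs are conventional
variant-calling floors and are exposed as parameters.

**Site-sharing null.** Because all lines share one reference background, a
site carried by many lines is more plausibly a systematic artifact than a
recurrent EMS hit. The null model asks: if each line's mutations were
placed uniformly at random over the site catalogue (preserving each line's
mutation count), how large could per-site carrier frequencies get? Each
permutation reshuffles all lines, recomputes per-site frequencies and keeps
one upper-tail summary — the `per_perm_tail`-th largest frequency (default
500, i.e. the smallest value inside the retained extreme block of 500
sites). The cutoff is the `rank`-th largest summary over `n_perm`
permutations (defaults rank 5, 1000 permutations, an empirical tail level
of 5/1000). Both knobs are parameters rather than constants because
reasonable variants of "the extreme block" exist; the defaults reproduce a
~0.7% cutoff at full population scale (1839 lines). Filtering is strictly
greater-than: a site exactly at the cutoff survives. Site identity is
(chrom, pos, alt), 1-based per VCF convention.

**Annotation.** Gene and impact come from a SnpEff-style `ANN` INFO field;
when a variant carries several annotations the most severe impact is kept
(HIGH > MODERATE > LOW > MODIFIER), the usual burden-test convention.

## Gene burden matrices

Three gene × line matrices are built in one pass: raw counts, 0/1
presence, and the impact-weighted burden Σe. The impact weights are a
modelling choice — annotation tools emit classes, not numbers — with
defaults HIGH = 1.0, MODERATE = 0.66, LOW = 0.33, MODIFIER = 0.1: a simple
decreasing ladder over the expected functional consequence, fully
configurable and recomputable after aggregation (the per-impact count
matrices are retained). The burden sums over all of a line's mutations in
the gene with no cap. Mutations outside any gene are excluded from the
matrices and counted in the log.

## Dual-pathway association

**Deviant split (reverse pathway).** Lines are deviant when
|y − center|/σ ≥ z. The center is the mutant-population mean by default
(the wild-type mean is available), σ is always the mutant-population SD,
and z defaults to 1.5 — chosen so that both groups stay non-trivially
populated at EMS-typical effect sizes; it is exposed as `--z-threshold`.
A constant trait yields an empty deviant set with a warning (or all lines
at z = 0).

**Enrichment statistic.** The literal one-cell form
χ² = (Obs − Exp)²/Exp (Obs = deviant carriers, Exp = independence
expectation n_dev·carriers/n) is implemented exactly as written, but has no
calibrated null; the default is therefore the standard 1-df 2×2
contingency χ² over carrier × deviant, computed without continuity
correction. Genes with zero expectation or a degenerate margin are skipped
and flagged. P-values come from the χ²(1) law.

**Burden regression (forward pathway).** Per gene, OLS of the trait on the
per-line predictor (weighted burden by default; raw count and 0/1 presence
available) with intercept, and a two-sided t-test on the slope (df n − 2).
The implementation is a vectorized closed form over all genes at once;
tests pin it against statsmodels to 1e-8. Zero-variance predictors are
skipped and flagged. Wild-type reference rows are excluded from both
pathways.

**Permutation threshold.** Trait values (regression) or deviant labels
(enrichment) are permuted across lines; per permutation the most extreme
per-gene statistic (|t| or χ²) is recorded, and the threshold is the k-th
largest of the n_perm maxima with k = ⌊α(n_perm + 1)⌋. Under
exchangeability the probability that the observed maximum exceeds this
order statistic is k/(n_perm + 1) ≈ α exactly, which is why an order
statistic is used rather than an interpolated quantile. Per-gene pointwise
null quantiles are available behind a flag. A constant phenotype returns an
infinite threshold with a warning.

**Candidates.** Genes are ranked per pathway by p ascending, ties broken
lexicographically by gene id; the candidate set is (top-K of pathway 1) ∩
(top-K of pathway 2), then filtered to genes whose statistics strictly
exceed both permutation thresholds — selection first, threshold filter
second. K defaults to 300 and is clipped with a warning when it exceeds
the number of tested genes. Traits are analysed independently, with no
cross-trait multiplicity correction. Candidates can be ranked by their
peak FPKM over named tissues; genes missing from the expression matrix are
retained and flagged rather than silently dropped.

## Spikelet-trajectory geometry

Each line's ordered spikelet values are mapped by rank onto [0, 20]
(spikelet i of n → 20(i−1)/(n−1)), fitted with a degree-4 polynomial by
least squares (exact interpolation at 5 points; <5 spikelets excludes the
line), evaluated at the 21 integer nodes, and averaged over the fixed
region grouping 3/8/8/2 (bottom, lower-middle, upper-middle, top). The
region sizes are constants with an override flag: the grouping reflects
where trajectory variance concentrates, but no recomputation rule is
defined, so the sizes are not data-dependent.

I/N/D typing compares each region mean with the population's **per-region**
mean: I above, D below, N within a ±2.5% relative band ("approximately
equal" needs a tolerance; 2.5% is the default and configurable; a
whole-spike population mean can be passed explicitly instead). A zero
population mean degrades the relative band, so the comparison falls back to
an absolute band of the same numeric width, logged. The code space is
3⁴ = 81. Typing is monotone: raising a region mean can only move its
letter along D → N → I.

Profile clustering uses Ward linkage on the Euclidean distance between
21-node vectors — chosen for determinism, since no particular algorithm is
canonical for this step.

## Epistasis scan and network

For each ordered-normalized pair of eligible genes (≥5 carriers each; the
floor avoids near-empty interaction cells) the full model
y = β₀ + β₁gᵢ + β₂gⱼ + β₃gᵢgⱼ is fitted by OLS on the presence encoding and
the two-sided t-test on β₃ is reported (df n − 4). Rank-deficient or
constant-interaction designs are skipped and flagged; a perfect fit
reports p = 0. The statistic is the full-design interaction t rather than a
correlation shortcut, so it is exactly testable against an independent
solver.

Per trait the `top_n` (default 1000) smallest-p pairs are kept, ties broken
by lexicographic pair id. Multi-trait networks merge parallel edges for
topology but keep the supporting trait list and the best p on each edge.
Degree counts incident merged edges; betweenness is standard normalized
shortest-path betweenness. Node-removal trajectories record the average
degree (2E/N) after each deletion: `hub` deletes the current max-degree
node (lexicographic tie-break), `candidate` a random candidate-flagged
node, `random` a uniform node.

## Synthetic-data generator

The generator's defaults are the study conditions of a wheat-scale indexed
EMS library: mean 4072 mutations per line (Poisson — only the mean is
known, so Poisson is this package's choice; a fixed-count mode exists for
exact tests), transition fraction 0.889, and an impact mixture with
MODERATE = 0.597 and the remaining mass split evenly over HIGH, LOW and
MODIFIER. Desk-scale experiments override the catalogue size and
per-line mean; e.g. 26 mutations per line over a 1000-gene × 10-site
catalogue reproduces the ~2.6% mean gene-level mutation frequency.

Sites are placed without replacement within each gene's span, and ref/alt
and impact are fixed per site at catalogue level (two lines hitting the
same site must agree on the allele, as a VCF requires); cross-gene position
collisions are resolved by redraw. Phenotypes follow
y = baseline + Σ effect·burden + Σ ε·presence·presence + N(0, σ²), with
wild-type rows (zero mutations by construction) appended. Spikelet tables
draw per-line values from 21-node template trajectories by linear
interpolation plus Gaussian noise.

What the generator does **not** emulate: recombination and selection,
chromatin-context mutation bias, heteroscedastic or non-Gaussian phenotype
noise, shared environmental structure, genotyping error, and any
correlation between impact class and effect size. Passing tests therefore
demonstrate the statistical machinery under idealized EMS-like sparsity,
not robustness to every artifact of real exome-capture data.

## Validation experiment sizes

The experiments in `emslink.validation` (run by the test suite and
`scripts/acceptance.py`) use desk-scale populations chosen as the package's
own benchmark conditions:

* composition fidelity: ~9×10⁴ distinct sites (60 lines × ~4000 mutations);
* null calibration: one 300-line × 1000-gene population at gene frequency
  ≈0.03, 100 pure-noise traits, 200 permutations each;
* planted recovery: 500 lines, 400 genes, 10 causal genes at frequency
  ≈0.03 with effects ±2.0 units against noise SD 0.2 — about 1.8
  population SDs per mutation. The sign-balanced effects keep the
  population mean at baseline, and the low-noise regime reflects the
  strong, near-Mendelian effects EMS screens are designed to surface; a
  prior power analysis shows the 1.5-SD deviant split cannot be cleared
  family-wise by carriers whose shift is much below ~1.5 population SDs,
  so weak-effect recovery is a known limitation of the reverse pathway,
  not of the implementation;
* planted epistasis: 48 genes at presence frequency ≈0.3 (1128 pairs),
  one pure interaction of ≈1.5 trait SDs — presence frequencies far below
  ~0.1 leave double-carrier cells empty at these sample sizes, which is an
  intrinsic power boundary of pairwise epistasis scans;
* network robustness: 50 preferential-attachment graphs (60 nodes,
  attachment 2), 30 removal steps.

## Known limitations

* The literal one-cell χ² has no proper null distribution; it is provided
  for fidelity, with the contingency form as the calibrated default.
* The enrichment pathway's χ² is discrete at small carrier counts; its
  permutation threshold is slightly conservative there.
* Multi-allelic VCF records contribute only their first alternate allele.
* No kinship/structure correction: appropriate for EMS panels, wrong for
  natural populations.
* Expression-based prioritization is a filter-and-rank on FPKM, not a
  differential-expression model.
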