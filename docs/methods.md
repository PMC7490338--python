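# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## Differential expression

Per dataset, case-vs-control differences on log2-scale matrices are tested
with an empirical-Bayes moderated t-statistic. The hierarchical model treats
the per-feature residual variances s²_g (each with d_g = n₁+n₂−2 degrees of
freedom) as draws from a scaled inverse-chi-square prior with hyperparameters
(d0, s0²). These are estimated by the method of moments on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of Var(e_g) over
ψ′(d_g/2) identifies ψ′(d0/2), inverted by bisection on the trigamma
function to a tolerance of 1e−8; the mean of e_g then gives s0². When the
excess variance is non-positive, d0 is infinite and all features share s0²
(the statistic becomes z-like). Features with zero sample variance are
excluded from the hyperparameter fit but still shrunk. The implementation
reproduces the reference empirical-Bayes implementation (limma `eBayes`,
used as a frozen independent oracle in the test suite) to ~1e−9 on both t
and p.

Forcing `prior_df=0` recovers the ordinary pooled-variance t-test exactly —
this limit is part of the test contract. DEG calling uses raw p-values by
default (reproducing the typical workflow this package supports);
Benjamini–Hochberg adjustment is available behind a flag. The fold-change
cutoff is applied on the log2 scale, |log2FC| ≥ log2(1.5), with the p-value
bound strict (p < 0.05, so p = 0.05 exactly is excluded); features with
|log2FC| ≥ 1 are tracked as the stricter 2-fold subset.

## Permutation-stability correlation

The central methodological problem: miRNA and mRNA expression come from
different cohorts with unequal group sizes, so no sample pairing exists and
a single Pearson coefficient is undefined. The procedure makes the pairing
explicit and random:

* i = the minimum of the four group sizes (miRNA case/control, mRNA
  case/control). With the default study layout (miRNA 8 vs 4, mRNA 9 vs 13)
  i = 4, giving 2i = 8 pooled points per run.
* Each of n_runs = 1,000 runs draws i case and i control samples without
  replacement, independently from the two datasets, and pairs them by draw
  order within group. Pearson's r is computed on the pooled case+control
  points (pooling captures condition-driven covariation; a within-group
  variant is available for sensitivity analysis), with a two-sided p-value
  from the exact t-transform t = r·√((2i−2)/(1−r²)).
* The *stability* of a pair is the fraction of runs significant at
  α = 0.01 whose sign agrees with the majority sign among significant runs.
  Pairs pass at stability ≥ 0.95 (inclusive) and, for repression edges, must
  be negative. Counting sign-flipping runs as support would be incoherent
  with the repression interpretation, so sign consistency is built into the
  stability fraction.

Because the pairing is random, each run measures association between the
*group structures* of the two features; within-group covariation cannot
contribute. The stability fraction is therefore a measure of pairing-robust,
condition-driven association — this is deliberate and is what makes the
statistic well-defined for unpaired cohorts, but users should be aware it is
not a substitute for a paired-sample correlation.

Randomness discipline: every (miRNA, mRNA) pair derives its own PCG64
substream from the user seed plus a SHA-256 hash of the two feature ids, so
results are independent of evaluation order and of which other pairs are
evaluated.

Calibration (recomputed by `scripts/acceptance.py`): on 500 independent null
pairs at the default group sizes, no pair reaches stability 0.95
(empirical false-acceptance rate < 0.5%).

## Target integration

miRNA→mRNA catalog records are kept when experimentally validated OR
predicted by at least 4 of the 11 declared prediction methods. lncRNA→miRNA
and lncRNA→mRNA records come from experimentally supported interaction
databases and bypass the method-count rule; all lncRNA records are filtered
only by membership of their target in the relevant DEG/DEM set, with
database provenance retained as a union across sources. Duplicate catalog
rows merge as validated = OR, n_methods = max, databases = union.

Catalog support and stability-selected pairs are intersected per condition,
yielding per-miRNA counts |Target|, |PCC| and |Target ∩ PCC|. When the two
contrasts are merged, a miRNA→mRNA edge must be dual-supported *within* a
condition to count there, and the tag "both" means dual support under both
contrasts — support is never pooled across conditions before the test, which
would let a correlation seen only under one contrast validate a catalog
record from the other.

## TF binding-site prediction

Position frequency matrices are converted to log2-odds with a proportional
pseudocount: p_bj = (c_bj + w·bg_b·C_j)/(C_j(1+w)), w = 0.01, scored in
bits against the promoter-wide background composition. Promoters span
[TSS−2000, TSS+500) on the gene's strand (0-based half-open, minus-strand
sequences reverse-complemented on input; coordinates follow the BED
convention throughout). Scanning covers every offset on both strands; any
window containing an N scores −∞ and can never be a site.

Significance is empirical: M ≥ 10⁵ null scores from i.i.d. background
sequences of motif length, p = (#null ≥ score + 1)/(M+1). The i.i.d. null
(rather than promoter shuffling) was chosen because it admits an exact
enumeration oracle — for motif length 4 the empirical tail is verified
against all 256 words. The site cutoff defaults to p ≤ 1e−4, a conventional
motif-scan operating point (the minimum attainable p at M = 10⁵ is 1e−5);
it is configurable. Conservation enters as a per-base track in [0,1]
(phastCons-like); a site must have mean conservation ≥ 0.5 over its span,
and genes without a track pass with a warning. A gene is a TF target if at
least one surviving site passes the cutoff; overlapping sites are not
merged since target assignment is existential.

## Overlap enrichment

For target sets A, B in a universe of N genes the enrichment p-value is the
inclusive upper tail P(K ≥ k) of the hypergeometric distribution, computed
in log space (exact to < 1e−12 against rational arithmetic for N ≤ 25 — the
point mass alone is not a significance level). The universe defaults to the
union of features measured in the relevant contrast, the least
anti-conservative choice when no universe is stated; it can be overridden.
Raw p-values are starred at 10⁻²/10⁻⁴/10⁻⁶; no multiple-testing correction
is applied to the pairwise matrix by default (BH is available).

## ceRNA detection

An mRNA is a ceRNA candidate when ≥ 2 miRNAs repress it — each with dual
(catalog + negative stability-selected correlation) support — and the
intersection of those miRNAs' lncRNA-sponge sets is non-empty. Intersection
(a lncRNA must sponge *every* shared miRNA) is the default because it
matches the shared-pool reading; a union mode is available. Condition scope
defaults to the established-disease contrast and is configurable. Output
order is deterministic and independent of input edge order.

## Synthetic-data generator

The generator emulates the study *structure*, not microarray physics:

* log2 expression is Normal(μ_feature, noise_sd = 0.3), μ drawn uniformly
  per feature (miRNAs 6–10, genes 6–12);
* three datasets with the study's unequal group sizes (mRNA-EDN 4 vs 4,
  mRNA-DN 9 vs 13, miRNA-DN 8 vs 4); miRNA and mRNA matrices are generated
  from one latent subject pool per condition and expose **disjoint** subject
  subsets, reproducing the unpaired-cohort problem while keeping a
  well-defined population pooled correlation for planted pairs;
* DE genes (10% by default) get a ±1.5 log2 case shift; repressing miRNAs
  get a +3.0 log2 case shift and each planted target is
  baseline − β·(miRNA value) + noise with β = 1.0. These defaults place the
  population pooled correlation of a planted pair near −0.9 (median
  per-run r ≈ −0.96); they were chosen so that the planted effect is strong
  (clear repression) yet finite-sample per-run power at 2i = 8 points still
  matters. A fifth of the planted edges share targets between two miRNAs to
  create ceRNA structure, and two hub lncRNAs sponge every repressing miRNA;
* the catalog contains every planted edge (validated) plus 3× decoys
  (unvalidated, < 4 methods) so the evidence filter is load-bearing;
* promoters are uniform-random sequence with consensus motif instances
  planted at random positions and strands (P(minus) = 0.5), conservation
  0.9 over planted sites vs 0.2 background.

What passing tests on this generator show: the statistics are calibrated
under the stated model, planted structure is recovered through the full
pipeline, and every filter excludes what it should. What they do not show:
robustness to batch effects, platform biases, non-Gaussian intensity
distributions, probe-level artifacts, or correlated background genes — none
of which the generator attempts to mimic.

## Numerical and engineering choices

* Trigamma inversion by bisection (tol 1e−8); hypergeometric terms summed
  from the largest log-term for stability; Pearson r clipped to [−1, 1]
  against rounding.
* Degenerate inputs: features identical across groups give t = 0, p = 1;
  constant vectors are a "zero variance" error in the correlation; runs with
  a constant subsample are counted as non-significant; fewer than 2 features
  falls back to the ordinary t-test with a warning.
* All randomness flows from `np.random.default_rng` (PCG64) seeds; the
  pipeline manifest records the seed, a config hash and per-file SHA-256s,
  and identical config + seed reproduces outputs byte-for-byte.
* Problem sizes in the test suite and acceptance script (e.g. 300–400 genes,
  1,000 permutation runs, 10⁵ PWM null samples, N ≤ 25 enumeration) are the
  smallest at which each property is meaningfully exercised at its stated
  tolerance; they complete in seconds on one CPU.

## Known limitations

* The stability statistic detects condition-driven covariation only; a
  miRNA–mRNA pair both differential in the same direction for unrelated
  reasons can pass (the catalog requirement exists precisely to temper
  this).
* Feature identifiers are matched verbatim (case-sensitive, no miRNA name
  normalization); harmonizing `miR-21` vs `miR-21-5p` across sources is the
  caller's responsibility, since silent normalization would create false
  joins.
* Probe-to-gene collapsing, normalization and batch correction are out of
  scope; input matrices are assumed normalized and gene-level.
* TF→lncRNA edges appear only when lncRNA promoters are supplied and
  scanned; otherwise the TF layer connects to mRNAs only.
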