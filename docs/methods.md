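# Methods

This note documents the statistical models and procedures implemented in
`lncmeth`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Coordinates, promoters, and probe handling

All intervals are stored 0-based half-open; GTF input (1-based inclusive) is
converted on ingest. The promoter of a gene is the window
`[TSS − 2000, TSS + 2000)` clipped to the chromosome, where the TSS is the
annotated gene start on the `+` strand and the annotated end on the `−`
strand — the analysis operates at gene level, so no per-transcript TSS
choice arises. A probe belongs to a promoter when its position lies in the
half-open interval; a probe inside two overlapping promoters counts for
both genes, mirroring the fact that lncRNA and protein-coding promoters are
mapped independently.

Probe exclusion (chrX/Y, SNP overlap, non-unique mapping, absence from the
EPIC array) is driven by manifest flags rather than recomputed from dbSNP or
alignment: recomputation would need external databases and is out of scope
for a reusable pipeline that accepts any pre-flagged manifest. A probe with
several flags is removed once and counted under each flag in the filter
report.

## Promoter summarization and categorization

Promoter methylation of gene *g* in sample *s* is the arithmetic mean of the
non-missing betas of *g*'s mapped probes. Categorization uses strict
inequalities throughout: *hyper* requires beta > 0.7 in **more than** 80% of
non-missing samples, *hypo* beta < 0.3 in more than 80%, everything else is
*inter*. "More than" is read literally (a gene at exactly 80% is inter), and
denominators count non-missing samples per gene so dropout does not bias
the fractions. Genes with no observed sample are reported separately as
unclassifiable. Hyper and hypo are mutually exclusive by construction
(the two sample fractions cannot both exceed 0.8).

## Sequence features

GC content is (G+C)/(non-N bases). The CpG observed/expected ratio uses the
classic convention: observed = CG dinucleotides over an overlapping scan
divided by L−1; expected = (GC/2)². The denominator L−1 is the standard
choice for overlapping dinucleotide windows. When GC = 0 the ratio is
undefined and reported missing. Note a non-obvious consequence: diluting a
sequence with AT *raises* the O/E ratio (the expected fraction falls
quadratically while the observed falls only linearly in 1/L); the closed
form for "CG" + "AT"·k is 4(1+k)²/(1+2k). Category comparisons use
Kolmogorov–Smirnov for distribution-shaped features (GC, normalized CpG)
and Wilcoxon rank-sum for counts and scores (CpG count, exon count,
conservation), with exact enumeration when both groups have n ≤ 20 and the
normal approximation with continuity correction otherwise.

## Consensus clustering

Per-probe standard deviation (ddof 1, non-missing samples) ranks probes;
the top `ceil(0.05 · P)` are retained, with boundary ties broken by probe-id
lexicographic order so selection is deterministic, and the realized SD
cutoff is logged. Clustering then runs 50 resampling iterations per k: 80%
of samples drawn without replacement (samples only, not features) and
partitioned by k-means. The "1 − Pearson" distance is implemented by
z-scoring each sample across features, under which squared Euclidean
distance is proportional to 1 − r; this keeps the well-tested k-means
machinery while honoring the correlation geometry. Consensus(i, j) is the
co-clustered count divided by the co-sampled count; the final partition at
each k is an average-linkage hierarchical cut of 1 − consensus, and k is
chosen by minimizing PAC — the fraction of off-diagonal consensus entries
strictly inside (0.1, 0.9). These defaults (base clusterer, distance,
k-selection rule, linkage) are configurable; they were fixed once as
standard consensus-clustering practice, since the clustering package the
procedure is modeled on leaves them unspecified. At desk scale the k range
defaults to 2–10 (2–8 in the pipeline) rather than the 2–60 of a
2,000-sample cohort.

## Deconvolution

A bulk profile y is modeled as y ≈ S·w with S the probes × cell-types
signature matrix (full column rank enforced) and w ≥ 0. The default solver
is NNLS on raw betas; the alternative is a linear nu-SVR (nu ∈
{0.25, 0.5, 0.75}, best by reconstruction RMSE, negative coefficients
clipped), with profile and signature standardized before fitting as the
CIBERSORT convention dictates. NNLS is the default because it is
transparent, convex, and its planted-mixture recovery is directly testable;
the nu-SVR route exists for users wanting the CIBERSORT-style estimator.
Either way coefficients are renormalized to sum to one (clip-then-normalize,
fixed order), so fractions are relative abundances. At least 80% of
signature probes must be present; missing probes are dropped pairwise.
Significance uses an empirical null: the profile's values are permuted
across probes, the fit correlation recomputed, and
p = (1 + #{null ≥ observed}) / (n_perm + 1) with n_perm = 100 by default, so
the smallest attainable p is 1/101. No quantile normalization is applied at
any point. Signature scores (checkpoints, CYT, HLA, IFN, TILs, and similar
probe sets supplied as tables) are plain per-sample means over each set's
present probes.

## Association calling and multiple testing

Within each cluster holding at least 10 samples, Spearman's ρ (average
ranks) is computed between every lncRNA's promoter methylation and every
cell-type fraction; p-values use the t approximation with n − 2 df.
Adjustment is Benjamini–Hochberg applied across lncRNAs **within each
(cluster × cell type) stratum** — the reporting unit of the analysis —
with Bonferroni available as an option. A call requires |ρ| > 0.3 *and*
adjusted p < 0.05; both conditions are conjunctive, so a tiny p cannot
rescue a weak correlation. Constant columns yield records with missing ρ
and are never called. Enrichment of methylation categories among called
lncRNAs is Fisher's exact test on the 2×2 membership table (the enrichment
test is a design choice; the underlying analysis names none).

Pathway assignment is genomic proximity: a called lncRNA linked to any
protein-coding gene whose interval hull lies within 10 kb (gap 0 when
overlapping; strict — a gap of 10,001 is out) inherits that gene's
immune-pathway memberships, and a lncRNA's pathway count is the union over
its links. Hull-gap distance is the default because "within 10 kb" reads
most naturally as interval proximity; a TSS-to-TSS mode is available.

Differential methylation is a one-vs-rest Welch t-test per (cluster, gene)
with Δ = mean(cluster) − mean(rest); Welch because cluster sizes and
variances differ grossly in this design. Calls require |Δ| > 0.2 and **raw**
p < 0.05 — the call asymmetry with the adjusted-p association rule is
deliberate and mirrors how such analyses are conventionally reported.

## Survival

The maximally selected cutpoint scans every threshold between consecutive
distinct marker values that leaves at least 10% of samples on each side
(the documented default of the R `surv_cutpoint` convention this
re-specifies) and maximizes the standardized two-group log-rank statistic
|O − E|/√V. Ties are broken toward the more balanced split, then toward the
smaller cutpoint; the statistic is rounded to 9 decimals before comparison
so exact statistical ties are not broken by floating-point noise. The
reported p is the naive log-rank p of the chosen split, as Kaplan–Meier
panels conventionally show; an optional permutation-corrected p (recompute
the maximal statistic on permuted markers) quantifies the optimism of
cutpoint selection.

Cox models are fit by partial-likelihood maximization with Efron tie
handling via lifelines — a mature, well-tested implementation of exactly
this estimator; re-deriving the Newton iteration by hand would add risk
without adding content. Nested tiers (age + sex ⊂ + WHO category ⊂ +
methylation cluster) are dummy-coded drop-first; exactly duplicated or
zero-variance design columns are removed so a redundant covariate
contributes ΔLR = 0 instead of a singular fit. Each increment is
ΔLR = 2(ℓ_larger − ℓ_smaller) with a χ² p on the added parameter count;
non-convergence and separation (a level with no events) are reported per
tier, not raised.

## Synthetic cohorts

The generator plants everything downstream stages are asked to recover.

* **Noise model.** Probe betas follow Beta(μφ, (1−μ)φ): bounded in [0, 1]
  with variance μ(1−μ)/(φ+1), mimicking array beta-value behavior. φ
  (`beta_precision`, default 200 ≈ probe SD 0.025 at μ = 0.5) is a
  calibration knob, not an estimate of any particular array's noise — real
  studies start from measured arrays and need no noise model. φ = ∞ is the
  exact noiseless limit used by invariant tests.
* **Categories.** Planted hyper/hypo/inter promoter means are 0.85 / 0.15 /
  0.5; defaults plant 30% hyper and 40% hypo, the rough proportions such
  cohorts report. In the noiseless model every planted hyper mean exceeds
  0.7 and every hypo mean is below 0.3, so the categorization rule recovers
  the labels exactly.
* **Clusters.** A small set of inter lncRNAs (5% by default, one block per
  cluster) has promoter mean 0.5 ± `cluster_shift` depending on the
  sample's balanced planted cluster; these probes dominate the variance
  ranking, which is what makes top-5% selection followed by consensus
  clustering a faithful test.
* **Mixtures and associations.** Cell mixtures are Dirichlet(1); signature
  probes equal mixture · signature plus the same beta noise. Couplings
  between a lncRNA and one cell-type fraction use a Gaussian copula on the
  latent scale with latent correlation 2·sin(π·ρ/6), so the *Spearman*
  correlation equals the requested ρ — rank-based statistics see only the
  copula, making the marginal map irrelevant.
* **Geometry.** One chromosome by default; inter-gene gaps are drawn so
  promoters never overlap (> 4 kb TSS spacing) and so that exactly the
  recorded lncRNA–PCG pairs fall within the 10-kb window (near gaps
  4.1–9 kb, far gaps > 10.5 kb), giving unambiguous linkage truth.
  Synthetic sequences are i.i.d. bases at a target GC with CG dinucleotides
  planted at a boosted rate for a CpG-island-like subset.
* **Survival.** Event times are exponential with cluster-specific hazards
  spanning a `hazard_ratio`-fold range geometrically across clusters;
  censoring is an independent uniform time whose horizon is solved
  numerically (Brent) so the expected censoring fraction hits
  `censor_rate`. Age, sex, and WHO category are independent of cluster by
  default, which gives the nested-Cox likelihood-ratio test a calibrated
  null.

What the generator does **not** emulate: IDAT-level artifacts, background
or dye bias, batch structure, probe cross-reactivity beyond the manifest
flags, correlated probe noise within a promoter, or realistic linkage
between annotation features and methylation state beyond the planted
structure. Passing tests therefore demonstrate that the *procedures* are
implemented correctly and recover planted truth under a plausible noise
law — not that any particular biological cohort would behave the same way.

## Problem sizes and determinism

Simulation-based checks run at desk scale, chosen to exercise the
procedures well inside routine runtimes: categorization recovery on
200 × 2,000 lncRNAs at φ ∈ {200, 50}; clustering recovery on 200 samples
with 4 planted clusters (50 iterations, resample 0.8, k = 2..8); 100
Dirichlet mixtures at noise SD 0.02; association sensitivity over 50
planted couplings at n = 100 and a fully null false-call run of 500
replicates (250,000 tests); cutpoint–oracle agreement over 200 instances
with n ≤ 30; Cox LR calibration over 1,000 null and 200 power replicates at
n = 200. All randomness flows from explicit seeds through
`numpy.random.default_rng`; the pipeline derives per-stage seeds by hashing
the stage name with the global seed, so stages are reproducible in
isolation, and identical config + seed reproduces every output file byte
for byte.

## Known limitations

* No normalization, batch correction, or cross-array harmonization — the
  beta matrix is assumed preprocessed.
* Deconvolution is relative (fractions sum to 1); no absolute-abundance
  mode and no derivation of new signatures from purified references.
* The naive post-cutpoint log-rank p is optimistic by construction; use the
  permutation-corrected option when the cutpoint itself is data-derived.
* Cox modeling assumes proportional hazards; no competing risks,
  time-varying covariates, or diagnostics.
* The PAC-minimizing k is a convention; flat-structure data can make PAC
  nearly tie across k, in which case the smaller k wins.
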