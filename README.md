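# lncmeth

Promoter-methylation analysis of long noncoding RNAs (lncRNAs) on
methylation-array cohorts, built as a tested, reusable pipeline. It targets
the kind of study where Illumina 450K beta values from a large tumor cohort
(for example, pediatric CNS tumors) are combined with a gene annotation to
ask four questions:

1. **Which lncRNAs are epigenetically silenced or active?** Probes are
   filtered (chrX/Y, SNP-overlapping, non-uniquely mapping, absent from the
   EPIC array), mapped to 4-kb promoters centered on the strand-aware TSS,
   and averaged per gene. A lncRNA is *hyper-methylated* if its promoter
   beta exceeds 0.7 in more than 80% of samples, *hypo-methylated* if it is
   below 0.3 in more than 80%, and *inter-methylated* otherwise. Sequence
   features (GC content, CpG observed/expected with expected = (GC/2)²,
   exon counts, promoter conservation) are compared across the three
   categories by Kolmogorov–Smirnov and Wilcoxon rank-sum tests.
2. **What methylation subtypes exist?** The top 5% most variable
   lncRNA-promoter probes feed resampled consensus clustering (50
   iterations, 80% sample resampling, k-means under a Pearson-correlation
   distance); the cluster number is chosen by minimizing the proportion of
   ambiguous clustering (PAC).
3. **How immune-infiltrated is each tumor, and which lncRNAs track it?**
   Cell fractions over ten reference cell types (CD14, CD19, CD4_Eff, CD56,
   CD8, Endothelial, Eos, Fib, Neu, Treg) are estimated from a
   methylation signature matrix by non-negative least squares (or a
   CIBERSORT-style nu-SVR), with an empirical permutation p-value
   (100 permutations, no quantile normalization). Per cluster, the Spearman
   correlation ρ between each lncRNA's promoter methylation and each cell
   fraction is tested; calls require |ρ| > 0.3 **and** BH-adjusted p < 0.05.
   Called lncRNAs inherit immune-pathway annotations from protein-coding
   genes within 10 kb.
4. **Is any of this prognostic?** One-vs-rest Welch t-tests flag
   differentially methylated lncRNAs (|Δβ| > 0.2, p < 0.05); samples are
   split at the maximally selected log-rank cutpoint of a marker's
   methylation and compared by log-rank; and nested Cox models
   (age + sex ⊂ + WHO category ⊂ + methylation cluster) quantify the added
   prognostic value through likelihood-ratio increments,
   ΔLR = 2(ℓ₁ − ℓ₀) ~ χ²(Δdf).

Because real cohorts of this kind are assembled from controlled-access
repositories, the package ships a first-class synthetic-data generator
(`lncmeth.synthetic`) that emulates every input — annotation, probe
manifest, signature matrix, beta matrix, survival table — with planted
cluster structure, methylation categories, cell-type mixtures,
lncRNA–infiltration couplings, and cluster-dependent survival, so the whole
pipeline is testable end to end without any download.

## Worked example

```python
import lncmeth as lm

cfg = lm.SyntheticConfig(n_samples=60, n_clusters=3, n_lncrna=80,
                         n_pcg=30, n_assoc_lncrna=8, seed=3)
ds = lm.simulate_dataset(cfg)

retained, report = lm.filter_probes(ds.annotation.manifest)
proms = lm.annotation.promoters_of(ds.annotation.lncrnas)
mapping = lm.map_probes_to_promoters(retained, proms)
pm = lm.summarize_promoter(ds.beta, mapping)
cats = lm.categorize(pm)
print(cats["label"].value_counts().to_dict())
print((cats["label"] == ds.truth.category_of_lncrna[cats.index]).mean())
```

prints

```
{'hypo': 24, 'hyper': 18, 'inter': 18}
1.0
```

— 80 lncRNAs were planted with 30% hyper / 40% hypo promoters (a handful of
the inter genes carry cluster or infiltration signal instead), and the
categorization rule recovers every planted label at the default noise level
(beta-distributed array noise with concentration φ = 200).

The same cohort runs end to end from the shell:

```bash
lncmeth run-all --seed 11 --outdir run/
```

which writes per-stage TSVs (`categories.tsv`, `cluster_assignments.tsv`,
`cell_fractions.tsv`, `associations.tsv`, `diff_methylation.tsv`,
`nested_cox_lr.tsv`, `survival_cutpoints.tsv`, …) plus a sha256 manifest;
rerunning with the same seed reproduces every file byte for byte.

## Layout

- `src/lncmeth/annotation.py` — gene models, strand-aware promoters, sequence
  and conservation features, category comparisons
- `src/lncmeth/methylation.py` — probe filtering, promoter mapping and
  summarization, three-way categorization
- `src/lncmeth/clustering.py` — variable-probe selection, consensus
  clustering, PAC, sample–sample correlation
- `src/lncmeth/deconvolution.py` — signature-based cell fractions,
  permutation significance, signature scores, per-cluster ANOVA
- `src/lncmeth/immune.py` — Spearman association calls, BH adjustment,
  category enrichment, 10-kb pathway proximity, one-vs-rest differential
  methylation
- `src/lncmeth/survival.py` — maximally selected cutpoints, log-rank,
  nested Cox LR tests
- `src/lncmeth/synthetic.py` — the planted-truth cohort generator
- `src/lncmeth/pipeline.py`, `cli.py` — orchestration and the `lncmeth` CLI

See `docs/methods.md` for the models, parameter defaults, and the design
decisions behind them.
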