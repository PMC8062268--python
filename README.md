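# flora

**Fast long-noncoding-RNA analysis** — a toolkit for discovering lncRNAs from
RNA-seq alignments and turning them into clinically interpretable tumor
subtypes and prognostic biomarkers.

Long noncoding RNAs (transcripts > 200 nt with no protein-coding capacity)
are expressed at low levels but in a highly tissue- and state-specific way,
which makes them attractive features for classifying tumors and for
prognosis. Assembling them from whole-transcriptome data is expensive,
however, because the vast majority of reads come from coding genes. `flora`
addresses both problems: it removes reads mapped to coding regions and other
RNA species *before* assembly (only a few percent of properly mapped reads
are intergenic, so this shrinks the assembler's input drastically), then
filters assembled transcripts into a confident lncRNA set, and finally
provides the downstream statistical toolbox: differential expression,
consensus subtyping with cross-platform transfer, survival analysis with
optimal expression cut-offs, co-expression-based function prediction, and
ensemble biomarker ranking.

## What is implemented

| stage | module | method |
|---|---|---|
| interval core | `flora.genomic_core` | GTF/GFF parsing (0-based half-open internally), interval-tree overlap index, exonic-overlap novelty labelling |
| read prefilter | `flora.prefilter` | per-read region class (coding exon > UTR > other RNA > intron > intergenic) from CIGAR-derived aligned blocks; SAM/BAM in/out, composition report |
| lncRNA calling | `flora.lncrna_caller` | intron-chain merging; CPAT-style coding potential `P(coding) = logistic(ORF length, ORF coverage, Fickett TESTCODE, in-frame hexamer log-ratio)`; filters: length > 200 nt, ≥ 2 exons, score < 0.5, mean FPKM > 0.1, no same-strand coding-exon overlap |
| expression & DE | `flora.quantify_de` | `FPKM = 10⁹·c/(N·L)`; Wilcoxon rank-sum on log₂(x+1), BH q ≤ 0.05, abs(log₂FC) ≥ 1 |
| subtyping | `flora.subtype` | Monti-style consensus k-means, delta-area k selection; one-vs-rest marker tests; Fisher exact enrichment; linear-SVM transfer with per-cohort z-normalization |
| survival | `flora.survival` | Kaplan–Meier, k-group log-rank (incl. cross-factor "multivariate" mode), Cox PH (Efron ties), minimum-log-rank-P expression cut-off with companion Cox p |
| function | `flora.function_net` | Spearman co-expression partners (BH across genes), one-sided hypergeometric GO enrichment |
| prioritization | `flora.prioritize` | weighted rank-sum (Borda) over tumor expression, survival p, risk-SNP distance, literature support |
| synthetic data | `flora.simdata` | deterministic generators with recorded ground truth for every stage |

## Worked example

Subtype a synthetic cohort, test the subtypes against survival, and carry
the labels to a second, platform-shifted cohort:

```python
from flora.simdata import SimConfig, make_cohort
from flora.subtype import consensus_cluster, subtype_markers, train_transfer_classifier
from flora.survival import cox_fit, logrank_test

cfg = SimConfig(seed=42)                      # 90 tumors, 30 normals, 3 planted subtypes
cohort_a, cohort_b, clinical, truth = make_cohort(cfg)
tumors = cohort_a.subset_samples(cohort_a.samples_in_group("tumor"))

results, k = consensus_cluster(tumors, k_range=(2, 3, 4), n_resamples=50, seed=42)
labels = results[k].labels
markers = subtype_markers(tumors, labels)
chi2, df, p = logrank_test(clinical.assign(subtype=labels), "subtype")
fit = cox_fit(clinical.assign(is_s2=(clinical["subtype"] == 2).astype(int)),
              ["is_s2", "age", "stage"])
clf = train_transfer_classifier(tumors, labels, cohort_b.feature_ids, seed=42)
pred = clf.predict(cohort_b)
```

This prints (seed 42):

```
selected k = 3; cluster sizes = [30, 30, 30]
markers per subtype = {2: 51, 1: 51, 0: 51}
log-rank over subtypes: chi2 = 4.15, df = 2, p = 0.125
HR(subtype 2 vs rest) = 1.63 [0.98, 2.71], p = 0.0605
transfer classifier CV accuracy = 1.00; external predictions = [30, 30, 30]
```

The consensus clustering recovers the three planted subtypes exactly and the
SVM transfers them perfectly to the distorted second cohort. The highest-risk
planted subtype carries a hazard ratio of 1.63 in this 90-tumor draw — the
point estimate is right (the planted log-HR is 1.2 relative to baseline,
diluted here by the one-vs-rest encoding) but a cohort this small does not
reach significance, which is exactly why the large-cohort simulations in the
acceptance script use several hundred patients.

A shell workflow over files works the same way:

```bash
flora simulate --seed 1 --out fixture/
flora prefilter --bam fixture/reads.sam --gtf fixture/annotation.gtf \
      --keep intergenic,intron -o filtered.sam --report report.tsv
```

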