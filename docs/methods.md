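# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Coordinates and annotation

All intervals are 0-based half-open internally; GTF/GFF I/O converts from
the on-disk 1-based closed convention at the boundary. The overlap index is
an interval tree per chromosome; every indexed interval maps back to exactly
one (transcript, exon) pair.

A merged/assembled transcript is labelled **known** when its exonic bases
overlap the merged exonic bases of a single annotated lncRNA locus on a
compatible strand by at least `min_frac` (default 0.5) of its own exonic
length, else **novel**. Unstranded transcripts ('.') match either strand,
since most whole-transcriptome libraries are not strand-specific. The 0.5
fraction and the same-strand rule are package defaults, deliberately
exposed as parameters: known/novel proportions are sensitive to both.

## Read prefiltering

Aligned reference blocks are the M/=/X runs of the CIGAR, merged across
deletions (D) and split at skips (N). A read's region class is the highest
priority class any block touches by ≥ 1 bp:

    coding_exon > UTR > other_RNA > intron > intergenic

with `coding_exon` fed by CDS features, `UTR` by protein-coding exons,
`other_RNA` by rRNA/tRNA/snoRNA/miRNA/snRNA exons, and `intron` by the
transcript spans of all of the above. Annotated lncRNA exons are
deliberately *not* indexed as a removable class: prefiltering exists to
retain lncRNA-derived reads, so reads over annotated lncRNAs fall through
to intergenic/intron and survive the default filter
(`keep = {intergenic, intron}`). Keeping intronic reads is itself a choice:
dropping them (`--keep intergenic`) trades sensitivity for antisense- and
intronic-lncRNA false discovery, and both modes are supported.

Secondary and supplementary alignments are excluded from both the output
and the report denominator, so fractions are over primary records —
"properly mapped" composition statistics are only meaningful on that
denominator. When one mate of a pair is removed, the other is kept; class
is a per-record property.

## Coding potential

The score is a logistic regression over four sequence features:

* `log(1 + ORF length)` — longest ATG-initiated, stop-terminated ORF over
  the three forward frames (ties break 5'),
* ORF coverage — ORF length / transcript length,
* Fickett TESTCODE statistic (classic position/content lookup tables),
* mean in-frame hexamer log-likelihood ratio over the longest ORF.

The hexamer table counts in-frame hexamers of the longest ORF for **both**
training classes. The symmetry matters: counting whole-sequence hexamers
for the noncoding class lets the 4096-parameter table memorize individual
training sequences, which shows up as far-from-chance held-out AUROC on
degenerate inputs (identical class sets). For the same reason the held-out
split is drawn per class with a shared RNG. The logistic weights are fit by
maximum likelihood (scikit-learn); the default decision cutoff is 0.5 and
the model reports its held-out AUROC so users can judge their training
sets. Sequences shorter than 200 nt or more than 50 % N are rejected.

## lncRNA calling

Per-sample assemblies merge on identical intron chains (chromosome, strand,
splice junctions); outermost exon boundaries take the union over members.
Single-exon transcripts merge transitively by ≥ 1 bp same-strand overlap.
`min_samples` defaults to 1.

The filter cascade keeps transcripts with spliced length **> 200 nt**
(strict, matching the definitional "longer than 200 nucleotides"), **≥ 2
exons**, coding-potential score **< 0.5**, mean expression **> 0.1 FPKM**
across all samples (tumors-only averaging is a flag), and **no same-strand
exonic overlap with protein-coding exons**. All predicates are evaluated
independently for every transcript, so the survivor set is order-free by
construction and the attrition report counts every violated predicate, not
just the first.

## Expression and differential expression

`FPKM[f,s] = 10⁹ · counts[f,s] / (library_size[s] · length[f])`, library
size defaulting to the column sum (so FPKM·length/10⁹ sums to 1 per
sample). The default DE test is the two-sided Wilcoxon rank-sum on
log₂(x+1), BH-corrected across features, calling a direction only when
q ≤ 0.05 **and** |log₂FC| ≥ 1; Welch's t on logs and a paired signed-rank
mode are alternatives. These defaults are documented rather than canonical —
rank tests are robust to FPKM skew but insensitive to small shifts at
n < ~10 per group.

## Consensus subtyping

Monti-style consensus clustering: in each of `n_resamples` (default 250)
iterations, an 80 % sample subset is clustered by k-means on per-feature
standardized log₂ values; consensus[i,j] is the fraction of co-sampled runs
in which i and j co-cluster. Final labels come from average-linkage
hierarchical clustering of 1 − consensus. k is chosen by the delta-area
elbow: the largest k whose relative gain in consensus-CDF area over k−1 is
at least 0.1. (The textbook convention that k=2's "delta" is its own area
mechanically prefers k=2 on almost any data, so the elbow form is used.)
A seed is mandatory; identical seeds give identical labels.

Markers are one-vs-rest Wilcoxon tests, BH across all (feature, cluster)
pairs; a feature may mark only the cluster where its positive effect is
largest. Categorical enrichment per (cluster, category) is the two-sided
Fisher exact test on the 2×2 in/out table.

Cross-cohort transfer restricts to platform-shared features, z-scores each
feature *within* its own cohort (which absorbs per-feature affine platform
distortions — the generator's platform-shift model is exactly the family
this normalization cancels), and fits a one-vs-rest linear SVM (C = 1),
reporting 5-fold cross-validated training accuracy.

## Survival analysis

Kaplan–Meier, the k-group log-rank test and Cox proportional hazards are
computed by lifelines (Efron tie handling; Newton optimization;
non-convergence and separation are flagged, never silently returned). The
"multivariate log-rank" over two factors is the k-group log-rank on their
cross-classification.

The expression cut-off search scans every midpoint between adjacent
distinct values that leaves ≥ `min_group_frac` (default 0.1) of samples in
each group and returns the cut-off minimizing the two-group log-rank p.
The scan is vectorized over cut-offs (per-event-time sums via
`np.add.reduceat`), so a 375-sample scan costs milliseconds. **The minimum
p is selection-biased by construction** — under the null its distribution
is stochastically smaller than uniform — so the Cox p of the *continuous*
expression covariate is always reported alongside as the selection-free
companion statistic, and no multiplicity correction is applied to the scan
itself.

## Function prediction

Partners of a focal lncRNA are all candidate (coding) genes with Spearman
|r| ≥ 0.3 and BH q ≤ 0.05 across candidates (Pearson optional); p-values
use the t transform of r. GO enrichment is the one-sided hypergeometric
tail P(X ≥ overlap) with the expressed candidate set as universe, BH across
terms. No GO-graph propagation is performed; term–gene maps are flat
two-column tables.

## Prioritization

Each component — mean tumor expression (higher better), Cox p of continuous
expression (lower better), distance to the nearest risk SNP (lower better;
0 inside the locus, ∞ on SNP-free chromosomes), literature support
(boolean) — is converted to an average rank and combined as a weighted rank
sum (equal weights by default). Rank aggregation makes the result invariant
to monotone transforms of any single component; aggregate ties break
deterministically by id.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed) and record ground truth
for every planted quantity.

* **Genome/reads**: non-overlapping three-exon coding genes (CDS in the
  middle exon), two-exon lncRNAs, single-exon small RNAs; reads are 50M
  single-block records planted uniformly inside their class's regions
  (defaults 40 % coding exon, 15 % UTR, 10 % other RNA, 15 % intron, 20 %
  intergenic out of 1,000 reads). No sequencing error, no splice noise, no
  multi-mapping, no overlapping genes — read classification on real data is
  harder wherever annotations overlap.
* **Cohorts**: log-normal expression; 90 tumors / 30 normals; 3 subtypes ×
  50 markers shifted by 2 log₂ units over 150 noise features; a second
  cohort re-drawn from the same model then distorted per feature by an
  affine map (scale 0.6–1.6, shift sd 0.5) plus Gaussian noise (sd 0.4).
  Survival is exponential with per-subtype log-HRs (0, 0.5, 1.2), baseline
  hazard 0.02/month, uniform administrative censoring on [0, 80] months —
  chosen for closed-form sanity checks, not realism (no covariate-dependent
  censoring, no cure fraction, proportional hazards true by construction).
* **Coding/noncoding sequences**: coding = short UTRs around one
  ATG–(sense codons)–stop ORF with a *fixed* skewed codon-usage table
  shared by all generators (a species-level property; per-seed usage tables
  would decouple fixtures from models trained under other seeds);
  noncoding = uniform random nucleotides. Real negatives (UTR fragments,
  pseudogenes) are far harder than uniform noise, so held-out AUROC = 1 here
  bounds nothing about real data beyond implementation correctness.
* **Networks**: one latent factor shared by the focal lncRNA and 50 module
  genes (R² = 0.5) among 950 independent genes.

Passing tests on these fixtures demonstrates contract correctness —
oracle equivalence, calibration, monotonicity, exact truth recovery — not
real-data performance.

## Simulation sizes

Large-sample checks use cohort sizes a real study of this kind would have:
Cox effect recovery at n = 300, CI coverage over 500 null replicates at
n = 60, and cut-off recovery at n = 375 (the scale of a large tumor
expression cohort) over 200 replicates; at n = 200 the 70th-percentile
threshold is recovered within ±5 percentile points only ~78 % of the time —
a precision limit of the estimator, not a defect.

## Known limitations

* No BAM index/TABIX support, no liftover, no alt contigs.
* The prefilter classifies per record; paired-consistency is optional and
  mates are not rescued jointly.
* Coding-potential accuracy is entirely determined by the supplied training
  sets; no pretrained model ships with the package.
* Consensus clustering cost grows as O(n_resamples · n²); the consensus
  matrix is dense.
* The cut-off scan reports, but does not correct, its selection bias.
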