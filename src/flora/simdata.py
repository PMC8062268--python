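"""Deterministic synthetic fixtures for every pipeline stage.

Emulates the statistical structure the downstream analyses assume — reads
planted per genomic region class, subtype-specific lncRNA over-expression,
subtype-linked hazards, platform-shifted replication cohorts, and
lncRNA-coding co-expression modules — while recording ground truth for each
planted quantity, so every module can be scored without re-deriving truth.
All generators are pure functions of their config and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .genomic_core import (
    Exon,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    write_gtf,
)
from .quantify_de import ExpressionMatrix

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

#: the 61 sense codons with a fixed, skewed "species" usage table, shared by
#: every generator so coding-like sequences agree in hexamer statistics
#: regardless of which seed produced them
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_CODON_USAGE = np.random.default_rng(20210319).dirichlet(
    np.full(len(_SENSE_CODONS), 0.35)
)


def _coding_body(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons, p=_CODON_USAGE))


@dataclass
class SimConfig:
    """All knobs of the synthetic world; identical config + seed => identical output."""

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_coding_genes: int = 8
    n_lncrna_genes: int = 6
    n_other_rna_genes: int = 4
    # read model: planted reads per region class
    reads_per_class: dict = field(
        default_factory=lambda: {
            "coding_exon": 400,
            "UTR": 150,
            "other_RNA": 100,
            "intron": 150,
            "intergenic": 200,
        }
    )
    read_length: int = 50
    proper_pair_frac: float = 1.0
    # cohort model
    n_tumors: int = 90
    n_normals: int = 30
    k_subtypes: int = 3
    markers_per_subtype: int = 50
    n_noise_features: int = 150
    marker_effect_log2: float = 2.0
    platform_scale_range: tuple = (0.6, 1.6)
    platform_shift_sd: float = 0.5
    platform_noise_sd: float = 0.4
    # survival model
    baseline_hazard: float = 0.02
    subtype_log_hr: tuple = (0.0, 0.5, 1.2)
    censor_horizon: float = 80.0
    # network model
    module_size: int = 50
    n_network_noise: int = 950
    module_r2: float = 0.5
    network_samples: int = 100

    def __post_init__(self):
        if self.k_subtypes > self.n_tumors // 3:
            raise ValueError("k_subtypes > n_tumors/3: clusters would be degenerate")


# ---------------------------------------------------------------------------
# genome, annotation, and planted reads


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_genome_and_reads(
    cfg: Optional[SimConfig] = None, outdir: Optional[str] = None
) -> tuple[dict[str, str], GenomeAnnotation, list[dict], pd.DataFrame]:
    """Toy genome + annotation + reads planted per region class, with truth.

    Returns ``(genome, annotation, reads, truth)`` where ``reads`` are dicts
    ready to be written as SAM records and ``truth`` records each read's
    planted region class.  When ``outdir`` is given, ``genome.fa``,
    ``annotation.gtf``, ``reads.sam`` and ``truth.tsv`` are written there.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome = {c: _random_seq(rng, cfg.chrom_length) for c in chroms}

    ann = GenomeAnnotation()
    # region pools for read planting, per class
    pools: dict[str, list[GenomicInterval]] = {
        "coding_exon": [],
        "UTR": [],
        "other_RNA": [],
        "intron": [],
        "intergenic": [],
    }
    slot = 4_000  # each gene occupies [g, g+2400) within a 4 kb slot
    genes = (
        [("protein_coding", i) for i in range(cfg.n_coding_genes)]
        + [("lncRNA", i) for i in range(cfg.n_lncrna_genes)]
        + [("tRNA", i) for i in range(cfg.n_other_rna_genes)]
    )
    total_slots = cfg.n_chroms * (cfg.chrom_length // slot - 1)
    if len(genes) > total_slots:
        raise ValueError("gene composition overflows the genome")
    positions = [
        (chroms[s % cfg.n_chroms], (s // cfg.n_chroms) * slot + 1_000)
        for s in range(len(genes))
    ]
    margin = cfg.read_length + 10
    for (bt, i), (chrom, g) in zip(genes, positions):
        strand = "+" if rng.random() < 0.5 else "-"
        if bt == "protein_coding":
            e1 = GenomicInterval(chrom, g, g + 300, strand)
            e2 = GenomicInterval(chrom, g + 800, g + 1_400, strand)
            e3 = GenomicInterval(chrom, g + 1_900, g + 2_200, strand)
            tx = TranscriptModel(
                id=f"PC{i}", gene_id=f"PCG{i}", strand=strand,
                exons=[Exon(e) for e in (e1, e2, e3)],
                cds=[GenomicInterval(chrom, g + 800, g + 1_400, strand)],
            )
            ann.add(tx, "protein_coding")
            pools["coding_exon"].append(GenomicInterval(chrom, g + 800, g + 1_400 - margin))
            pools["UTR"].append(GenomicInterval(chrom, g, g + 300 - margin))
            pools["intron"].append(GenomicInterval(chrom, g + 310, g + 800 - margin))
        elif bt == "lncRNA":
            e1 = GenomicInterval(chrom, g, g + 400, strand)
            e2 = GenomicInterval(chrom, g + 1_000, g + 1_500, strand)
            tx = TranscriptModel(
                id=f"LNC{i}", gene_id=f"LNCG{i}", strand=strand,
                exons=[Exon(e1), Exon(e2)],
            )
            ann.add(tx, "lncRNA")
        else:  # tRNA-like small RNA, single exon
            e1 = GenomicInterval(chrom, g, g + 200, strand)
            ann.add(
                TranscriptModel(id=f"TR{i}", gene_id=f"TRG{i}", strand=strand,
                                exons=[Exon(e1)]),
                "tRNA",
            )
            pools["other_RNA"].append(GenomicInterval(chrom, g, g + 200 - margin))
    # intergenic pool: the tail half of each chromosome beyond the last slot
    used = max(p[1] for p in positions) + slot
    for chrom in chroms:
        pools["intergenic"].append(
            GenomicInterval(chrom, used + 1_000, cfg.chrom_length - margin)
        )

    reads: list[dict] = []
    truth_rows = []
    counter = 0
    for cls, n_reads in cfg.reads_per_class.items():
        pool = pools[cls]
        if n_reads > 0 and not pool:
            raise ValueError(f"no region available to plant class {cls!r}")
        for _ in range(n_reads):
            region = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(region.start, region.end - cfg.read_length))
            name = f"read{counter}"
            counter += 1
            reads.append(
                {
                    "name": name,
                    "chrom": region.chrom,
                    "pos": pos,
                    "cigar": f"{cfg.read_length}M",
                    "proper_pair": bool(rng.random() < cfg.proper_pair_frac),
                }
            )
            truth_rows.append((name, cls))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=["read", "true_class"]).iloc[order]

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(genome, os.path.join(outdir, "genome.fa"))
        write_gtf(ann, os.path.join(outdir, "annotation.gtf"))
        write_sam(reads, genome, os.path.join(outdir, "reads.sam"))
        truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    return genome, ann, reads, truth


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(reads: list[dict], genome: dict[str, str], path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = r["name"]
            rec.reference_name = r["chrom"]
            rec.reference_start = r["pos"]
            rec.cigarstring = r["cigar"]
            rec.mapping_quality = 60
            rec.flag = 0
            if r.get("proper_pair"):
                rec.is_paired = True
                rec.is_proper_pair = True
            length = sum(
                l for op, l in rec.cigartuples if op in (0, 1, 4, 7, 8)
            )
            rec.query_sequence = "A" * length
            out.write(rec)


# ---------------------------------------------------------------------------
# cohorts: expression + clinical + subtype truth


def make_cohort(
    cfg: Optional[SimConfig] = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Two cohorts of subtype-structured expression plus clinical outcomes.

    Cohort A ("rnaseq", FPKM-like) carries tumors and normals; tumor samples
    belong to ``k_subtypes`` planted subtypes, each over-expressing its own
    marker block by ``marker_effect_log2``.  Cohort B ("array") re-draws
    tumors from the same subtype model and then distorts every feature by an
    affine platform shift plus noise.  Survival times are exponential with
    per-subtype log hazard ratios and uniform administrative censoring.
    Returns ``(cohort_a, cohort_b, clinical, truth_labels)``; truth covers
    both cohorts' tumors.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    k = cfg.k_subtypes
    n_feat = k * cfg.markers_per_subtype + cfg.n_noise_features
    features = [f"lnc{j}" for j in range(n_feat)]
    marker_of = np.full(n_feat, -1)
    for s in range(k):
        lo = s * cfg.markers_per_subtype
        marker_of[lo : lo + cfg.markers_per_subtype] = s

    base_mu = rng.normal(2.0, 0.8, size=n_feat)

    def draw_cohort(n_t: int, n_n: int, tag: str, rng: np.random.Generator):
        subtype = np.repeat(np.arange(k), int(np.ceil(n_t / k)))[:n_t]
        cols, groups, labels = [], [], []
        log2x = np.empty((n_feat, n_t + n_n))
        for j in range(n_t):
            mu = base_mu + cfg.marker_effect_log2 * (marker_of == subtype[j])
            log2x[:, j] = rng.normal(mu, 1.0)
            cols.append(f"{tag}_T{j}")
            groups.append("tumor")
            labels.append(subtype[j])
        for j in range(n_n):
            log2x[:, n_t + j] = rng.normal(base_mu, 1.0)
            cols.append(f"{tag}_N{j}")
            groups.append("normal")
        return log2x, cols, groups, pd.Series(labels, index=cols[:n_t])

    log2a, cols_a, groups_a, labels_a = draw_cohort(
        cfg.n_tumors, cfg.n_normals, "A", rng
    )
    vals_a = pd.DataFrame(np.exp2(log2a), index=features, columns=cols_a)
    meta_a = pd.DataFrame(
        {"group": groups_a, "cohort": "A", "platform": "rnaseq"}, index=cols_a
    )
    cohort_a = ExpressionMatrix(vals_a, meta_a, unit="FPKM")

    log2b, cols_b, groups_b, labels_b = draw_cohort(cfg.n_tumors, 0, "B", rng)
    scale = rng.uniform(*cfg.platform_scale_range, size=n_feat)[:, None]
    shift = rng.normal(0.0, cfg.platform_shift_sd, size=n_feat)[:, None]
    log2b = scale * log2b + shift + rng.normal(0, cfg.platform_noise_sd, log2b.shape)
    vals_b = pd.DataFrame(log2b, index=features, columns=cols_b)
    meta_b = pd.DataFrame(
        {"group": groups_b, "cohort": "B", "platform": "array"}, index=cols_b
    )
    cohort_b = ExpressionMatrix(vals_b, meta_b, unit="log2_intensity")

    truth = pd.concat([labels_a, labels_b]).rename("subtype")

    # survival for cohort A tumors
    tumor_cols = [c for c, g in zip(cols_a, groups_a) if g == "tumor"]
    log_hr = np.asarray(cfg.subtype_log_hr[:k])
    hazards = cfg.baseline_hazard * np.exp(log_hr[labels_a.to_numpy()])
    t_event = rng.exponential(1.0 / hazards)
    t_cens = rng.uniform(0, cfg.censor_horizon, size=len(tumor_cols))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame(
        {
            "time": np.maximum(time, 1e-3),
            "event": event,
            "subtype": labels_a.to_numpy(),
            "age": rng.normal(65, 9, size=len(tumor_cols)).round(1),
            "stage": rng.integers(1, 5, size=len(tumor_cols)),
            "histology": rng.choice(["intestinal", "diffuse"], size=len(tumor_cols)),
        },
        index=tumor_cols,
    )
    return cohort_a, cohort_b, clinical, truth


def make_de_cohort(
    n_up: int = 100,
    n_down: int = 50,
    n_null: int = 850,
    n_per_group: int = 30,
    effect_fold: float = 4.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Tumor/normal matrix with planted up/down/null features and truth labels."""
    rng = np.random.default_rng(seed)
    n_feat = n_up + n_down + n_null
    truth = pd.Series(
        ["up"] * n_up + ["down"] * n_down + ["ns"] * n_null,
        index=[f"f{i}" for i in range(n_feat)],
        name="truth",
    )
    base_mu = rng.normal(3.0, 0.5, size=n_feat)
    shift = np.zeros(n_feat)
    shift[:n_up] = np.log2(effect_fold)
    shift[n_up : n_up + n_down] = -np.log2(effect_fold)
    cols = [f"T{j}" for j in range(n_per_group)] + [f"N{j}" for j in range(n_per_group)]
    log2x = np.empty((n_feat, 2 * n_per_group))
    log2x[:, :n_per_group] = rng.normal(
        (base_mu + shift)[:, None], 0.8, size=(n_feat, n_per_group)
    )
    log2x[:, n_per_group:] = rng.normal(
        base_mu[:, None], 0.8, size=(n_feat, n_per_group)
    )
    meta = pd.DataFrame(
        {"group": ["tumor"] * n_per_group + ["normal"] * n_per_group}, index=cols
    )
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2x), index=truth.index, columns=cols), meta, "FPKM"
    )
    return expr, truth


# ---------------------------------------------------------------------------
# co-expression module fixture


def make_coexpression(
    module_size: int = 50,
    n_noise: int = 950,
    n_samples: int = 100,
    r2: float = 0.5,
    seed: int = 0,
    focal: str = "LNC_FOCAL",
    term: str = "GO:ECM",
    n_decoy_terms: int = 20,
    term_size: int = 25,
) -> tuple[ExpressionMatrix, dict[str, set[str]], set[str]]:
    """Focal lncRNA plus a latent-factor module among noise genes.

    The focal vector and each of ``module_size`` coding genes share a latent
    factor explaining ``r2`` of their variance.  The GO map plants ``term``
    on a subset of the module genes and scatters decoy terms over noise
    genes.  Returns ``(expr, go_map, module_gene_set)``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(module_size + n_noise)]
    module = set(genes[:module_size])
    latent = rng.normal(size=n_samples)
    w = np.sqrt(r2)
    noise_w = np.sqrt(1 - r2)
    rows = {focal: w * latent + noise_w * rng.normal(size=n_samples)}
    for g in genes:
        if g in module:
            rows[g] = w * latent + noise_w * rng.normal(size=n_samples)
        else:
            rows[g] = rng.normal(size=n_samples)
    cols = [f"S{j}" for j in range(n_samples)]
    vals = pd.DataFrame(rows, index=cols).T
    expr = ExpressionMatrix(
        np.exp2(vals + 4.0), pd.DataFrame(index=cols), unit="FPKM"
    )
    go_map = {term: set(list(module)[:term_size])}
    noise_genes = genes[module_size:]
    for t in range(n_decoy_terms):
        picked = rng.choice(noise_genes, size=term_size, replace=False)
        go_map[f"GO:decoy{t}"] = set(picked)
    return expr, go_map, module


# ---------------------------------------------------------------------------
# coding / noncoding training sequences


def make_sequence_sets(
    n_per_class: int = 300, min_len: int = 300, max_len: int = 900, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Synthetic separable sequences for coding-potential training.

    Coding: ATG followed by random non-stop codons (biased codon usage) and
    a stop, padded with short UTRs.  Noncoding: uniform random nucleotides
    with stop codons guaranteed frequent in every frame.
    """
    rng = np.random.default_rng(seed)
    coding = []
    for _ in range(n_per_class):
        n_codons = int(rng.integers(min_len // 3, max_len // 3))
        body = _coding_body(rng, n_codons)
        utr5 = _random_seq(rng, int(rng.integers(5, 30)))
        utr3 = _random_seq(rng, int(rng.integers(5, 30)))
        coding.append(utr5 + "ATG" + body + "TAA" + utr3)
    noncoding = [
        _random_seq(rng, int(rng.integers(min_len, max_len)))
        for _ in range(n_per_class)
    ]
    return coding, noncoding


# ---------------------------------------------------------------------------
# caller fixture with planted pass/fail composition


def make_caller_fixture(
    seed: int = 0,
    n_pass: int = 12,
    n_fail_per_reason: int = 4,
) -> tuple[list[TranscriptModel], GenomeAnnotation, dict[str, str], ExpressionMatrix, pd.Series]:
    """Merged transcripts with known filter outcomes.

    Each failing transcript violates exactly one filter (short, single-exon,
    coding-like sequence, low expression, or coding-exon overlap); passing
    transcripts satisfy all five.  Returns ``(transcripts, annotation,
    genome, expression, truth)`` where truth maps transcript id ->
    'pass' or the violated reason.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrF"
    genome_len = 400_000
    seq = list(_random_seq(rng, genome_len))
    # stomp periodic stops into the whole chromosome so background ORFs stay tiny
    for i in range(0, genome_len - 12, 48):
        for off in range(3):  # j % 3 cycles through all frames (4 ≡ 1 mod 3)
            j = i + off * 4
            seq[j : j + 3] = list(_STOPS[int(rng.integers(3))])
    ann = GenomeAnnotation()
    txs: list[TranscriptModel] = []
    truth = {}
    cursor = 1_000
    uid = 0

    def add_tx(n_exons: int, exon_len: int, reason: str, strand: str = "+"):
        nonlocal cursor, uid
        exons = []
        pos = cursor
        for _ in range(n_exons):
            exons.append(Exon(GenomicInterval(chrom, pos, pos + exon_len, strand)))
            pos += exon_len + 300
        tx = TranscriptModel(
            id=f"TX{uid}", gene_id=f"TXG{uid}", strand=strand,
            exons=exons, source_samples={"s1"},
        )
        uid += 1
        cursor = pos + 1_500
        txs.append(tx)
        truth[tx.id] = reason
        return tx

    for _ in range(n_pass):
        add_tx(3, 200, "pass")
    for _ in range(n_fail_per_reason):
        add_tx(2, 80, "min_length")  # 160 nt total
    for _ in range(n_fail_per_reason):
        add_tx(1, 600, "min_exons")
    for _ in range(n_fail_per_reason):
        tx = add_tx(2, 300, "coding_potential")
        # overwrite the spliced sequence with one long ORF (plus strand)
        body_len = tx.length_nt - 6
        body = _coding_body(rng, body_len // 3)
        full = ("ATG" + body + "TAA").ljust(tx.length_nt, "A")
        offset = 0
        for iv in tx.exon_intervals:
            seq[iv.start : iv.end] = list(full[offset : offset + iv.length])
            offset += iv.length
    for _ in range(n_fail_per_reason):
        add_tx(2, 300, "min_mean_fpkm")
    # coding-overlap failures sit on top of an annotated coding exon
    for j in range(n_fail_per_reason):
        pc_exon = GenomicInterval(chrom, cursor, cursor + 500, "+")
        ann.add(
            TranscriptModel(
                id=f"PCREF{j}", gene_id=f"PCREFG{j}", strand="+",
                exons=[Exon(pc_exon)],
                cds=[pc_exon],
            ),
            "protein_coding",
        )
        tx = add_tx(2, 300, "coding_overlap")
        # shift its first exon onto the coding exon
        first = GenomicInterval(chrom, pc_exon.start + 100, pc_exon.start + 400, "+")
        second = tx.exon_intervals[1]
        txs[-1] = TranscriptModel(
            id=tx.id, gene_id=tx.gene_id, strand="+",
            exons=[Exon(first), Exon(second)], source_samples={"s1"},
        )
        truth[tx.id] = "coding_overlap"
    # one annotated lncRNA so novelty labelling has a reference
    lnc_exon = GenomicInterval(chrom, cursor + 5_000, cursor + 6_000, "+")
    ann.add(
        TranscriptModel(id="LNCREF", gene_id="LNCREFG", strand="+", exons=[Exon(lnc_exon)]),
        "lncRNA",
    )

    genome = {chrom: "".join(seq)}
    fpkm = {}
    for tx in txs:
        fpkm[tx.gene_id] = 0.01 if truth[tx.id] == "min_mean_fpkm" else float(
            rng.uniform(1.0, 20.0)
        )
    expr = ExpressionMatrix(
        pd.DataFrame(
            {f"S{j}": pd.Series(fpkm) for j in range(4)}
        ),
        unit="FPKM",
    )
    return txs, ann, genome, expr, pd.Series(truth, name="truth")


def make_candidates(n: int = 100, noise: float = 0.02, seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Candidate table with a planted total ordering over the four components."""
    rng = np.random.default_rng(seed)
    quality = np.arange(n, dtype=float)  # 0 = best
    jitter = lambda: rng.normal(0, noise * n, size=n)
    tab = pd.DataFrame(
        {
            "tumor_expression": (n - quality) + jitter(),
            "survival": np.clip((quality + jitter()) / n, 1e-6, 1.0),
            "snp_adjacency": np.clip(quality * 1_000 + jitter() * 1_000, 0, None),
            "literature": quality < n / 2,
        },
        index=[f"cand{i:03d}" for i in range(n)],
    )
    planted = pd.Series(quality + 1, index=tab.index, name="planted_rank")
    return tab, planted
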