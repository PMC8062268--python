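"""Candidate lncRNA calling: merge assemblies, score coding potential, filter.

The coding-potential score is a logistic model over four sequence features —
longest-ORF length, ORF coverage, Fickett TESTCODE statistic, and in-frame
hexamer usage log-ratio — trained from user-supplied (or synthetic) coding
and noncoding sequence sets.  A transcript is reported as a prospective
lncRNA when it is longer than 200 nt (spliced length), has at least two
exons, scores below the coding-potential cutoff, shows a mean expression
above 0.1 FPKM, and does not overlap protein-coding exons on its own strand.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .genomic_core import (
    AnnotationIndex,
    Exon,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    locus_overlap,
    overlap_bases,
)

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CallerConfig:
    """Thresholds of the lncRNA filters (all strictly positive)."""

    min_length_nt: int = 200
    min_exons: int = 2
    coding_potential_cutoff: float = 0.5
    min_mean_fpkm: float = 0.1
    min_samples: int = 1
    novelty_min_frac: float = 0.5

    def __post_init__(self):
        if self.min_length_nt <= 0 or self.min_exons <= 0 or self.min_samples <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0 < self.coding_potential_cutoff < 1):
            raise ValueError("coding_potential_cutoff must be in (0, 1)")
        if self.min_mean_fpkm <= 0:
            raise ValueError("min_mean_fpkm must be strictly positive")


# ---------------------------------------------------------------------------
# transcript merging


def merge_transcripts(
    per_sample: Sequence[Iterable[TranscriptModel]], min_samples: int = 1
) -> list[TranscriptModel]:
    """Merge per-sample assemblies into a unified transcript set.

    Multi-exon transcripts merge on an identical intron chain (same
    chromosome, strand and splice junctions); the merged model takes the
    union of member exon boundaries (outermost ends).  Single-exon
    transcripts merge transitively by >= 1 bp same-strand overlap.  Models
    supported by fewer than ``min_samples`` distinct samples are dropped.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    seen_chrom: dict[str, str] = {}
    multi: dict[tuple, list[TranscriptModel]] = {}
    single: list[TranscriptModel] = []
    for sample in per_sample:
        for tx in sample:
            if seen_chrom.setdefault(tx.id, tx.chrom) != tx.chrom:
                raise ValueError(f"transcript id {tx.id} occurs on different chromosomes")
            if len(tx.exons) >= 2:
                key = (tx.chrom, tx.strand, tx.intron_chain)
                multi.setdefault(key, []).append(tx)
            else:
                single.append(tx)

    merged: list[TranscriptModel] = []
    for (chrom, strand, chain), members in multi.items():
        first_starts = [m.exons[0].interval.start for m in members]
        last_ends = [m.exons[-1].interval.end for m in members]
        bounds = [min(first_starts)] + [c for j in chain for c in j] + [max(last_ends)]
        exons = [
            Exon(GenomicInterval(chrom, s, e, strand))
            for s, e in zip(bounds[::2], bounds[1::2])
        ]
        samples = set().union(*(m.source_samples for m in members))
        merged.append(
            TranscriptModel(
                id=members[0].id,
                gene_id=members[0].gene_id,
                exons=exons,
                strand=strand,
                source_samples=samples,
            )
        )

    # union-find over single-exon transcripts on the same chrom/strand
    single.sort(key=lambda t: (t.chrom, t.strand, t.exons[0].interval.start))
    cluster: list[TranscriptModel] = []
    for tx in single + [None]:  # type: ignore[list-item]
        if cluster and (
            tx is None
            or tx.chrom != cluster[0].chrom
            or tx.strand != cluster[0].strand
            or tx.exons[0].interval.start >= max(m.exons[0].interval.end for m in cluster)
        ):
            start = min(m.exons[0].interval.start for m in cluster)
            end = max(m.exons[0].interval.end for m in cluster)
            c0 = cluster[0]
            merged.append(
                TranscriptModel(
                    id=c0.id,
                    gene_id=c0.gene_id,
                    exons=[Exon(GenomicInterval(c0.chrom, start, end, c0.strand))],
                    strand=c0.strand,
                    source_samples=set().union(*(m.source_samples for m in cluster)),
                )
            )
            cluster = []
        if tx is not None:
            cluster.append(tx)

    return [m for m in merged if len(m.source_samples) >= min_samples]


# ---------------------------------------------------------------------------
# ORF scanning


def longest_orf(seq: str) -> tuple[int, int, int]:
    """Longest ATG-initiated ORF ending at a stop, over the 3 forward frames.

    Returns ``(start, end, length_aa)`` with ``end`` just past the stop codon
    and ``length_aa`` the peptide length excluding the stop.  Ties break to
    the 5'-most start.  No ORF yields ``(0, 0, 0)``.
    """
    seq = seq.upper()
    best = (0, 0, 0)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length_aa = (i - start) // 3
                if length_aa > best[2]:
                    best = (start, i + 3, length_aa)
                start = None
    return best


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic

# classic position/content lookup tables of the TESTCODE statistic
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE score combining codon-position asymmetry and composition."""
    seq = seq.upper()
    if len(seq) < 3:
        return 0.0
    total = 0.0
    n = len(seq)
    for base in "ACGT":
        counts = [sum(1 for i in range(f, n, 3) if seq[i] == base) for f in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = sum(counts) / n
        total += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        total += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return total


# ---------------------------------------------------------------------------
# hexamer usage

_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(_HEXAMERS)}


def _hexamer_counts(seq: str, frame: int = 0) -> np.ndarray:
    counts = np.zeros(4096)
    seq = seq.upper()
    for i in range(frame, len(seq) - 5, 3):
        idx = _HEX_INDEX.get(seq[i : i + 6])
        if idx is not None:
            counts[idx] += 1
    return counts


def hexamer_table(
    coding: Iterable[str], noncoding: Iterable[str], pseudocount: float = 1.0
) -> np.ndarray:
    """Log-likelihood ratio of in-frame hexamer usage, coding vs noncoding.

    Both classes contribute the in-frame hexamers of their longest ORF
    (whole sequence when none), mirroring how sequences are scored; the
    symmetry guarantees a null table when the two classes coincide.
    """

    def orf_counts(seq: str) -> np.ndarray:
        s, e, aa = longest_orf(seq)
        return _hexamer_counts(seq[s:e] if aa > 0 else seq)

    cod = np.full(4096, pseudocount)
    non = np.full(4096, pseudocount)
    for seq in coding:
        cod += orf_counts(seq)
    for seq in noncoding:
        non += orf_counts(seq)
    return np.log(cod / cod.sum()) - np.log(non / non.sum())


def hexamer_score(seq: str, table: np.ndarray) -> float:
    """Mean hexamer log-ratio over the longest ORF (whole sequence if none)."""
    s, e, aa = longest_orf(seq)
    target = seq[s:e] if aa > 0 else seq
    counts = _hexamer_counts(target)
    n = counts.sum()
    if n == 0:
        return 0.0
    return float(counts @ table / n)


# ---------------------------------------------------------------------------
# coding-potential model


@dataclass
class CodingPotentialModel:
    """Logistic model over (ORF length, ORF coverage, Fickett, hexamer) features."""

    hexamer_table: np.ndarray
    coef: np.ndarray
    intercept: float
    heldout_auroc: Optional[float] = None
    feature_names: tuple = ("log_orf_length", "orf_coverage", "fickett", "hexamer")

    def features(self, seq: str) -> np.ndarray:
        seq = seq.upper()
        _, _, aa = longest_orf(seq)
        orf_nt = 3 * aa
        return np.array(
            [
                math.log1p(orf_nt),
                orf_nt / len(seq) if seq else 0.0,
                fickett_score(seq),
                hexamer_score(seq, self.hexamer_table),
            ]
        )

    def score(self, seq: str) -> float:
        z = float(self.features(seq) @ self.coef + self.intercept)
        return 1.0 / (1.0 + math.exp(-z))


def _read_fasta(path: str) -> list[str]:
    seqs, cur = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            else:
                cur.append(line.strip())
    if cur:
        seqs.append("".join(cur))
    return seqs


def fit_coding_model(
    coding: Union[str, Sequence[str]],
    noncoding: Union[str, Sequence[str]],
    seed: int = 0,
    heldout_frac: float = 0.25,
) -> CodingPotentialModel:
    """Train the coding-potential logistic model from two sequence sets.

    Arguments may be FASTA paths or sequence lists; each class needs at
    least 100 sequences.  The hexamer table is estimated on the training
    split only, and a held-out AUROC is reported.
    """
    cod = _read_fasta(coding) if isinstance(coding, str) else list(coding)
    non = _read_fasta(noncoding) if isinstance(noncoding, str) else list(noncoding)
    for name, seqs in (("coding", cod), ("noncoding", non)):
        if len(seqs) < 100:
            raise ValueError(f"{name} set has {len(seqs)} sequences; >= 100 required")
    seqs = cod + non
    y = np.array([1] * len(cod) + [0] * len(non))
    # split each class with the same RNG so the hexamer table sees matched
    # training subsets (and cancels exactly when the classes coincide)
    cod_train, cod_test = train_test_split(
        np.arange(len(cod)), test_size=heldout_frac, random_state=seed
    )
    non_train, non_test = train_test_split(
        np.arange(len(non)), test_size=heldout_frac, random_state=seed
    )
    idx_train = np.concatenate([cod_train, len(cod) + non_train])
    idx_test = np.concatenate([cod_test, len(cod) + non_test])
    table = hexamer_table(
        [seqs[i] for i in idx_train if y[i] == 1],
        [seqs[i] for i in idx_train if y[i] == 0],
    )
    stub = CodingPotentialModel(hexamer_table=table, coef=np.zeros(4), intercept=0.0)
    X = np.array([stub.features(s) for s in seqs])
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(X[idx_train], y[idx_train])
    auroc = float(
        roc_auc_score(y[idx_test], clf.predict_proba(X[idx_test])[:, 1])
    )
    return CodingPotentialModel(
        hexamer_table=table,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        heldout_auroc=auroc,
    )


def coding_potential(seq: str, model: CodingPotentialModel) -> float:
    """Coding probability in [0, 1] for one transcript sequence (>= 200 nt)."""
    seq = seq.upper()
    if len(seq) < 200:
        raise ValueError(f"sequence length {len(seq)} < 200 nt")
    if seq.count("N") > 0.5 * len(seq):
        raise ValueError("sequence is more than 50% N")
    return model.score(seq)


# ---------------------------------------------------------------------------
# the filter cascade


def transcript_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence; minus-strand models are reverse-complemented."""
    try:
        chrom_seq = genome[tx.chrom]
    except KeyError:
        raise ValueError(f"transcript {tx.id}: chromosome {tx.chrom} not in genome")
    parts = [str(chrom_seq[iv.start : iv.end]) for iv in tx.exon_intervals]
    seq = "".join(parts).upper()
    return reverse_complement(seq) if tx.strand == "-" else seq


FILTER_REASONS = (
    "min_length",
    "min_exons",
    "coding_potential",
    "min_mean_fpkm",
    "coding_overlap",
)


def call_lncrnas(
    merged: Iterable[TranscriptModel],
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    expression,
    model: CodingPotentialModel,
    cfg: Optional[CallerConfig] = None,
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Apply the lncRNA filter cascade and label survivors known/novel.

    ``expression`` is an :class:`~flora.quantify_de.ExpressionMatrix` (or a
    pandas DataFrame) whose rows cover the merged transcripts' gene ids, in
    FPKM.  All predicates are evaluated independently for every transcript,
    so the survivor set does not depend on filter order; the attrition dict
    counts, per reason, how many transcripts fail that predicate.
    """
    cfg = cfg or CallerConfig()
    values = getattr(expression, "values_frame", None)
    if values is None:
        values = expression
    coding_index = _coding_exon_index(annotation)

    survivors: list[TranscriptModel] = []
    attrition = {r: 0 for r in FILTER_REASONS}
    attrition["pass"] = 0
    for tx in merged:
        seq = transcript_sequence(tx, genome)
        if not seq:
            raise ValueError(f"transcript {tx.id}: no sequence retrievable")
        fails = set()
        if tx.length_nt <= cfg.min_length_nt:
            fails.add("min_length")
        if len(tx.exons) < cfg.min_exons:
            fails.add("min_exons")
        score = model.score(seq)
        if score >= cfg.coding_potential_cutoff:
            fails.add("coding_potential")
        if tx.gene_id in values.index:
            mean_fpkm = float(values.loc[tx.gene_id].mean())
        elif tx.id in values.index:
            mean_fpkm = float(values.loc[tx.id].mean())
        else:
            raise ValueError(f"transcript {tx.id}: no expression row for {tx.gene_id}")
        if mean_fpkm <= cfg.min_mean_fpkm:
            fails.add("min_mean_fpkm")
        if _overlaps_coding(tx, coding_index):
            fails.add("coding_overlap")
        for r in fails:
            attrition[r] += 1
        if not fails:
            tx.coding_potential = score
            tx.novelty = locus_overlap(tx, annotation, cfg.novelty_min_frac)
            survivors.append(tx)
            attrition["pass"] += 1
    return survivors, attrition


def _coding_exon_index(annotation: GenomeAnnotation) -> Optional[AnnotationIndex]:
    has_coding = any(bt == "protein_coding" for bt in annotation.biotype.values())
    if not has_coding:
        return None
    return AnnotationIndex(annotation, {"protein_coding"})


def _overlaps_coding(tx: TranscriptModel, index: Optional[AnnotationIndex]) -> bool:
    if index is None:
        return False
    for iv in tx.exon_intervals:
        probe = GenomicInterval(iv.chrom, iv.start, iv.end, tx.strand)
        if index.query(probe, same_strand=True):
            return True
    return False
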