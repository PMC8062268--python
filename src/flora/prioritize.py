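"""Ensemble prioritization of candidate lncRNA biomarkers.

Candidates are ranked on four components — mean tumor expression (higher is
better), association with survival (smaller Cox p on the continuous
expression is better), adjacency to disease-risk SNPs (smaller genomic
distance is better), and literature support (boolean) — and aggregated by a
weighted rank sum (Borda count), which makes the final ordering invariant
to monotone transforms of any single numeric component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genomic_core import GenomicInterval, TranscriptModel

#: component name -> True when larger raw values are better
COMPONENT_DIRECTIONS = {
    "tumor_expression": True,
    "survival": False,  # Cox p
    "snp_adjacency": False,  # distance in bp
    "literature": True,  # boolean support
}


def read_bed(path: str) -> list[GenomicInterval]:
    """Parse a BED3+/BED6 file of SNP positions (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer BED coordinates")
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-." else "."
            out.append(GenomicInterval(parts[0], start, end, strand))
    return out


def snp_adjacency(
    loci: Mapping[str, GenomicInterval] | Iterable[TranscriptModel],
    snps: Sequence[GenomicInterval] | str,
) -> pd.Series:
    """Distance in bp from each lncRNA locus span to its nearest risk SNP.

    Zero when a SNP falls inside the locus span; ``inf`` for loci on
    chromosomes carrying no SNP.
    """
    if isinstance(snps, str):
        snps = read_bed(snps)
    if not isinstance(loci, Mapping):
        loci = {tx.id: tx.span for tx in loci}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    dist = {}
    for name, span in loci.items():
        best = math.inf
        for s in by_chrom.get(span.chrom, []):
            if s.start < span.end and span.start < s.end:
                best = 0.0
                break
            # gap between half-open intervals; touching boundaries count as 0
            gap = max(span.start - s.end, s.start - span.end)
            best = min(best, float(gap))
        dist[name] = best
    return pd.Series(dist, name="snp_distance_bp")


@dataclass
class PriorityScore:
    """One candidate's component ranks, aggregate score and final rank."""

    lncrna_id: str
    component_ranks: dict[str, float]
    aggregate: float
    final_rank: int


def ensemble_rank(
    candidates: pd.DataFrame,
    weights: Optional[Mapping[str, float]] = None,
    top_n: Optional[int] = None,
) -> list[PriorityScore]:
    """Weighted rank-sum aggregation over the candidate component table.

    ``candidates`` is indexed by lncRNA id with columns named as in
    :data:`COMPONENT_DIRECTIONS` (literature may be boolean).  Each
    component is converted to an average rank with best = 1, the aggregate
    is the weighted sum of ranks (lower is better), and ties in the
    aggregate break deterministically by id.
    """
    components = [c for c in COMPONENT_DIRECTIONS if c in candidates.columns]
    if not components:
        raise ValueError("no known component columns in candidate table")
    if weights is None:
        weights = {c: 1.0 for c in components}
    total_w = sum(weights.get(c, 0.0) for c in components)
    if total_w <= 0:
        raise ValueError("weights must sum to a positive value")

    ranks = pd.DataFrame(index=candidates.index)
    for c in components:
        col = candidates[c]
        if col.dtype == bool:
            col = col.astype(float)
        ranks[c] = col.rank(ascending=not COMPONENT_DIRECTIONS[c], method="average")
    aggregate = sum(weights.get(c, 0.0) * ranks[c] for c in components)
    order = sorted(candidates.index, key=lambda i: (aggregate[i], str(i)))
    scores = [
        PriorityScore(
            lncrna_id=str(i),
            component_ranks={c: float(ranks.loc[i, c]) for c in components},
            aggregate=float(aggregate[i]),
            final_rank=pos + 1,
        )
        for pos, i in enumerate(order)
    ]
    return scores[:top_n] if top_n else scores
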