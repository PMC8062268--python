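"""Function prediction for lncRNAs via co-expression and GO enrichment.

A focal lncRNA's putative function is read off the annotated coding genes it
co-expresses with: correlate the focal expression vector against every
coding gene across samples, keep significant partners, and test the partner
set for over-representation of GO terms by the one-sided hypergeometric
test against the expressed-gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantify_de import ExpressionMatrix, bh_adjust


@dataclass
class CoexpressionNetwork:
    """Significant co-expression partners of one focal lncRNA."""

    focal: str
    partners: pd.DataFrame  # index: gene, columns: r, p, q (sorted by q, |r| desc)
    method: str

    @property
    def partner_ids(self) -> list[str]:
        return list(self.partners.index)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for correlation coefficients via the t transform."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def coexpression_partners(
    expr: ExpressionMatrix,
    focal: str,
    method: str = "spearman",
    alpha_q: float = 0.05,
    min_abs_r: float = 0.3,
    candidate_ids: Optional[Iterable[str]] = None,
) -> CoexpressionNetwork:
    """Correlate the focal feature against every candidate gene.

    ``candidate_ids`` defaults to all other features in the matrix (i.e. the
    expressed coding genes when the matrix is restricted to them).  BH runs
    across candidates; partners satisfy q <= ``alpha_q`` and |r| >=
    ``min_abs_r``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    vals = expr.values_frame
    if focal not in vals.index:
        raise ValueError(f"focal feature {focal!r} not in matrix")
    n = vals.shape[1]
    if n < 10:
        raise ValueError("need >= 10 samples")
    cands = [c for c in (candidate_ids or vals.index) if c != focal]
    X = vals.loc[cands].to_numpy(float)
    y = vals.loc[focal].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError("focal expression vector is constant")
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ yc / denom, 0.0)
    p = _corr_pvalues(r, n)
    q = bh_adjust(p)
    tab = pd.DataFrame({"r": r, "p": p, "q": q}, index=pd.Index(cands, name="gene"))
    hits = tab[(tab["q"] <= alpha_q) & (tab["r"].abs() >= min_abs_r)]
    hits = hits.sort_values(["q", "r"], key=lambda s: s if s.name == "q" else -s.abs())
    return CoexpressionNetwork(focal=focal, partners=hits, method=method)


@dataclass
class GOEnrichment:
    """Hypergeometric over-representation of GO terms in a partner set."""

    table: pd.DataFrame  # index: term, columns: term_size, overlap, p, q, genes

    @property
    def top_terms(self) -> list[str]:
        return list(self.table.index)


def go_enrichment(
    partners: Iterable[str],
    go_map: dict[str, set[str]],
    universe: Iterable[str],
) -> GOEnrichment:
    """One-sided hypergeometric P(X >= overlap) per term, BH across terms.

    Population = |universe|, successes = term size (restricted to the
    universe), draws = |partners|.  Partners must lie inside the universe.
    """
    universe = set(universe)
    partner_set = set(partners)
    if not partner_set <= universe:
        raise ValueError("partners must be a subset of the universe")
    if not partner_set:
        warnings.warn("empty partner set; no enrichment computed")
        return GOEnrichment(
            table=pd.DataFrame(columns=["term_size", "overlap", "p", "q", "genes"])
        )
    M, N = len(universe), len(partner_set)
    rows = []
    for term, genes in go_map.items():
        term_genes = genes & universe
        if not term_genes:
            continue
        k = len(partner_set & term_genes)
        p = float(stats.hypergeom.sf(k - 1, M, len(term_genes), N))
        rows.append((term, len(term_genes), k, p, ",".join(sorted(partner_set & term_genes))))
    tab = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "p", "genes"]
    ).set_index("term")
    if len(tab):
        tab["q"] = bh_adjust(tab["p"])
        tab = tab[["term_size", "overlap", "p", "q", "genes"]].sort_values(["q", "p"])
    else:
        tab["q"] = []
    return GOEnrichment(table=tab)


def predict_function(
    expr: ExpressionMatrix,
    focal: str,
    go_map: dict[str, set[str]],
    method: str = "spearman",
    alpha_q: float = 0.05,
    min_abs_r: float = 0.3,
    candidate_ids: Optional[Iterable[str]] = None,
) -> tuple[CoexpressionNetwork, GOEnrichment]:
    """Co-expression network construction followed by GO enrichment."""
    net = coexpression_partners(
        expr, focal, method=method, alpha_q=alpha_q, min_abs_r=min_abs_r,
        candidate_ids=candidate_ids,
    )
    universe = [c for c in (candidate_ids or expr.feature_ids) if c != focal]
    if not net.partner_ids:
        return net, GOEnrichment(
            table=pd.DataFrame(columns=["term_size", "overlap", "p", "q", "genes"])
        )
    enrich = go_enrichment(net.partner_ids, go_map, universe)
    return net, enrich


def read_go_map(path: str) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> term -> gene-set mapping."""
    go: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            go.setdefault(parts[0], set()).add(parts[1])
    return go
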