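"""Expression containers, FPKM conversion, and tumor-vs-normal DE testing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VALID_UNITS = ("counts", "FPKM", "log2_intensity")


@dataclass
class ExpressionMatrix:
    """Features x samples non-negative matrix with per-sample metadata.

    ``sample_meta`` is indexed by sample id and may carry ``group``
    (tumor/normal), ``cohort`` and ``platform`` columns.  ``unit`` tags the
    scale of the values (raw counts, FPKM, or log2 microarray intensity).
    """

    values_frame: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    unit: str = "FPKM"

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")
        if self.values_frame.index.has_duplicates or self.values_frame.columns.has_duplicates:
            raise ValueError("duplicate feature or sample ids")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=self.values_frame.columns)
        missing = set(self.values_frame.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from sample_meta: {sorted(missing)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values_frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values_frame.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta has no 'group' column")
        return list(self.sample_meta.index[self.sample_meta["group"] == group])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values_frame[samples], self.sample_meta.loc[samples], self.unit
        )

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values_frame.loc[list(features)], self.sample_meta, self.unit
        )

    @classmethod
    def read_tsv(
        cls, path: str, meta_path: Optional[str] = None, unit: str = "FPKM"
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = (
            pd.read_csv(meta_path, sep="\t", index_col=0)
            if meta_path
            else pd.DataFrame(index=values.columns)
        )
        return cls(values, meta, unit)

    def to_tsv(self, path: str) -> None:
        self.values_frame.to_csv(path, sep="\t")


def counts_to_fpkm(
    counts: pd.DataFrame,
    feature_lengths: pd.Series,
    library_sizes: Optional[pd.Series] = None,
    sample_meta: Optional[pd.DataFrame] = None,
) -> ExpressionMatrix:
    """Convert raw counts to FPKM: ``1e9 * c / (library_size * length_nt)``.

    Library sizes default to the per-sample column sums.
    """
    lengths = feature_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("feature lengths missing for some features")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    fpkm = 1e9 * counts.div(library_sizes, axis=1).div(lengths, axis=0)
    meta = sample_meta if sample_meta is not None else pd.DataFrame(index=counts.columns)
    return ExpressionMatrix(fpkm, meta, unit="FPKM")


@dataclass
class DEResult:
    """Per-feature differential-expression table (tumor vs normal)."""

    table: pd.DataFrame  # columns: lfc, stat, p, q, direction

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "down"])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    method: str = "wilcoxon",
    alpha_q: float = 0.05,
    min_abs_lfc: float = 1.0,
    paired: bool = False,
) -> DEResult:
    """Two-sided tumor-vs-normal test per feature on log2(x+1) values.

    ``wilcoxon`` is the rank-sum (Mann-Whitney) test, or the signed-rank
    test in ``paired`` mode; ``t_log`` is Welch's t-test on the log values.
    Direction calls require both BH q <= ``alpha_q`` and |log2 fold change|
    >= ``min_abs_lfc``.
    """
    if method not in ("wilcoxon", "t_log"):
        raise ValueError(f"unknown method {method!r}")
    tumors = expr.samples_in_group("tumor")
    normals = expr.samples_in_group("normal")
    if not tumors or not normals:
        raise ValueError("both tumor and normal groups are required")
    if min(len(tumors), len(normals)) < 3:
        raise ValueError("need >= 3 samples per group")

    vals = expr.values_frame
    if expr.unit == "log2_intensity":
        log_t = vals[tumors].to_numpy(float)
        log_n = vals[normals].to_numpy(float)
    else:
        log_t = np.log2(vals[tumors].to_numpy(float) + 1.0)
        log_n = np.log2(vals[normals].to_numpy(float) + 1.0)
    lfc = log_t.mean(axis=1) - log_n.mean(axis=1)

    if paired:
        if len(tumors) != len(normals):
            raise ValueError("paired mode requires equal group sizes in pair order")
        res = stats.wilcoxon(log_t, log_n, axis=1, zero_method="wilcox")
        stat, p = res.statistic, res.pvalue
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(log_t, log_n, axis=1, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    else:
        res = stats.ttest_ind(log_t, log_n, axis=1, equal_var=False)
        stat, p = res.statistic, res.pvalue

    p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
    q = bh_adjust(p)
    direction = np.where(
        (q <= alpha_q) & (lfc >= min_abs_lfc),
        "up",
        np.where((q <= alpha_q) & (lfc <= -min_abs_lfc), "down", "ns"),
    )
    table = pd.DataFrame(
        {"lfc": lfc, "stat": stat, "p": p, "q": q, "direction": direction},
        index=vals.index,
    )
    return DEResult(table)
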