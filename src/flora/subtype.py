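"""lncRNA-based tumor subtyping.

Consensus clustering (Monti-style resampling of a base k-means) over
tumor-specific lncRNA expression defines the subtypes; one-vs-rest
rank tests call per-subtype marker lncRNAs; Fisher's exact test measures
enrichment of categorical sample annotations per subtype; and a linear
SVM transfers the subtype labels to external cohorts profiled on other
platforms after within-cohort per-feature standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from .quantify_de import ExpressionMatrix, bh_adjust


@dataclass
class ConsensusResult:
    """Consensus-clustering output at one k."""

    k: int
    labels: pd.Series  # sample -> cluster id (0..k-1)
    consensus_matrix: pd.DataFrame  # samples x samples in [0,1]
    mean_within_consensus: float
    cdf_area: float


def _log_standardize(expr: ExpressionMatrix) -> pd.DataFrame:
    """log2(x+1) then per-feature z-score; samples in rows."""
    vals = expr.values_frame
    if expr.unit == "log2_intensity":
        logged = vals.to_numpy(float)
    else:
        logged = np.log2(vals.to_numpy(float) + 1.0)
    sd = logged.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all features have zero variance")
    keep = sd > 0
    z = (logged[keep] - logged[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z.T, index=vals.columns, columns=vals.index[keep])


def consensus_cluster(
    expr: ExpressionMatrix,
    k_range: Iterable[int] = (2, 3, 4, 5),
    n_resamples: int = 250,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> tuple[dict[int, ConsensusResult], int]:
    """Resampled k-means consensus clustering over standardized log expression.

    For each k and resample, a ``subsample_frac`` fraction of samples is
    clustered by k-means; the consensus matrix is the fraction of co-sampled
    runs in which two samples co-cluster.  Final labels come from average-
    linkage hierarchical clustering of 1 - consensus.  k is selected by the
    largest relative increase in consensus-CDF area (delta-area criterion).
    """
    if n_resamples < 20:
        raise ValueError("n_resamples must be >= 20")
    k_range = sorted(set(k_range))
    X = _log_standardize(expr).to_numpy()
    samples = list(expr.sample_ids)
    n = len(samples)
    if n < 3 * max(k_range):
        raise ValueError(f"{n} samples too few for k up to {max(k_range)}")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))

    results: dict[int, ConsensusResult] = {}
    areas: dict[int, float] = {}
    for k in k_range:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(
                n_clusters=k, n_init=3, random_state=int(rng.integers(2**31))
            ).fit(X[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            cosampled[np.ix_(idx, idx)] += 1
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2
        hc = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        ).fit(1.0 - consensus)
        labels = pd.Series(hc.labels_, index=samples, name="subtype")
        within = _mean_within_consensus(consensus, hc.labels_)
        area = _cdf_area(consensus)
        areas[k] = area
        results[k] = ConsensusResult(
            k=k,
            labels=labels,
            consensus_matrix=pd.DataFrame(consensus, index=samples, columns=samples),
            mean_within_consensus=within,
            cdf_area=area,
        )

    selected = _select_k(areas)
    return results, selected


def _mean_within_consensus(consensus: np.ndarray, labels: np.ndarray) -> float:
    vals = []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) > 1:
            block = consensus[np.ix_(idx, idx)]
            vals.append(block[np.triu_indices(len(idx), k=1)].mean())
    return float(np.mean(vals)) if vals else 1.0


def _cdf_area(consensus: np.ndarray) -> float:
    tri = consensus[np.triu_indices(consensus.shape[0], k=1)]
    xs = np.sort(tri)
    cdf = np.arange(1, len(xs) + 1) / len(xs)
    return float(np.trapezoid(cdf, xs))


def _select_k(areas: dict[int, float], min_rel_delta: float = 0.1) -> int:
    """Largest k whose relative consensus-CDF-area gain is still substantial.

    The relative delta-area curve drops sharply once k exceeds the true
    cluster count; the elbow is the last k gaining at least
    ``min_rel_delta`` of the previous area.
    """
    ks = sorted(areas)
    selected = ks[0]
    for prev, k in zip(ks, ks[1:]):
        base = areas[prev] if areas[prev] > 0 else 1e-12
        if (areas[k] - areas[prev]) / base >= min_rel_delta:
            selected = k
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# subtype markers


def subtype_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    alpha_q: float = 0.05,
    min_cluster_size: int = 3,
) -> dict[int, list[str]]:
    """Per-subtype enriched features by one-vs-rest rank-sum tests.

    BH correction runs across all (feature, cluster) tests; a feature is
    enriched where q <= ``alpha_q`` with a positive one-vs-rest log-fold
    change, and may mark only the cluster with its largest effect.
    """
    labels = labels.reindex(expr.sample_ids).dropna()
    clusters = [
        c for c, size in labels.value_counts().items() if size >= min_cluster_size
    ]
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters of usable size")
    logged = np.log2(expr.values_frame[labels.index].to_numpy(float) + 1.0)
    feats = expr.feature_ids
    rows = []
    for c in clusters:
        mask = (labels == c).to_numpy()
        res = stats.mannwhitneyu(
            logged[:, mask], logged[:, ~mask], axis=1, alternative="two-sided"
        )
        lfc = logged[:, mask].mean(axis=1) - logged[:, ~mask].mean(axis=1)
        p = np.nan_to_num(np.asarray(res.pvalue, float), nan=1.0)
        for f, l, pv in zip(feats, lfc, p):
            rows.append((f, c, l, pv))
    tab = pd.DataFrame(rows, columns=["feature", "cluster", "lfc", "p"])
    tab["q"] = bh_adjust(tab["p"])
    hits = tab[(tab["q"] <= alpha_q) & (tab["lfc"] > 0)]
    best = hits.loc[hits.groupby("feature")["lfc"].idxmax()]
    out: dict[int, list[str]] = {c: [] for c in clusters}
    for _, row in best.iterrows():
        out[row["cluster"]].append(row["feature"])
    return {c: sorted(v) for c, v in out.items()}


# ---------------------------------------------------------------------------
# categorical enrichment


def fisher_enrichment(
    labels: pd.Series, categories: pd.Series
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per (cluster, category) 2x2 table.

    Rows: cluster, category, in-cluster-with-category count, table margins,
    odds ratio (inf allowed), exact p and BH q across all tests.
    """
    shared = labels.index.intersection(categories.dropna().index)
    if len(shared) == 0:
        raise ValueError("labels and categories share no samples")
    lab = labels.loc[shared]
    cat = categories.loc[shared]
    rows = []
    for c in sorted(lab.unique()):
        in_c = lab == c
        for v in sorted(cat.unique()):
            has = cat == v
            if has.sum() == 0:
                continue
            a = int((in_c & has).sum())
            b = int((in_c & ~has).sum())
            cc = int((~in_c & has).sum())
            d = int((~in_c & ~has).sum())
            odds, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
            rows.append((c, v, a, b, cc, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["cluster", "category", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    out["q"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# cross-cohort transfer


@dataclass
class SubtypeClassifier:
    """Linear-SVM subtype classifier over platform-shared features.

    Features are standardized per cohort (per-feature z-score within the
    cohort being predicted), which absorbs affine platform distortions.
    """

    features: list[str]
    model: SVC
    classes: list
    cv_accuracy: float
    train_cohort: Optional[str] = None

    def _normalize(self, expr: ExpressionMatrix) -> np.ndarray:
        vals = expr.values_frame.reindex(self.features)
        if vals.isna().any().any():
            missing = vals.index[vals.isna().any(axis=1)]
            raise ValueError(f"features missing from matrix: {list(missing)[:5]}")
        if expr.unit == "log2_intensity":
            logged = vals.to_numpy(float)
        else:
            logged = np.log2(vals.to_numpy(float) + 1.0)
        mu = logged.mean(axis=1, keepdims=True)
        sd = logged.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        return ((logged - mu) / sd).T

    def predict(self, expr: ExpressionMatrix) -> pd.Series:
        X = self._normalize(expr)
        return pd.Series(self.model.predict(X), index=expr.sample_ids, name="subtype")


def train_transfer_classifier(
    train_expr: ExpressionMatrix,
    train_labels: pd.Series,
    test_feature_ids: Iterable[str],
    min_shared_features: int = 10,
    min_class_size: int = 5,
    C: float = 1.0,
    seed: int = 0,
    cv: int = 5,
) -> SubtypeClassifier:
    """Fit the one-vs-rest linear SVM on platform-shared features."""
    shared = [f for f in train_expr.feature_ids if f in set(test_feature_ids)]
    if len(shared) < min_shared_features:
        raise ValueError(
            f"only {len(shared)} shared features; >= {min_shared_features} required"
        )
    labels = train_labels.reindex(train_expr.sample_ids).dropna()
    counts = labels.value_counts()
    if (counts < min_class_size).any():
        small = counts[counts < min_class_size]
        raise ValueError(f"training classes too small: {small.to_dict()}")
    sub = ExpressionMatrix(
        train_expr.values_frame.loc[shared, labels.index],
        train_expr.sample_meta.loc[labels.index],
        train_expr.unit,
    )
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=seed)
    stub = SubtypeClassifier(
        features=shared, model=clf, classes=[], cv_accuracy=float("nan")
    )
    X = stub._normalize(sub)
    y = labels.to_numpy()
    acc = float(np.mean(cross_val_score(clf, X, y, cv=cv)))
    clf.fit(X, y)
    return SubtypeClassifier(
        features=shared,
        model=clf,
        classes=sorted(set(y)),
        cv_accuracy=acc,
    )
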