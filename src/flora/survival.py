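"""Survival analysis: Kaplan-Meier, log-rank tests, Cox regression, and the
minimum-log-rank-P expression cut-off search.

The cut-off search dichotomizes a continuous expression vector at the value
minimizing the log-rank p over all admissible cut-offs.  Because the minimum
over many correlated tests is anti-conservative, the companion Cox p for the
*continuous* covariate is always reported alongside as the selection-free
statistic; callers should quote both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"records need a {col!r} column")
    if (records["time"] <= 0).any() or ~np.isfinite(records["time"]).all():
        raise ValueError("times must be finite and positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return records


def km_estimate(
    records: pd.DataFrame, group: Optional[str] = None
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group value, a frame with columns ``time``, ``survival``
    and ``at_risk``; survival starts at 1 and is non-increasing.
    """
    records = _validate(records)
    groups = records[group] if group else pd.Series("all", index=records.index)
    out: dict[str, pd.DataFrame] = {}
    for g, sub in records.groupby(groups):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        times = kmf.survival_function_.index.to_numpy()
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
        out[g] = pd.DataFrame({"time": times, "survival": surv, "at_risk": at_risk})
    return out


def logrank_test(
    records: pd.DataFrame, group, multivariate_with: Optional[str] = None
) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p).

    ``group`` is a column name or a label Series.  ``multivariate_with``
    crosses the grouping with a second factor column and tests over the
    combined classification (e.g. histology x subtype).
    """
    records = _validate(records)
    labels = records[group] if isinstance(group, str) else pd.Series(group).reindex(records.index)
    if multivariate_with is not None:
        labels = labels.astype(str) + "|" + records[multivariate_with].astype(str)
    k = labels.nunique()
    if k < 2:
        raise ValueError("need >= 2 groups")
    if records["event"].sum() < 1:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(records["time"], labels, records["event"])
    return float(res.test_statistic), k - 1, float(res.p_value)


@dataclass
class CoxFit:
    """Fitted proportional-hazards model: per-covariate HR table and fit state."""

    table: pd.DataFrame  # columns: coef, hr, ci_low, ci_high, p
    log_likelihood: float
    converged: bool
    warnings: list[str]

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def cox_fit(records: pd.DataFrame, covariates: Iterable[str]) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton iterations).

    Non-convergence and separation are flagged, never silently returned.
    """
    records = _validate(records)
    covariates = list(covariates)
    df = records[["time", "event"] + covariates].dropna()
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    if df["event"].sum() < len(covariates) + 1:
        raise ValueError("fewer events than covariates + 1")
    cph = CoxPHFitter()
    msgs: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            return CoxFit(
                table=pd.DataFrame(
                    index=covariates, columns=["coef", "hr", "ci_low", "ci_high", "p"]
                ),
                log_likelihood=float("nan"),
                converged=False,
                warnings=[str(exc)],
            )
        msgs = [str(w.message) for w in caught]
    if any("convergence" in m.lower() or "separation" in m.lower() for m in msgs):
        converged = False
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    return CoxFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        warnings=msgs,
    )


# ---------------------------------------------------------------------------
# minimum-p cut-off search


def _logrank_scan(
    order_time: np.ndarray, order_event: np.ndarray, in_high: np.ndarray
) -> np.ndarray:
    """Two-group log-rank chi-squares for many groupings at once.

    ``order_time``/``order_event`` are sorted by time; ``in_high`` is a
    boolean (n, K) matrix whose columns are candidate high-group masks.
    Observed-minus-expected sums with hypergeometric variance accumulate at
    each distinct event time, vectorized over the K columns; cross-checked
    against the generic k-group test in the suite.
    """
    n = len(order_time)
    H = in_high.astype(float)
    if H.ndim == 1:
        H = H[:, None]
    ev = order_event.astype(float)
    # start index of each distinct-time block
    starts = np.flatnonzero(np.r_[True, order_time[1:] != order_time[:-1]])
    counts = np.diff(np.r_[starts, n])
    d = np.add.reduceat(ev, starts)  # deaths per time
    d_high = np.add.reduceat(ev[:, None] * H, starts, axis=0)
    c_high = np.add.reduceat(H, starts, axis=0)
    at_risk = n - np.r_[0, np.cumsum(counts)[:-1]]
    tot_high = H.sum(axis=0)
    at_risk_high = tot_high[None, :] - np.vstack(
        [np.zeros_like(tot_high), np.cumsum(c_high, axis=0)[:-1]]
    )
    frac = at_risk_high / at_risk[:, None]
    use = d > 0
    o_minus_e = ((d_high - d[:, None] * frac) * use[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = (
            d[:, None]
            * frac
            * (1 - frac)
            * np.where(at_risk > 1, (at_risk - d) / np.maximum(at_risk - 1, 1), 0.0)[
                :, None
            ]
        )
    var = (var_t * use[:, None]).sum(axis=0)
    chi2 = np.where(var > 0, o_minus_e**2 / np.maximum(var, 1e-300), 0.0)
    return chi2


def _two_group_logrank_chi2(
    order_time: np.ndarray, order_event: np.ndarray, in_high: np.ndarray
) -> float:
    """Single-mask convenience wrapper around :func:`_logrank_scan`."""
    return float(_logrank_scan(order_time, order_event, in_high[:, None])[0])


def optimal_cutoff(
    records: pd.DataFrame,
    expression: pd.Series,
    min_group_frac: float = 0.1,
) -> dict:
    """Expression cut-off minimizing the log-rank p between high/low groups.

    Scans every midpoint between adjacent distinct expression values that
    leaves at least ``min_group_frac`` of the samples in each group.
    Returns the chosen cut-off, its log-rank p (uncorrected for the scan —
    an optimistic, selection-biased quantity by construction), the Cox p of
    the continuous expression covariate, and the high/low group labels.
    """
    from scipy import stats as _st

    records = _validate(records)
    if not (0 < min_group_frac <= 0.5):
        raise ValueError("min_group_frac must be in (0, 0.5]")
    expr = expression.reindex(records.index)
    if expr.isna().any():
        raise ValueError("expression missing for some records")
    values = expr.to_numpy(float)
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("expression is constant")
    n = len(values)
    order = np.argsort(records["time"].to_numpy())
    t_sorted = records["time"].to_numpy()[order]
    e_sorted = records["event"].to_numpy()[order].astype(bool)
    v_sorted = values[order]

    cuts = (uniq[:-1] + uniq[1:]) / 2
    n_high = (values[:, None] > cuts[None, :]).sum(axis=0)
    admissible = np.minimum(n_high, n - n_high) >= min_group_frac * n
    cuts = cuts[admissible]
    if cuts.size == 0:
        raise ValueError("no admissible cut-off under min_group_frac")
    masks = v_sorted[:, None] > cuts[None, :]
    chi2 = _logrank_scan(t_sorted, e_sorted, masks)
    ps = _st.chi2.sf(chi2, df=1)
    best_i = int(np.argmin(ps))
    best_cut, best_p = float(cuts[best_i]), float(ps[best_i])

    cox_df = records[["time", "event"]].copy()
    cox_df["expression"] = values
    fit = cox_fit(cox_df, ["expression"])
    groups = pd.Series(
        np.where(values > best_cut, "high", "low"), index=records.index, name="group"
    )
    return {
        "cutoff": float(best_cut),
        "p_logrank": best_p,
        "p_cox": float(fit.table.loc["expression", "p"]) if fit.converged else float("nan"),
        "groups": groups,
    }
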