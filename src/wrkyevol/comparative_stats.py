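"""Correlation grids and duplicate-pair expression-divergence statistics.

Evolutionary-rate / feature / expression relationships are summarized as
Pearson correlation grids with the conventional star annotation
(* p < 0.05, ** p < 0.01, no multiple-testing correction by default).
Expression divergence of a duplicate pair is measured per tissue as the
absolute difference of log2(RPKM + pseudocount); a tissue is called
divergent at a two-fold difference (delta >= 1 in log2 units).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RATE_VARS = ("ks", "ka", "ratio")
FEATURE_VARS = ("fop", "length_aa", "gc1", "gc2", "gc3")


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    if not math.isnan(p) and p < 0.01:
        return "**"
    if not math.isnan(p) and p < 0.05:
        return "*"
    return ""


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    var_x: str = "x",
    var_y: str = "y",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation over complete cases; p is NA below n = 3 or for a
    constant argument."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y differ in length")
    mask = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[mask], ya[mask]
    n = len(xa)
    nan = float("nan")

    def _near_constant(v: np.ndarray) -> bool:
        scale = max(np.max(np.abs(v)), 1.0)
        return bool(np.std(v) <= 1e-13 * scale)

    if n < 2 or _near_constant(xa) or _near_constant(ya):
        return CorrelationResult(var_x, var_y, nan, nan, n)
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown method {method!r}")
    if n < 3:
        p = nan
    return CorrelationResult(var_x, var_y, float(r), float(p), n)


def two_sample_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; (NaN, NaN) with fewer than two values in
    either sample."""
    xa = pd.Series(x, dtype=float).dropna()
    ya = pd.Series(y, dtype=float).dropna()
    if len(xa) < 2 or len(ya) < 2:
        return float("nan"), float("nan")
    stat, p = stats.mannwhitneyu(xa, ya, alternative="two-sided")
    return float(stat), float(p)


def _collapse_pair(values_a: pd.Series, values_b: pd.Series, how: str) -> pd.Series:
    if how == "mean":
        return (values_a + values_b) / 2.0
    if how == "min":
        return np.minimum(values_a, values_b)
    if how == "max":
        return np.maximum(values_a, values_b)
    if how == "first":
        return values_a
    raise ValueError(f"unknown collapse {how!r}")


def pair_feature_frame(
    pairs: pd.DataFrame,
    features: pd.DataFrame,
    collapse: str = "mean",
) -> pd.DataFrame:
    """Join member-level features onto pairs (columns ``a``/``b``),
    collapsing the two members (default: mean)."""
    out = pairs.reset_index(drop=True).copy()
    for col in FEATURE_VARS:
        if col not in features.columns:
            continue
        fa = features[col].reindex(out["a"]).reset_index(drop=True)
        fb = features[col].reindex(out["b"]).reset_index(drop=True)
        out[col] = _collapse_pair(fa, fb, collapse)
    return out


def correlation_grid(
    frame: pd.DataFrame,
    row_vars: Sequence[str],
    col_vars: Sequence[str],
    method: str = "pearson",
) -> dict[str, pd.DataFrame]:
    """Grid of pairwise correlations; returns ``r``, ``p``, ``n`` and a
    star-annotated ``pretty`` frame."""
    r = pd.DataFrame(index=list(row_vars), columns=list(col_vars), dtype=float)
    p = r.copy()
    n = pd.DataFrame(index=list(row_vars), columns=list(col_vars), dtype=int)
    pretty = pd.DataFrame(index=list(row_vars), columns=list(col_vars), dtype=object)
    for rv in row_vars:
        for cv in col_vars:
            res = correlate(frame[rv], frame[cv], rv, cv, method=method)
            r.loc[rv, cv] = res.r
            p.loc[rv, cv] = res.p
            n.loc[rv, cv] = res.n
            pretty.loc[rv, cv] = (
                "NA" if math.isnan(res.r) else f"{res.r:.3f}{res.stars}"
            )
    return {"r": r, "p": p, "n": n, "pretty": pretty}


def rate_feature_matrix(
    rates: pd.DataFrame,
    features: pd.DataFrame,
    collapse: str = "mean",
    method: str = "pearson",
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-relation correlation grids of {Ks, Ka, Ka/Ks} x gene features.

    ``rates`` carries one row per retained pair (``a``, ``b``,
    ``relation``, ``ka``, ``ks``, ``ratio``); pair features are the mean of
    the two members unless another collapse is requested.
    """
    joined = pair_feature_frame(rates, features, collapse)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    feature_cols = [c for c in FEATURE_VARS if c in joined.columns]
    for relation, sub in joined.groupby("relation"):
        out[relation] = correlation_grid(sub, RATE_VARS, feature_cols, method)
    return out


def log_expression(
    expr: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(RPKM + pseudocount); the pseudocount handles zero RPKM."""
    if (expr.fillna(0) < 0).any().any():
        raise ValueError("negative expression values")
    return np.log2(expr + pseudocount)


def expression_divergence(
    pairs: Iterable,
    expr: pd.DataFrame,
    pseudocount: float = 1.0,
    threshold: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-tissue expression divergence of duplicate pairs.

    ``pairs`` yields ``(a, b)`` tuples or objects with ``a``/``b``
    attributes.  For each pair and tissue the absolute log2 difference is
    computed; deltas at or above ``threshold`` (default 1 = two-fold) mark
    a divergent tissue.  Pairs with a member missing from the matrix are
    skipped (with a count in the summary).  The cohort summary gives the
    fraction of pairs with at least one divergent tissue, plus per-tissue
    divergence fractions.
    """
    logx = log_expression(expr, pseudocount)
    tissues = list(logx.columns)
    rows = []
    skipped = 0
    per_tissue_divergent = pd.Series(0.0, index=tissues)
    for pair in pairs:
        a, b = (pair.a, pair.b) if hasattr(pair, "a") else tuple(pair)[:2]
        if a not in logx.index or b not in logx.index:
            skipped += 1
            continue
        delta = (logx.loc[a] - logx.loc[b]).abs()
        divergent = delta >= threshold
        per_tissue_divergent += divergent.astype(float)
        row = {"a": a, "b": b,
               "divergent_tissues": int(divergent.sum()),
               "fraction_divergent": float(divergent.mean()),
               "max_delta": float(delta.max())}
        for t in tissues:
            row[f"delta_{t}"] = float(delta[t])
        rows.append(row)
    table = pd.DataFrame(rows)
    n_pairs = len(table)
    summary = {
        "n_pairs": n_pairs,
        "n_skipped": skipped,
        "threshold": threshold,
        "pseudocount": pseudocount,
        "fraction_pairs_divergent": (
            float((table["divergent_tissues"] >= 1).mean()) if n_pairs else float("nan")
        ),
        "per_tissue_fraction": (
            (per_tissue_divergent / n_pairs) if n_pairs else per_tissue_divergent * float("nan")
        ),
    }
    return table, summary


def pair_expression_frame(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    pseudocount: float = 1.0,
    collapse: str = "mean",
) -> pd.DataFrame:
    """Pair-level log2 expression per tissue (mean of the two members)."""
    logx = log_expression(expr, pseudocount)
    out = pairs.reset_index(drop=True).copy()
    for t in logx.columns:
        ea = logx[t].reindex(out["a"]).reset_index(drop=True)
        eb = logx[t].reindex(out["b"]).reset_index(drop=True)
        out[f"expr_{t}"] = _collapse_pair(ea, eb, collapse)
    return out


def rate_expression_matrix(
    rates: pd.DataFrame,
    features: pd.DataFrame,
    expr: pd.DataFrame,
    pseudocount: float = 1.0,
    collapse: str = "mean",
    method: str = "pearson",
) -> dict[str, pd.DataFrame]:
    """Correlations of {Ks, Ka, Ka/Ks, Fop, length, GC1-3} x tissue
    expression across duplicate pairs (pair values = member means)."""
    joined = pair_feature_frame(rates, features, collapse)
    joined = pair_expression_frame(joined, expr, pseudocount, collapse)
    tissue_cols = [c for c in joined.columns if c.startswith("expr_")]
    row_vars = [v for v in (*RATE_VARS, *FEATURE_VARS) if v in joined.columns]
    grids = correlation_grid(joined, row_vars, tissue_cols, method)
    for key in grids:
        grids[key].columns = [c.removeprefix("expr_") for c in grids[key].columns]
    return grids
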