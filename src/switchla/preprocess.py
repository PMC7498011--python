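"""Probe-level preprocessing and differential expression.

Turns raw probe tables into the analysis-ready gene x sample matrix:
duplicate probes are collapsed to per-gene means, the matrix is restricted to
a gene list of interest (e.g. an immune-annotation set), optional sample-wise
quantile normalization removes array-level distribution differences, and each
gene row is normal-quantile transformed and standardized for the screening
stage.

Differential expression uses a moderated two-sample t-statistic: per-gene
pooled variances ``s_g^2`` (d_g = n1 + n2 - 2 df) are shrunk toward a prior
``s0^2`` with ``d0`` prior degrees of freedom,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t = (mean1 - mean2) / (s~_g * sqrt(1/n1 + 1/n2)) is
referred to a t distribution with d0 + d_g df. The hyperparameters (d0, s0)
are estimated by closed-form method of moments on log s_g^2 across the gene
ensemble (matching the scaled-F marginal of the hierarchical model).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix

__all__ = [
    "DEGResult",
    "collapse_duplicates",
    "filter_gene_set",
    "quantile_normalize",
    "normal_quantile_transform",
    "standardize",
    "transform_matrix",
    "moderated_t_test",
    "moderated_t_by_disease",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    mean_case: float
    mean_control: float
    moderated_t: float
    p: float
    is_deg: bool


def collapse_duplicates(table: pd.DataFrame, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene by the arithmetic mean.

    ``table`` is a probe x sample DataFrame (probe ids in the index).
    Probes absent from ``probe_map`` are dropped (count logged). Gene order
    follows the first occurrence of each gene among the mapped probes.
    """
    mapped = [p for p in table.index if p in probe_map]
    if not mapped:
        raise ValueError("no probe in the table is present in the probe map")
    dropped = table.shape[0] - len(mapped)
    if dropped:
        logger.info("collapse_duplicates: dropped %d unmapped probes", dropped)
    sub = table.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="gene_id")
    order = list(dict.fromkeys(genes))  # first-occurrence order
    collapsed = sub.groupby(genes, sort=False).mean().loc[order]
    return ExpressionMatrix(collapsed)


def filter_gene_set(matrix: ExpressionMatrix, keep: list[str]) -> ExpressionMatrix:
    """Restrict the matrix to ``keep`` (matrix row order preserved)."""
    if not keep:
        raise ValueError("gene list is empty")
    keep_set = set(keep)
    unknown = keep_set - set(matrix.gene_ids)
    if unknown:
        logger.warning("filter_gene_set: %d listed genes absent from the matrix", len(unknown))
    retained = [g for g in matrix.gene_ids if g in keep_set]
    if not retained:
        raise ValueError("no listed gene is present in the matrix")
    logger.info("filter_gene_set: retained %d genes", len(retained))
    return ExpressionMatrix(matrix.values.loc[retained], matrix.sample_meta)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample's values onto the mean sorted profile across samples."""
    arr = matrix.to_array()
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_genes = arr.shape[0]
    rows = np.arange(n_genes)
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_profile = np.sort(arr, axis=0).mean(axis=1)
    out = mean_profile[ranks]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.sample_meta,
    )


def normal_quantile_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform.

    The value at rank r (1-based; ties get average ranks) maps to
    Phi^{-1}((r - 0.5) / n). Invariant to strictly monotone transforms of
    tie-free input; a constant vector is rejected.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]):
        raise ValueError("constant vector: all ranks tied")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def standardize(x: np.ndarray) -> np.ndarray:
    """Centre to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def transform_matrix(matrix: ExpressionMatrix, quantile_norm: bool = False) -> ExpressionMatrix:
    """Screening-stage transform: optional sample quantile normalization,
    then per-gene normal quantile transform + standardization."""
    m = quantile_normalize(matrix) if quantile_norm else matrix
    arr = m.to_array()
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = standardize(normal_quantile_transform(arr[i]))
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.sample_meta
    )


# -- moderated t -----------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene variances.

    Under the hierarchical model, log s_g^2 = log s0^2 + log chi2_{d_g}/d_g
    - log chi2_{d0}/d0 in distribution; matching the mean and variance of
    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) gives closed-form d0, s0.
    """
    ok = s2 > 0
    if not np.any(ok):
        raise ValueError("all genes have zero variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def moderated_t_test(
    matrix: ExpressionMatrix,
    groups: dict[str, str] | pd.Series,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> list[DEGResult]:
    """Empirical-Bayes moderated two-sample t-test, one result per gene.

    ``groups`` maps sample id -> "case" / "control". ``prior_df`` overrides
    the estimated d0 (0 recovers the classical pooled t).
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    case_cols = [s for s in matrix.sample_ids if groups.get(s) == "case"]
    ctrl_cols = [s for s in matrix.sample_ids if groups.get(s) == "control"]
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if matrix.n_genes < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")

    a = matrix.values[case_cols].to_numpy(dtype=float)
    b = matrix.values[ctrl_cols].to_numpy(dtype=float)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    dg = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg

    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, dg)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2, dg)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    return [
        DEGResult(
            gene_id=g,
            mean_case=float(m1[i]),
            mean_control=float(m2[i]),
            moderated_t=float(t[i]),
            p=float(p[i]),
            is_deg=bool(p[i] < alpha),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def moderated_t_by_disease(matrix: ExpressionMatrix, alpha: float = 0.05) -> dict[str, list[DEGResult]]:
    """Run the moderated t separately for each disease (case vs control)."""
    if matrix.sample_meta is None:
        raise ValueError("matrix has no sample metadata")
    out: dict[str, list[DEGResult]] = {}
    for disease in matrix.diseases():
        cols = [s for s in matrix.sample_ids if matrix.sample_meta.loc[s, "disease"] == disease]
        sub = matrix.subset_samples(cols)
        grp = {s: matrix.sample_meta.loc[s, "status"] for s in cols}
        out[disease] = moderated_t_test(sub, grp, alpha=alpha)
    return out
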