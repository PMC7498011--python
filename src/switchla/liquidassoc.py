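"""Exhaustive liquid-association triplet screening.

For every ordered choice of a candidate switch gene X3 and unordered pair
(X1, X2), the screen measures how the X1–X2 Pearson correlation differs
between the samples where X3 is high and where it is low. Samples are
stratified by the rank of X3 (tertiles by default: top third = "high",
bottom third = "low"); the conditional correlations rho_high and rho_low and
their absolute difference rho_diff quantify the switch. The classical liquid
association score — the mean elementwise triple product of the (normal
quantile transformed, standardized) profiles — is attached to every triplet.

Significance of the correlation switch defaults to a Fisher-z two-sample
test of rho_high vs rho_low (the two strata are disjoint sample sets); a
permutation test that shuffles the stratum assignment is available as a
slower, assumption-free alternative. Multiplicity control is Bonferroni
(called "FDR" in parts of this literature; the thresholded quantity is a
family-wise error rate) with m = the number of enumerated triplets by
default, and a Benjamini–Hochberg option.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "Triplet",
    "ScreenConfig",
    "la_statistic",
    "conditional_correlations",
    "fisher_z_pvalue",
    "permutation_pvalue",
    "bonferroni_adjust",
    "bh_adjust",
    "screen_triplets",
    "write_triplets_tsv",
    "read_triplets_tsv",
]


@dataclass(frozen=True)
class Triplet:
    """One screened triplet: pair (x1 < x2), switch candidate x3, statistics."""

    x1: str
    x2: str
    x3: str
    rho_high: float
    rho_low: float
    rho_diff: float
    rho_diff_signed: float
    la_score: float
    p: float
    p_adj: float
    n_high: int
    n_low: int

    def genes(self) -> tuple[str, str, str]:
        return (self.x1, self.x2, self.x3)


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters.

    stratum_rule: "tertile", "median", or a float q in (0, 0.5] giving the
    per-stratum sample fraction. p_method: "fisher_z" or "permutation".
    bonferroni_m: "auto" (= number of enumerated triplets), an explicit
    integer, or "bh" for Benjamini–Hochberg. rho_diff_min is a reporting
    floor on |rho_high - rho_low|.
    """

    stratum_rule: str | float = "tertile"
    p_method: str = "fisher_z"
    n_perm: int = 1000
    rho_diff_min: float = 0.5
    bonferroni_m: int | str = "auto"
    fdr_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.stratum_rule, float) and not 0 < self.stratum_rule <= 0.5:
            raise ValueError("quantile stratum rule must be in (0, 0.5]")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.p_method not in ("fisher_z", "permutation"):
            raise ValueError(f"unknown p_method {self.p_method!r}")

    def stratum_fraction(self) -> float:
        if self.stratum_rule == "tertile":
            return 1.0 / 3.0
        if self.stratum_rule == "median":
            return 0.5
        return float(self.stratum_rule)


def la_statistic(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray) -> float:
    """Liquid association score: mean elementwise triple product.

    Inputs are assumed already normal-quantile transformed and standardized;
    the score is symmetric in x1 and x2.
    """
    x1, x2, x3 = (np.asarray(v, dtype=float) for v in (x1, x2, x3))
    if not (x1.shape == x2.shape == x3.shape) or x1.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x1.size < 3:
        raise ValueError("need at least 3 samples")
    return float(np.mean(x1 * x2 * x3))


def _stratum_sizes(n: int, fraction: float) -> int:
    k = int(math.floor(n * fraction))
    if fraction == 0.5 and n % 2 == 0:
        k = n // 2
    return k


def conditional_correlations(
    x1: np.ndarray,
    x2: np.ndarray,
    x3: np.ndarray,
    rule: str | float = "tertile",
) -> tuple[float, float, float, int, int]:
    """Pair correlations in the high and low X3 strata.

    Returns (rho_high, rho_low, rho_diff, n_high, n_low) where rho_diff is
    the absolute difference. Strata are the top/bottom ``fraction`` of
    samples ranked by x3 (tertile: fraction = 1/3).
    """
    x1, x2, x3 = (np.asarray(v, dtype=float) for v in (x1, x2, x3))
    fraction = ScreenConfig(stratum_rule=rule).stratum_fraction()
    n = x3.size
    k = _stratum_sizes(n, fraction)
    if k < 4:
        raise ValueError("each stratum needs at least 4 samples")
    order = np.argsort(x3, kind="stable")
    low_idx, high_idx = order[:k], order[n - k :]
    rhos = []
    for idx in (high_idx, low_idx):
        a, b = x1[idx], x2[idx]
        if a.std() == 0 or b.std() == 0:
            raise ValueError("zero variance within a stratum")
        rhos.append(float(np.corrcoef(a, b)[0, 1]))
    rho_high, rho_low = rhos
    return rho_high, rho_low, abs(rho_high - rho_low), k, k


def fisher_z_pvalue(rho_high: float, rho_low: float, n_high: int, n_low: int) -> float:
    """Two-sided p for a difference of correlations from disjoint strata.

    z = (atanh(rho_high) - atanh(rho_low)) / sqrt(1/(n_high-3) + 1/(n_low-3))
    against the standard normal. |rho| = 1 would send z to infinity; the
    smallest positive float is returned with a warning.
    """
    if n_high < 4 or n_low < 4:
        raise ValueError("need at least 4 samples per stratum")
    if abs(rho_high) >= 1.0 or abs(rho_low) >= 1.0:
        warnings.warn("|rho| = 1: p-value underflows, returning float minimum", stacklevel=2)
        return sys.float_info.min
    se = math.sqrt(1.0 / (n_high - 3) + 1.0 / (n_low - 3))
    z = (math.atanh(rho_high) - math.atanh(rho_low)) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def permutation_pvalue(
    x1: np.ndarray,
    x2: np.ndarray,
    x3: np.ndarray,
    rule: str | float = "tertile",
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for rho_diff: shuffle x3 across samples, recompute."""
    rng = np.random.default_rng(seed)
    _, _, obs, _, _ = conditional_correlations(x1, x2, x3, rule)
    x3 = np.asarray(x3, dtype=float)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x3)
        _, _, d, _, _ = conditional_correlations(x1, x2, perm, rule)
        if d >= obs:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def bonferroni_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    adj = np.minimum(1.0, np.asarray(p, dtype=float) * m)
    return float(adj) if np.isscalar(p) or np.ndim(p) == 0 else adj


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(1.0, ranked)
    return out


def screen_triplets(matrix: ExpressionMatrix, config: ScreenConfig = ScreenConfig()) -> list[Triplet]:
    """Enumerate and score all G * C(G-1, 2) triplets.

    The matrix must already be normal-quantile transformed and standardized
    per gene. Triplets with rho_diff >= config.rho_diff_min are returned,
    sorted by p ascending with a lexicographic (x1, x2, x3) tie-break.
    Adjusted p-values use Bonferroni with m = all enumerated triplets
    ("auto"), an explicit integer override, or Benjamini–Hochberg ("bh").
    """
    G, n = matrix.n_genes, matrix.n_samples
    if G < 3:
        raise ValueError("need at least 3 genes")
    fraction = config.stratum_fraction()
    k = _stratum_sizes(n, fraction)
    if k < 4:
        raise ValueError("each stratum needs at least 4 samples")

    arr = matrix.to_array()
    genes = matrix.gene_ids
    n_enumerated = G * math.comb(G - 1, 2)

    iu = np.triu_indices(G, k=1)
    records: list[tuple] = []
    for g in range(G):
        order = np.argsort(arr[g], kind="stable")
        low_idx, high_idx = order[:k], order[n - k :]
        with np.errstate(invalid="ignore"):
            c_high = np.corrcoef(arr[:, high_idx])
            c_low = np.corrcoef(arr[:, low_idx])
        la = (arr * arr[g]) @ arr.T / n
        rh, rl = c_high[iu], c_low[iu]
        diff = np.abs(rh - rl)
        keep = diff >= config.rho_diff_min
        # drop pairs that involve the switch gene itself
        keep &= (iu[0] != g) & (iu[1] != g)
        for i, j in zip(iu[0][keep], iu[1][keep]):
            records.append(
                (genes[i], genes[j], genes[g], c_high[i, j], c_low[i, j], la[i, j])
            )

    if config.p_method == "permutation":
        rng_seed = config.seed
        ps = []
        gene_pos = {g: i for i, g in enumerate(genes)}
        for rec_i, (g1, g2, g3, *_rest) in enumerate(records):
            ps.append(
                permutation_pvalue(
                    arr[gene_pos[g1]],
                    arr[gene_pos[g2]],
                    arr[gene_pos[g3]],
                    config.stratum_rule,
                    config.n_perm,
                    seed=rng_seed + rec_i,
                )
            )
        ps = np.asarray(ps)
    else:
        rh = np.array([r[3] for r in records])
        rl = np.array([r[4] for r in records])
        rh_c = np.clip(rh, -1 + 1e-15, 1 - 1e-15)
        rl_c = np.clip(rl, -1 + 1e-15, 1 - 1e-15)
        se = math.sqrt(2.0 / (k - 3))
        z = (np.arctanh(rh_c) - np.arctanh(rl_c)) / se
        ps = 2.0 * stats.norm.sf(np.abs(z))

    if config.bonferroni_m == "bh":
        p_adj = bh_adjust(ps) if len(records) else np.array([])
    else:
        m = n_enumerated if config.bonferroni_m == "auto" else int(config.bonferroni_m)
        p_adj = np.minimum(1.0, ps * m) if len(records) else np.array([])

    triplets = [
        Triplet(
            x1=g1,
            x2=g2,
            x3=g3,
            rho_high=float(rhi),
            rho_low=float(rlo),
            rho_diff=float(abs(rhi - rlo)),
            rho_diff_signed=float(rhi - rlo),
            la_score=float(la),
            p=float(p),
            p_adj=float(pa),
            n_high=k,
            n_low=k,
        )
        for (g1, g2, g3, rhi, rlo, la), p, pa in zip(records, ps, p_adj)
    ]
    triplets.sort(key=lambda t: (t.p, t.x1, t.x2, t.x3))
    return triplets


_TSV_COLUMNS = [
    "X1", "X2", "X3", "rho_high", "rho_low", "rho_diff", "rho_diff_signed",
    "la_score", "p", "p_adj", "n_high", "n_low",
]


def write_triplets_tsv(triplets: list[Triplet], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (t.x1, t.x2, t.x3, t.rho_high, t.rho_low, t.rho_diff, t.rho_diff_signed,
             t.la_score, t.p, t.p_adj, t.n_high, t.n_low)
            for t in triplets
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_triplets_tsv(path: str | Path) -> list[Triplet]:
    df = pd.read_csv(path, sep="\t")
    return [
        Triplet(
            x1=str(r.X1), x2=str(r.X2), x3=str(r.X3),
            rho_high=float(r.rho_high), rho_low=float(r.rho_low),
            rho_diff=float(r.rho_diff), rho_diff_signed=float(r.rho_diff_signed),
            la_score=float(r.la_score), p=float(r.p), p_adj=float(r.p_adj),
            n_high=int(r.n_high), n_low=int(r.n_low),
        )
        for r in df.itertuples()
    ]
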