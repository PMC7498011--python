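"""Pathway over-representation analysis with Holm correction and kappa grouping.

A query gene list (typically a disease's DEGs) is tested against each pathway
of a GMT-backed collection with the hypergeometric tail test; p-values are
adjusted by the Holm step-down procedure ("Bonferroni step down"). Passing
pathways (adjusted p below threshold and at least ``min_genes`` query hits)
are merged into groups by single-linkage clustering on Cohen's kappa of
their membership vectors, mirroring the term-grouping used by enrichment-map
tools. Pathway sizes are always computed against the restricted universe —
the genes actually present in the analysed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_test",
    "holm_adjust",
    "kappa_score",
    "enrich_deg_list",
    "shared_pathways",
    "write_enrichment_tsv",
]


@dataclass
class GeneSetCollection:
    """Named pathway -> member genes, plus the background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
        self.universe = set(self.universe)

    def restricted(self, genes: set[str]) -> "GeneSetCollection":
        """Restrict universe and memberships to ``genes``; drop emptied sets."""
        uni = self.universe & genes
        sets = {}
        for name, members in self.sets.items():
            kept = members & uni
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int          # query genes in the pathway
    K: int          # pathway size in the universe
    n: int          # query size
    N: int          # universe size
    p: float
    p_adj: float
    passes: bool
    group: str = ""  # kappa-group label (lowest-p member), passing sets only
    hits: tuple[str, ...] = field(default=())


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name <TAB> description <TAB> member genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not line.strip():
                continue
            name, _desc, *members = parts
            members = [m for m in members if m]
            if members:
                sets[name] = set(members)
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    uni = universe if universe is not None else set().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def hypergeometric_test(k: int, K: int, n: int, N: int, two_sided: bool = False) -> float:
    """Over-representation tail P(X >= k) for X ~ Hypergeom(N, K, n).

    ``two_sided=True`` doubles the smaller of the two tails (capped at 1),
    the construction used by some enrichment tools; the default is the plain
    upper tail.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    if not two_sided:
        return min(1.0, upper)
    lower = float(stats.hypergeom.cdf(k, N, K, n))
    return min(1.0, 2.0 * min(upper, lower))


def holm_adjust(ps: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sorted ascending, p'(i) = max_{j<=i} min(1, (m - j) * p(j)) with 0-based
    j; equals plain Bonferroni for the smallest p and never drops below the
    raw p.
    """
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, p[order] * (m - np.arange(m)))
    stepped = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = stepped
    return out


def kappa_score(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa of two membership indicator vectors over the universe."""
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    N = len(universe)
    a, b = len(set_a), len(set_b)
    both = len(set_a & set_b)
    neither = N - a - b + both
    po = (both + neither) / N
    pe = (a * b + (N - a) * (N - b)) / (N * N)
    if pe == 1.0:
        raise ValueError("chance agreement is 1 (both sets equal the universe)")
    return (po - pe) / (1.0 - pe)


def _kappa_groups(
    passing: list[EnrichmentResult],
    collection: GeneSetCollection,
    kappa_threshold: float,
) -> dict[str, str]:
    """Single-linkage grouping of passing pathways at kappa >= threshold.

    Returns pathway -> group label, the label being the lowest-p member of
    the group (ties broken by name).
    """
    names = [r.pathway for r in passing]
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            kap = kappa_score(
                collection.sets[names[i]], collection.sets[names[j]], collection.universe
            )
            if kap >= kappa_threshold:
                parent[find(names[i])] = find(names[j])

    by_root: dict[str, list[EnrichmentResult]] = {}
    for r in passing:
        by_root.setdefault(find(r.pathway), []).append(r)
    labels = {}
    for members in by_root.values():
        label = min(members, key=lambda r: (r.p, r.pathway)).pathway
        for r in members:
            labels[r.pathway] = label
    return labels


def enrich_deg_list(
    degs: list[str],
    collection: GeneSetCollection,
    min_genes: int = 3,
    threshold: float = 0.05,
    kappa_threshold: float = 0.4,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of a gene list against every pathway.

    Query genes outside the universe are dropped with a warning. ``passes``
    requires Holm-adjusted p < threshold and at least ``min_genes`` hits.
    Results are sorted by raw p ascending (ties by name).
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    query = set(degs)
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped", stacklevel=2)
        query &= collection.universe
    N = len(collection.universe)
    n = len(query)
    names = sorted(collection.sets)
    raw = []
    for name in names:
        members = collection.sets[name] & collection.universe
        hits = tuple(sorted(query & members))
        p = hypergeometric_test(len(hits), len(members), n, N, two_sided=two_sided)
        raw.append((name, hits, len(members), p))
    adj = holm_adjust([r[3] for r in raw])
    results = [
        EnrichmentResult(
            pathway=name,
            k=len(hits),
            K=K,
            n=n,
            N=N,
            p=p,
            p_adj=float(pa),
            passes=bool(pa < threshold and len(hits) >= min_genes),
            hits=hits,
        )
        for (name, hits, K, p), pa in zip(raw, adj)
    ]
    passing = [r for r in results if r.passes]
    labels = _kappa_groups(passing, collection, kappa_threshold) if passing else {}
    results = [
        EnrichmentResult(**{**r.__dict__, "group": labels.get(r.pathway, "")})
        for r in results
    ]
    results.sort(key=lambda r: (r.p, r.pathway))
    return results


def shared_pathways(per_disease: dict[str, list[str]], min_diseases: int = 5) -> list[tuple[str, int]]:
    """Pathways passing in at least ``min_diseases`` of the per-disease lists.

    Returns (pathway, disease count) sorted by count descending, then name.
    """
    if not per_disease:
        raise ValueError("need at least one disease")
    counts: dict[str, int] = {}
    for pathways in per_disease.values():
        for name in set(pathways):
            counts[name] = counts.get(name, 0) + 1
    kept = [(name, c) for name, c in counts.items() if c >= min_diseases]
    kept.sort(key=lambda x: (-x[1], x[0]))
    return kept


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.pathway, r.k, r.K, r.n, r.N, r.p, r.p_adj, r.passes, r.group, ",".join(r.hits))
            for r in results
        ],
        columns=["pathway", "k", "K", "n", "N", "p", "p_adj", "passes", "group", "hits"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
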