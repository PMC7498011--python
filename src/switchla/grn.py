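"""Mutual-information network inference with DPI pruning.

An undirected gene network is built ARACNE-style: mutual information (MI) is
computed for every gene pair, edges below a permutation-derived significance
threshold are discarded, and the data-processing inequality (DPI) removes the
weakest edge of every triangle — in a Markov chain X -> Y -> Z,
MI(X, Z) <= min(MI(X, Y), MI(Y, Z)), so the indirect X–Z edge is the strict
minimum of its triangle and can be pruned.

Two estimators are provided: a plug-in estimate on equal-frequency bins
(default, k = ceil(sqrt(n / 5)) bins per variable) and the Gaussian
closed form -0.5 * ln(1 - rho^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "GrnConfig",
    "GeneNetwork",
    "mutual_information",
    "mi_significance_threshold",
    "apply_dpi",
    "build_grn",
    "write_network_tsv",
    "read_network_tsv",
    "write_graphml",
]

MI_CAP = 50.0  # cap for the diverging Gaussian estimate at |rho| -> 1


@dataclass(frozen=True)
class GrnConfig:
    """estimator: "bins" (equal-frequency, k bins) or "gaussian";
    n_bins None = adaptive k = ceil(sqrt(n/5)); alpha is the permutation-null
    edge significance level; dpi_eps the DPI tolerance (0 = strict)."""

    estimator: str = "bins"
    n_bins: int | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    dpi_eps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ("bins", "gaussian"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.dpi_eps < 0:
            raise ValueError("dpi_eps must be nonnegative")


@dataclass
class GeneNetwork:
    """Undirected MI network: nodes + {frozenset(pair): (mi, p)} edges."""

    nodes: list[str]
    edges: dict[frozenset, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, (mi, _p) in self.edges.items():
            if len(pair) != 2:
                raise ValueError("self-loop or malformed edge")
            if mi < 0:
                raise ValueError("negative mutual information")

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, (mi, p) in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, mi=mi, p=p)
        return g


def _bin_indices(x: np.ndarray, k: int) -> np.ndarray:
    """Equal-frequency bin assignment (ranks split into k blocks)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * k) // x.size


def _adaptive_bins(n: int) -> int:
    return max(2, math.ceil(math.sqrt(n / 5.0)))


def mutual_information(
    x: np.ndarray, y: np.ndarray, estimator: str = "bins", n_bins: int | None = None
) -> float:
    """MI in nats between two sample vectors.

    "bins": plug-in estimate on a k x k equal-frequency contingency table.
    "gaussian": -0.5 * ln(1 - rho^2); diverges at |rho| = 1 and is capped
    at ``MI_CAP``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    if estimator == "gaussian":
        if x.std() == 0 or y.std() == 0:
            raise ValueError("constant input: correlation undefined")
        rho = float(np.corrcoef(x, y)[0, 1])
        if abs(rho) >= 1.0 - 1e-15:
            return MI_CAP
        return float(-0.5 * math.log1p(-rho * rho))
    k = n_bins or _adaptive_bins(n)
    bx, by = _bin_indices(x, k), _bin_indices(y, k)
    joint = np.zeros((k, k))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    plug_in = float(np.nansum(terms))
    # Miller-Madow first-order bias correction, floored at 0 (MI >= 0)
    return max(0.0, plug_in - (k - 1) ** 2 / (2.0 * n))


def mi_significance_threshold(matrix: ExpressionMatrix, config: GrnConfig) -> float:
    """(1 - alpha) quantile of MI over permuted gene pairs (the null)."""
    null = _null_mi_sample(matrix, config)
    return float(np.quantile(null, 1.0 - config.alpha))


def _null_mi_sample(matrix: ExpressionMatrix, config: GrnConfig) -> np.ndarray:
    if config.n_perm < 100 or config.n_perm < math.ceil(1.0 / config.alpha):
        raise ValueError("n_perm too small for the requested alpha quantile")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))
    arr = matrix.to_array()
    G, n = arr.shape
    out = np.empty(config.n_perm)
    for i in range(config.n_perm):
        a, b = rng.integers(0, G, size=2)
        y = arr[b][rng.permutation(n)]
        out[i] = mutual_information(arr[a], y, config.estimator, config.n_bins)
    return out


def apply_dpi(network: GeneNetwork, eps: float = 0.0) -> GeneNetwork:
    """Prune each triangle's strictly weakest edge (data-processing inequality).

    Edge (i, j) is removed iff some common neighbour k satisfies
    mi(i, j) < min(mi(i, k), mi(j, k)) - eps. All removals are evaluated
    against the input network, so the result is order-independent and the
    operation is idempotent.
    """
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    neighbours: dict[str, set[str]] = {n: set() for n in network.nodes}
    for pair in network.edges:
        a, b = tuple(pair)
        neighbours[a].add(b)
        neighbours[b].add(a)
    mi = {pair: v[0] for pair, v in network.edges.items()}
    to_remove = set()
    for pair in network.edges:
        a, b = tuple(pair)
        for k in neighbours[a] & neighbours[b]:
            if mi[pair] < min(mi[frozenset((a, k))], mi[frozenset((b, k))]) - eps:
                to_remove.add(pair)
                break
    kept = {pair: v for pair, v in network.edges.items() if pair not in to_remove}
    return GeneNetwork(nodes=list(network.nodes), edges=kept)


def build_grn(matrix: ExpressionMatrix, config: GrnConfig = GrnConfig()) -> GeneNetwork:
    """All-pairs MI -> permutation significance threshold -> DPI pruning."""
    arr = matrix.to_array()
    genes = matrix.gene_ids
    G = len(genes)
    null = _null_mi_sample(matrix, config)
    threshold = float(np.quantile(null, 1.0 - config.alpha))
    edges: dict[frozenset, tuple[float, float]] = {}
    for i in range(G):
        for j in range(i + 1, G):
            mi = mutual_information(arr[i], arr[j], config.estimator, config.n_bins)
            if mi > threshold:
                p = (1.0 + np.sum(null >= mi)) / (config.n_perm + 1.0)
                edges[frozenset((genes[i], genes[j]))] = (mi, float(p))
    network = GeneNetwork(nodes=list(genes), edges=edges)
    return apply_dpi(network, config.dpi_eps)


def write_network_tsv(network: GeneNetwork, path: str | Path) -> None:
    rows = sorted(
        (*sorted(pair), mi, pv) for pair, (mi, pv) in network.edges.items()
    )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "p"])
    with open(path, "w") as fh:
        fh.write("# nodes=" + ",".join(network.nodes) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_network_tsv(path: str | Path) -> GeneNetwork:
    nodes: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# nodes="):
            nodes = first[len("# nodes=") :].strip().split(",")
    df = pd.read_csv(path, sep="\t", comment="#")
    edges = {
        frozenset((str(r.gene_a), str(r.gene_b))): (float(r.mi), float(r.p))
        for r in df.itertuples()
    }
    if not nodes:
        nodes = sorted({g for pair in edges for g in pair})
    return GeneNetwork(nodes=nodes, edges=edges)


def write_graphml(network: GeneNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), path)
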