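"""Integration of screening, network and enrichment into final triplet calls.

A screened triplet is *statistically significant* when its adjusted p falls
below the configured threshold. It is *biologically relevant* when both of
two independent gates agree:

* **pathway coherence** — the regulated pair (X1, X2) are co-members of at
  least one pathway that is significantly enriched in at least one disease's
  DEG list; and
* **network support** — the triplet's regulatory relations are detectable in
  the MI network (default rule: edges X3–X1 and X3–X2 both present, treating
  the switch gene as the regulator; ``any_edge`` and ``connected`` are
  weaker alternatives).

The module also computes the screen's validation statistics: the per-gene X3
"event rate" among significant triplets against the uniform 1/G baseline
(concentration of triplets on few switch genes), and the DEG fraction among
X3 genes versus among all genes.

:func:`run_pipeline` chains every stage — simulation or file loading,
preprocessing, differential expression, triplet screening, network
inference, enrichment, integration — from a single config dict (or YAML
file) and writes all stage TSVs plus a run log and human-readable summary.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, read_expression_tsv, read_gene_list, read_probe_map
from .enrich import (
    EnrichmentResult,
    GeneSetCollection,
    enrich_deg_list,
    read_gmt,
    shared_pathways,
    write_enrichment_tsv,
)
from .grn import GeneNetwork, GrnConfig, build_grn, write_network_tsv
from .liquidassoc import ScreenConfig, Triplet, screen_triplets, write_triplets_tsv
from .preprocess import (
    DEGResult,
    collapse_duplicates,
    filter_gene_set,
    moderated_t_by_disease,
    transform_matrix,
)
from .synthdata import StudySpec, TripletSpec, generate_study, write_truth

__all__ = [
    "RelevanceCall",
    "ValidationSummary",
    "pathway_coherent",
    "grn_supported",
    "x3_event_rate",
    "deg_x3_proportion",
    "call_relevant_triplets",
    "run_pipeline",
    "toy_config",
]

SUPPORT_RULES = ("both_x3_edges", "any_edge", "connected")


@dataclass(frozen=True)
class RelevanceCall:
    triplet: Triplet
    pathway_coherent: bool
    coherent_pathways: tuple[str, ...]
    grn_supported: bool
    supporting_edges: tuple[tuple[str, str], ...]
    diseases_involved: tuple[str, ...] = ()

    @property
    def headline(self) -> bool:
        return self.pathway_coherent and self.grn_supported


@dataclass
class ValidationSummary:
    """X3 event-rate curve plus DEG overlap fractions."""

    thresholds: list[float]
    observed_rate: list[float]   # mean per-gene X3 rate among genes seen as X3
    n_significant: list[int]
    random_rate: float           # 1 / G
    deg_fraction_all: float
    deg_fraction_x3: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed_rate": self.observed_rate,
                "n_significant": self.n_significant,
                "random_rate": self.random_rate,
            }
        )


def pathway_coherent(
    triplet: Triplet,
    enrichments: dict[str, list[EnrichmentResult]],
    collection: GeneSetCollection,
) -> tuple[bool, tuple[str, ...]]:
    """True iff X1 and X2 co-occur in a pathway passing in >= 1 disease."""
    passing = {r.pathway for results in enrichments.values() for r in results if r.passes}
    names = tuple(
        sorted(
            name
            for name in passing
            if triplet.x1 in collection.sets.get(name, ())
            and triplet.x2 in collection.sets.get(name, ())
        )
    )
    return bool(names), names


def grn_supported(
    triplet: Triplet, network: GeneNetwork, rule: str = "both_x3_edges"
) -> tuple[bool, tuple[tuple[str, str], ...]]:
    """Is the triplet's regulatory structure detectable in the network?

    both_x3_edges: X3–X1 and X3–X2 both present (switch gene as regulator);
    any_edge: any of the three pairs; connected: the three genes lie in one
    connected component of the full network.
    """
    if rule not in SUPPORT_RULES:
        raise ValueError(f"unknown support rule {rule!r}; choose from {SUPPORT_RULES}")
    x1, x2, x3 = triplet.x1, triplet.x2, triplet.x3
    present = [
        (a, b)
        for (a, b) in ((x3, x1), (x3, x2), (x1, x2))
        if network.has_edge(a, b)
    ]
    if rule == "both_x3_edges":
        ok = network.has_edge(x3, x1) and network.has_edge(x3, x2)
    elif rule == "any_edge":
        ok = bool(present)
    else:
        g = network.to_networkx()
        ok = (
            x1 in g and x2 in g and x3 in g
            and nx_connected(g, x1, x2) and nx_connected(g, x1, x3)
        )
    return ok, tuple(present)


def nx_connected(g, a, b) -> bool:
    import networkx as nx

    return nx.has_path(g, a, b)


def x3_event_rate(
    triplets: list[Triplet], all_genes: int, thresholds: list[float]
) -> tuple[list[float], list[int]]:
    """Mean per-gene X3 frequency among significant triplets, per threshold.

    At each threshold t the significant set is {triplets with p <= t}; each
    gene's rate is its share of X3 positions; the curve reports the mean
    over genes occurring at least once as X3. The uniform baseline is
    1 / all_genes.
    """
    if not thresholds:
        raise ValueError("empty threshold grid")
    thresholds = sorted(thresholds)
    if not any(t.p <= max(thresholds) for t in triplets):
        raise ValueError("no triplet passes the loosest threshold")
    rates, counts = [], []
    for t in thresholds:
        sig = [tr for tr in triplets if tr.p <= t]
        counts.append(len(sig))
        if not sig:
            rates.append(float("nan"))
            continue
        x3_counts: dict[str, int] = {}
        for tr in sig:
            x3_counts[tr.x3] = x3_counts.get(tr.x3, 0) + 1
        per_gene = [c / len(sig) for c in x3_counts.values()]
        rates.append(float(np.mean(per_gene)))
    return rates, counts


def deg_x3_proportion(
    triplets: list[Triplet], degs: set[str], all_genes: set[str]
) -> tuple[float, float]:
    """(|DEGs| / |genes|, fraction of significant triplets with a DEG X3).

    Exact rational counts, evaluated with integer arithmetic before the
    single final division.
    """
    if not triplets:
        raise ValueError("empty triplet set")
    if not all_genes:
        raise ValueError("empty gene universe")
    frac_all = len(degs & all_genes) / len(all_genes)
    hits = sum(1 for t in triplets if t.x3 in degs)
    return frac_all, hits / len(triplets)


def call_relevant_triplets(
    triplets: list[Triplet],
    enrichments: dict[str, list[EnrichmentResult]],
    network: GeneNetwork,
    collection: GeneSetCollection,
    support_rule: str = "both_x3_edges",
    per_disease_triplets: dict[str, list[Triplet]] | None = None,
    fdr_threshold: float = 0.01,
) -> list[RelevanceCall]:
    """Annotate each significant triplet with both relevance gates.

    ``triplets`` should be the screened list; only those with
    p_adj < fdr_threshold are annotated. ``per_disease_triplets`` (from
    per-disease screening runs) fills ``diseases_involved``; pooled mode
    leaves it empty. Output is ordered by p ascending.
    """
    gene_universe = set(network.nodes)
    significant = [t for t in triplets if t.p_adj < fdr_threshold]
    missing = sorted(
        {g for t in significant for g in t.genes()} - gene_universe
    )
    if missing:
        raise ValueError(f"triplet genes absent from the network universe: {missing}")

    per_disease_sig: dict[str, set[tuple[str, str, str]]] = {}
    if per_disease_triplets:
        for disease, tl in per_disease_triplets.items():
            per_disease_sig[disease] = {
                t.genes() for t in tl if t.p_adj < fdr_threshold
            }

    calls = []
    for t in sorted(significant, key=lambda t: (t.p, t.x1, t.x2, t.x3)):
        coherent, names = pathway_coherent(t, enrichments, collection)
        supported, edges = grn_supported(t, network, support_rule)
        diseases = tuple(
            sorted(d for d, sig in per_disease_sig.items() if t.genes() in sig)
        )
        calls.append(
            RelevanceCall(
                triplet=t,
                pathway_coherent=coherent,
                coherent_pathways=names,
                grn_supported=supported,
                supporting_edges=edges,
                diseases_involved=diseases,
            )
        )
    return calls


# -- pipeline orchestration --------------------------------------------------


def toy_config(outdir: str | Path, seed: int = 17) -> dict:
    """Packaged demonstration config: 50 genes x 120 samples, one disease,
    3 planted switch triplets (the first also an MI driver of its pair),
    8 planted DEGs forming one planted pathway together with the driver
    triplet's pair, plus decoy pathways."""
    return {
        "outdir": str(outdir),
        "seed": seed,
        "simulate": {
            "n_genes": 50,
            "n_samples": 120,
            "n_deg": 8,
            "deg_effect": 2.0,
            "triplets": [
                {"x3": "g0000", "pair": ["g0001", "g0002"], "rho_high": 0.8,
                 "rho_low": -0.8, "driver_strength": 1.0},
                {"x3": "g0003", "pair": ["g0004", "g0005"], "rho_high": 0.7,
                 "rho_low": -0.6},
                {"x3": "g0006", "pair": ["g0007", "g0008"], "rho_high": 0.6,
                 "rho_low": -0.6},
            ],
            "pathway": {"name": "planted_pathway", "extra_members": ["g0001", "g0002"]},
            "n_decoy_pathways": 6,
            "decoy_size": 8,
        },
        "screen": {"rho_diff_min": 0.5, "fdr_threshold": 0.01, "stratum_rule": "tertile"},
        # dpi_eps 0.15: the planted driver triplet's true dependency graph is
        # a triangle (X3 drives both pair genes AND the pair is directly
        # coupled), where zero-tolerance DPI always prunes one true edge;
        # 0.15 is the tolerance conventional for ARACNE runs on dense graphs
        "grn": {"estimator": "bins", "alpha": 0.05, "n_perm": 1000, "dpi_eps": 0.15},
        "enrich": {"min_genes": 3, "fdr": 0.05, "kappa": 0.4, "min_diseases": 1},
        "integrate": {"support_rule": "both_x3_edges"},
        "deg_alpha": 0.05,
        "quantile_normalize": False,
    }


def _simulate_inputs(cfg: dict, seed: int):
    sim = cfg["simulate"]
    tspecs = tuple(
        TripletSpec(
            x3_id=t["x3"],
            pair_ids=tuple(t["pair"]),
            rho_high=t["rho_high"],
            rho_low=t["rho_low"],
            stratum_fraction=t.get("stratum_fraction", 1.0 / 3.0),
            driver_strength=t.get("driver_strength", 0.0),
        )
        for t in sim.get("triplets", [])
    )
    spec = StudySpec(
        n_genes=sim["n_genes"],
        n_samples=sim["n_samples"],
        n_deg=sim.get("n_deg", 0),
        deg_effect=sim.get("deg_effect", 0.0),
        triplets=tspecs,
        seed=seed,
    )
    matrix, truth = generate_study(spec)

    # planted pathway: the planted DEGs plus named extra members
    pathway_cfg = sim.get("pathway")
    sets: dict[str, set[str]] = {}
    if pathway_cfg:
        members = {g for g, _ in truth.planted_degs} | set(pathway_cfg.get("extra_members", []))
        sets[pathway_cfg["name"]] = members
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    used = set().union(*sets.values()) if sets else set()
    free = [g for g in matrix.gene_ids if g not in used]
    for i in range(sim.get("n_decoy_pathways", 0)):
        size = sim.get("decoy_size", 8)
        members = set(rng.choice(free, size=min(size, len(free)), replace=False))
        sets[f"decoy_{i:02d}"] = members
    collection = GeneSetCollection(sets=sets, universe=set(matrix.gene_ids))
    return matrix, truth, collection


def _load_inputs(cfg: dict):
    inp = cfg["inputs"]
    matrix = read_expression_tsv(inp["matrix"], inp.get("samples"))
    if "probe_map" in inp:
        matrix = collapse_duplicates(matrix.values, read_probe_map(inp["probe_map"]))
    if "keep" in inp:
        matrix = filter_gene_set(matrix, read_gene_list(inp["keep"]))
    collection = read_gmt(inp["gmt"], universe=set(matrix.gene_ids))
    return matrix, None, collection


def run_pipeline(config: dict | str | Path) -> dict:
    """Run preprocess -> DEG -> screen -> GRN -> enrich -> integrate.

    ``config`` is a dict or a path to a YAML file. Returns a dict of all
    stage artifacts and writes stage TSVs, a run log and a summary to
    ``config["outdir"]``. Fully deterministic for a fixed seed.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        matrix, truth, collection = _simulate_inputs(config, seed)
        matrix.write_tsv(outdir / "matrix.tsv", outdir / "samples.tsv")
        if truth is not None:
            write_truth(truth, outdir / "truth.tsv")
    elif "inputs" in config:
        matrix, truth, collection = _load_inputs(config)
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' section")

    # differential expression per disease (on the untransformed matrix)
    deg_alpha = float(config.get("deg_alpha", 0.05))
    degs_by_disease = moderated_t_by_disease(matrix, alpha=deg_alpha)
    deg_sets = {d: [r.gene_id for r in res if r.is_deg] for d, res in degs_by_disease.items()}
    for disease, res in degs_by_disease.items():
        pd.DataFrame(
            [(r.gene_id, r.mean_case, r.mean_control, r.moderated_t, r.p, r.is_deg) for r in res],
            columns=["gene_id", "mean_case", "mean_control", "moderated_t", "p", "is_deg"],
        ).to_csv(outdir / f"degs_{disease}.tsv", sep="\t", index=False, float_format="%.10g")

    # screening on the NQT + standardized matrix
    scfg = config.get("screen", {})
    screen_config = ScreenConfig(
        stratum_rule=scfg.get("stratum_rule", "tertile"),
        p_method=scfg.get("p_method", "fisher_z"),
        rho_diff_min=float(scfg.get("rho_diff_min", 0.5)),
        bonferroni_m=scfg.get("bonferroni_m", "auto"),
        fdr_threshold=float(scfg.get("fdr_threshold", 0.01)),
        seed=seed,
    )
    transformed = transform_matrix(matrix, quantile_norm=bool(config.get("quantile_normalize", False)))
    triplets = screen_triplets(transformed, screen_config)
    write_triplets_tsv(triplets, outdir / "triplets.tsv")
    significant = [t for t in triplets if t.p_adj < screen_config.fdr_threshold]

    # per-disease screening (for diseases_involved) when >1 disease
    per_disease_triplets = None
    diseases = matrix.diseases()
    if len(diseases) > 1:
        per_disease_triplets = {}
        for disease in diseases:
            cols = [
                s for s in matrix.sample_ids
                if matrix.sample_meta.loc[s, "disease"] == disease
            ]
            sub = transform_matrix(matrix.subset_samples(cols))
            per_disease_triplets[disease] = screen_triplets(sub, screen_config)

    # GRN
    gcfg = config.get("grn", {})
    grn_config = GrnConfig(
        estimator=gcfg.get("estimator", "bins"),
        n_perm=int(gcfg.get("n_perm", 1000)),
        alpha=float(gcfg.get("alpha", 0.05)),
        dpi_eps=float(gcfg.get("dpi_eps", 0.0)),
        seed=seed,
    )
    network = build_grn(transformed, grn_config)
    write_network_tsv(network, outdir / "grn.tsv")

    # enrichment per disease
    ecfg = config.get("enrich", {})
    restricted = collection.restricted(set(matrix.gene_ids))
    enrichments = {
        d: enrich_deg_list(
            deg_sets[d],
            restricted,
            min_genes=int(ecfg.get("min_genes", 3)),
            threshold=float(ecfg.get("fdr", 0.05)),
            kappa_threshold=float(ecfg.get("kappa", 0.4)),
        )
        for d in deg_sets
    }
    for disease, res in enrichments.items():
        write_enrichment_tsv(res, outdir / f"enrichment_{disease}.tsv")
    passing_by_disease = {
        d: [r.pathway for r in res if r.passes] for d, res in enrichments.items()
    }
    shared = shared_pathways(passing_by_disease, min_diseases=int(ecfg.get("min_diseases", 1)))
    pd.DataFrame(shared, columns=["pathway", "n_diseases"]).to_csv(
        outdir / "shared_pathways.tsv", sep="\t", index=False
    )

    # integration
    icfg = config.get("integrate", {})
    calls = call_relevant_triplets(
        triplets,
        enrichments,
        network,
        restricted,
        support_rule=icfg.get("support_rule", "both_x3_edges"),
        per_disease_triplets=per_disease_triplets,
        fdr_threshold=screen_config.fdr_threshold,
    )
    annotated = pd.DataFrame(
        [
            (
                c.triplet.x1, c.triplet.x2, c.triplet.x3, c.triplet.rho_high,
                c.triplet.rho_low, c.triplet.rho_diff, c.triplet.la_score,
                c.triplet.p, c.triplet.p_adj, c.pathway_coherent,
                ",".join(c.coherent_pathways), c.grn_supported,
                ";".join("-".join(e) for e in c.supporting_edges),
                ",".join(c.diseases_involved),
            )
            for c in calls
        ],
        columns=[
            "X1", "X2", "X3", "rho_high", "rho_low", "rho_diff", "la_score",
            "p", "p_adj", "pathway_coherent", "coherent_pathways",
            "grn_supported", "supporting_edges", "diseases_involved",
        ],
    )
    annotated.to_csv(outdir / "triplets_annotated.tsv", sep="\t", index=False, float_format="%.10g")
    headline = [c for c in calls if c.headline]
    annotated[annotated["pathway_coherent"] & annotated["grn_supported"]].to_csv(
        outdir / "headline_triplets.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # validation statistics
    all_gene_set = set(matrix.gene_ids)
    union_degs = set().union(*deg_sets.values()) if deg_sets else set()
    if significant:
        grid = sorted({t.p for t in significant}) or [1.0]
        thresholds = [grid[0], float(np.median(grid)), grid[-1]]
        rates, counts = x3_event_rate(triplets, matrix.n_genes, thresholds)
        frac_all, frac_x3 = deg_x3_proportion(significant, union_degs, all_gene_set)
        summary = ValidationSummary(
            thresholds=thresholds,
            observed_rate=rates,
            n_significant=counts,
            random_rate=1.0 / matrix.n_genes,
            deg_fraction_all=frac_all,
            deg_fraction_x3=frac_x3,
        )
        vs = summary.to_frame()
        vs["deg_fraction_all"] = frac_all
        vs["deg_fraction_x3"] = frac_x3
        vs.to_csv(outdir / "validation_summary.tsv", sep="\t", index=False, float_format="%.10g")
    else:
        summary = None
        pd.DataFrame(
            columns=["threshold", "observed_rate", "n_significant", "random_rate",
                     "deg_fraction_all", "deg_fraction_x3"]
        ).to_csv(outdir / "validation_summary.tsv", sep="\t", index=False)

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"switchla {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}\n")
        fh.write(f"seed {seed}\n")
        fh.write(f"genes {matrix.n_genes} samples {matrix.n_samples}\n")
        fh.write(f"screen {screen_config}\n")
        fh.write(f"grn {grn_config}\n")
        fh.write(f"significant_triplets {len(significant)}\n")
        fh.write(f"grn_edges {network.n_edges()}\n")
        fh.write(f"headline_triplets {len(headline)}\n")

    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"genes analysed: {matrix.n_genes}\n")
        for d, lst in deg_sets.items():
            fh.write(f"DEGs ({d}, alpha={deg_alpha}): {len(lst)}\n")
        fh.write(f"significant triplets (adjusted p < {screen_config.fdr_threshold}): {len(significant)}\n")
        fh.write(f"network edges after DPI: {network.n_edges()}\n")
        for name, cnt in shared:
            fh.write(f"shared pathway: {name} in {cnt} disease(s)\n")
        fh.write(f"pathway-coherent triplets: {sum(1 for c in calls if c.pathway_coherent)}\n")
        fh.write(f"network-supported triplets: {sum(1 for c in calls if c.grn_supported)}\n")
        fh.write(f"headline (both gates): {len(headline)}\n")
        if summary is not None:
            fh.write(
                f"DEG fraction overall {summary.deg_fraction_all:.3f} vs among X3 {summary.deg_fraction_x3:.3f}\n"
            )

    return {
        "matrix": matrix,
        "truth": truth,
        "degs": degs_by_disease,
        "deg_sets": deg_sets,
        "triplets": triplets,
        "significant": significant,
        "network": network,
        "enrichments": enrichments,
        "shared": shared,
        "calls": calls,
        "headline": headline,
        "validation": summary,
        "collection": restricted,
    }
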