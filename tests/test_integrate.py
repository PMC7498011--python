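"""Relevance gates, validation statistics, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

import switchla as sla
from switchla.enrich import EnrichmentResult
from switchla.grn import GeneNetwork


def _triplet(x1="a", x2="b", x3="c", p=1e-9, p_adj=1e-4):
    return sla.Triplet(x1, x2, x3, 0.8, -0.8, 1.6, 1.6, 0.5, p, p_adj, 40, 40)


def _enr(pathway, passes, p=1e-4):
    return EnrichmentResult(
        pathway=pathway, k=4, K=6, n=10, N=50, p=p, p_adj=p * 5, passes=passes
    )


def _net(*pairs, nodes=("a", "b", "c", "d")):
    return GeneNetwork(
        nodes=list(nodes), edges={frozenset(p): (0.5, 0.01) for p in pairs}
    )


class TestPathwayCoherent:
    def _coll(self):
        return sla.GeneSetCollection(
            sets={"pw1": {"a", "b", "x"}, "pw2": {"a", "c"}},
            universe={"a", "b", "c", "d", "x"},
        )

    def test_pair_in_passing_pathway(self):
        ok, names = sla.pathway_coherent(
            _triplet(), {"D1": [_enr("pw1", True)]}, self._coll()
        )
        assert ok and names == ("pw1",)

    def test_non_passing_pathway_gated_out(self):
        ok, names = sla.pathway_coherent(
            _triplet(), {"D1": [_enr("pw1", False)]}, self._coll()
        )
        assert not ok and names == ()

    def test_pathway_without_both_pair_genes(self):
        ok, _ = sla.pathway_coherent(
            _triplet(), {"D1": [_enr("pw2", True)]}, self._coll()
        )
        assert not ok  # pw2 holds x1 but not x2


class TestGrnSupported:
    def test_full_support_under_every_rule(self):
        net = _net(("c", "a"), ("c", "b"))
        for rule in ("both_x3_edges", "any_edge", "connected"):
            ok, edges = sla.grn_supported(_triplet(), net, rule)
            assert ok
        assert set(edges) == {("c", "a"), ("c", "b")}

    def test_rule_discrimination(self):
        net = _net(("a", "b"))
        assert not sla.grn_supported(_triplet(), net, "both_x3_edges")[0]
        assert sla.grn_supported(_triplet(), net, "any_edge")[0]

    def test_connected_rule_uses_component(self):
        net = _net(("a", "d"), ("d", "b"), ("d", "c"))
        assert sla.grn_supported(_triplet(), net, "connected")[0]
        assert not sla.grn_supported(_triplet(), net, "both_x3_edges")[0]

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            sla.grn_supported(_triplet(), _net(), "bogus")

    def test_generative_fork_support(self):
        """X3 linearly drives X1 and X2 (rho 0.7, n = 500): both X3 edges
        recovered in >= 90% of replicates."""
        ok = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(4000 + rep)
            x3 = rng.standard_normal(500)
            mk = lambda: 0.7 * x3 + np.sqrt(0.51) * rng.standard_normal(500)
            rows = {"X3": x3, "X1": mk(), "X2": mk()}
            rows.update({f"n{i}": rng.standard_normal(500) for i in range(2)})
            mat = sla.ExpressionMatrix(
                pd.DataFrame(rows.values(), index=list(rows), columns=[f"s{i}" for i in range(500)])
            )
            net = sla.build_grn(mat, sla.GrnConfig(n_perm=300, seed=rep))
            ok += sla.grn_supported(_triplet("X1", "X2", "X3"), net)[0]
        assert ok >= 0.9 * n_rep


class TestValidationStats:
    def test_maximal_concentration(self):
        trips = [_triplet(x1=f"a{i}", x2=f"b{i}", x3="hub", p=1e-8) for i in range(5)]
        rates, counts = sla.x3_event_rate(trips, all_genes=50, thresholds=[1e-6])
        assert rates == [1.0] and counts == [5]

    def test_uniform_x3_matches_baseline(self, rng):
        """Random X3 labels: mean per-gene rate approaches the 1/G baseline
        (while concentrated X3 assignment, tested below, far exceeds it)."""
        G = 40
        means = []
        for _ in range(200):
            trips = [
                _triplet(x1=f"a{i}", x2=f"b{i}", x3=f"g{rng.integers(G)}", p=1e-8)
                for i in range(120)
            ]
            rates, _ = sla.x3_event_rate(trips, all_genes=G, thresholds=[1.0])
            means.append(rates[0])
        # with 120 uniform draws over 40 genes nearly every gene appears, so
        # the mean per-appearing-gene rate sits just above 1/G
        assert abs(np.mean(means) - 1.0 / G) < 0.005

    def test_planted_x3_concentration(self, planted_screen):
        """Planted switch genes dominate the top of the significant list."""
        _, _, triplets = planted_screen
        sig = [t for t in triplets if t.p_adj < 0.01]
        grid = sorted({t.p for t in sig})
        planted_x3 = {"g0000", "g0003", "g0006"}
        best = 0.0
        for thr in grid:
            cur = [t for t in sig if t.p <= thr]
            share = sum(t.x3 in planted_x3 for t in cur) / len(cur)
            best = max(best, share / 3)  # mean rate over the 3 planted genes
        assert best > 10 * (1.0 / 50.0)

    def test_empty_grid_and_unreachable_threshold(self):
        with pytest.raises(ValueError):
            sla.x3_event_rate([_triplet()], 50, [])
        with pytest.raises(ValueError):
            sla.x3_event_rate([_triplet(p=0.5)], 50, [1e-12])

    def test_deg_fraction_trivial_cases(self):
        trips = [_triplet(x3="c"), _triplet(x1="d", x2="e", x3="f")]
        genes = {"a", "b", "c", "d", "e", "f"}
        assert sla.deg_x3_proportion(trips, genes, genes) == (1.0, 1.0)
        assert sla.deg_x3_proportion(trips, set(), genes) == (0.0, 0.0)
        frac_all, frac_x3 = sla.deg_x3_proportion(trips, {"c"}, genes)
        assert frac_all == pytest.approx(1 / 6)
        assert frac_x3 == pytest.approx(1 / 2)

    def test_planted_x3_degs_enrich_fraction(self):
        """When planted switch genes are also DEGs, the X3-among-DEG fraction
        exceeds the overall DEG fraction (the 53% vs 25% pattern)."""
        spec = sla.StudySpec(
            n_genes=50,
            n_samples=120,
            seed=321,
            deg_effect=2.0,
            deg_ids=("g0000", "g0003", "g0006", "g0010", "g0011"),
            triplets=tuple(
                sla.TripletSpec(f"g{i*3:04d}", (f"g{i*3+1:04d}", f"g{i*3+2:04d}"), 0.8, -0.8)
                for i in range(3)
            ),
        )
        with pytest.warns(UserWarning):  # X3 genes double as DEGs, flagged
            mat, truth = sla.generate_study(spec)
        trips = sla.screen_triplets(sla.transform_matrix(mat))
        sig = [t for t in trips if t.p_adj < 0.01]
        degs = {g for g, _ in truth.planted_degs}
        frac_all, frac_x3 = sla.deg_x3_proportion(sig, degs, set(mat.gene_ids))
        assert frac_x3 > frac_all


class TestCallRelevantTriplets:
    def _inputs(self):
        coll = sla.GeneSetCollection(
            sets={"pw1": {"a", "b"}}, universe={"a", "b", "c", "d", "e", "f"}
        )
        enr = {"D1": [_enr("pw1", True)]}
        net = _net(("c", "a"), ("c", "b"), nodes=("a", "b", "c", "d", "e", "f"))
        return coll, enr, net

    def test_gate_monotonicity_and_annotation(self):
        coll, enr, net = self._inputs()
        trips = [
            _triplet(),                                   # both gates pass
            _triplet(x1="d", x2="e", x3="f", p=1e-8),      # both fail
        ]
        calls = sla.call_relevant_triplets(trips, enr, net, coll)
        assert len(calls) == 2  # failing triplet retained in the table
        headline = [c for c in calls if c.headline]
        assert len(headline) == 1 and headline[0].triplet.genes() == ("a", "b", "c")
        for c in calls:
            assert c.headline == (c.pathway_coherent and c.grn_supported)
            if c.grn_supported:  # default rule: both X3 edges present
                assert len(c.supporting_edges) >= 2

    def test_empty_significant_set(self):
        coll, enr, net = self._inputs()
        calls = sla.call_relevant_triplets(
            [_triplet(p_adj=0.5)], enr, net, coll, fdr_threshold=0.01
        )
        assert calls == []

    def test_universe_mismatch_named(self):
        coll, enr, net = self._inputs()
        with pytest.raises(ValueError, match="zz"):
            sla.call_relevant_triplets([_triplet(x3="zz")], enr, net, coll)

    def test_per_disease_involvement(self):
        coll, enr, net = self._inputs()
        per = {"D1": [_triplet()], "D2": [_triplet(p_adj=0.9)], "D3": [_triplet()]}
        calls = sla.call_relevant_triplets(
            [_triplet()], enr, net, coll, per_disease_triplets=per
        )
        assert calls[0].diseases_involved == ("D1", "D3")


class TestRunPipeline:
    def test_toy_run_outputs(self, toy_run):
        res, out = toy_run
        assert len(res["headline"]) >= 1
        assert ("g0001", "g0002", "g0000") in {c.triplet.genes() for c in res["headline"]}
        for f in (
            "matrix.tsv", "samples.tsv", "truth.tsv", "triplets.tsv", "grn.tsv",
            "degs_D1.tsv", "enrichment_D1.tsv", "shared_pathways.tsv",
            "triplets_annotated.tsv", "headline_triplets.tsv",
            "validation_summary.tsv", "run_log.txt", "summary.txt",
        ):
            assert (out / f).exists(), f

    def test_gate_subset_invariant(self, toy_run):
        res, _ = toy_run
        sig = {c.triplet.genes() for c in res["calls"]}
        coh = {c.triplet.genes() for c in res["calls"] if c.pathway_coherent}
        sup = {c.triplet.genes() for c in res["calls"] if c.grn_supported}
        head = {c.triplet.genes() for c in res["headline"]}
        assert head <= coh <= sig and head <= sup <= sig

    def test_deterministic_reports(self, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        sla.run_pipeline(sla.toy_config(d1, seed=17))
        sla.run_pipeline(sla.toy_config(d2, seed=17))
        for f in d1.glob("*.tsv"):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_stringent_threshold_empty_headline(self, tmp_path):
        cfg = sla.toy_config(tmp_path / "strict", seed=17)
        cfg["screen"]["fdr_threshold"] = 1e-12
        cfg["grn"]["n_perm"] = 300
        res = sla.run_pipeline(cfg)
        assert res["headline"] == []
        assert (tmp_path / "strict" / "triplets_annotated.tsv").exists()

    def test_yaml_config_accepted(self, tmp_path):
        import yaml

        cfg = sla.toy_config(tmp_path / "yaml_run", seed=17)
        cfg["grn"]["n_perm"] = 300
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg))
        res = sla.run_pipeline(path)
        assert len(res["significant"]) >= 3

    def test_file_inputs_mode(self, tmp_path, toy_run):
        """The pipeline reads back its own TSV/GMT exports."""
        res, out = toy_run
        gmt = tmp_path / "sets.gmt"
        sla.write_gmt(res["collection"], gmt)
        cfg = {
            "outdir": str(tmp_path / "fromfiles"),
            "seed": 17,
            "inputs": {
                "matrix": str(out / "matrix.tsv"),
                "samples": str(out / "samples.tsv"),
                "gmt": str(gmt),
            },
            "screen": {"rho_diff_min": 0.5, "fdr_threshold": 0.01},
            "grn": {"n_perm": 300},
        }
        res2 = sla.run_pipeline(cfg)
        assert {t.genes() for t in res2["significant"]} == {
            t.genes() for t in res["significant"]
        }
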