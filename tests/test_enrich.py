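"""Over-representation statistics, Holm correction, kappa grouping."""

import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.multitest import multipletests

import switchla as sla

GENES = [f"g{i:04d}" for i in range(60)]
UNIVERSE = set(GENES)


@pytest.fixture(scope="module")
def collection():
    sets = {"planted": set(GENES[:6])}
    sets.update({f"decoy_{i}": set(GENES[10 + i * 6 : 16 + i * 6]) for i in range(5)})
    return sla.GeneSetCollection(sets=sets, universe=UNIVERSE)


def exact_upper_tail(k, K, n, N):
    """Enumeration oracle: sum of C(K,i) C(N-K,n-i) / C(N,n) over i >= k."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / denom


class TestHypergeometric:
    def test_full_overlap_small_case(self):
        assert sla.hypergeometric_test(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap(self):
        assert sla.hypergeometric_test(0, 7, 9, 20) == pytest.approx(1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(200):
            N = int(rng.integers(2, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            assert sla.hypergeometric_test(k, K, n, N) == pytest.approx(
                exact_upper_tail(k, K, n, N), abs=1e-12
            )

    def test_two_sided_capped(self):
        p = sla.hypergeometric_test(3, 10, 10, 20, two_sided=True)
        assert 0 < p <= 1

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            sla.hypergeometric_test(6, 5, 5, 10)


class TestHolm:
    def test_hand_worked_ladder(self):
        assert np.allclose(sla.holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert sla.holm_adjust([0.2]) == pytest.approx([0.2])

    def test_against_statsmodels(self, rng):
        ps = rng.uniform(size=40)
        expected = multipletests(ps, method="holm")[1]
        assert np.allclose(sla.holm_adjust(ps), expected)

    def test_never_below_raw_and_bonferroni_at_min(self, rng):
        ps = rng.uniform(size=25)
        adj = sla.holm_adjust(ps)
        assert np.all(adj >= ps)
        i = np.argmin(ps)
        assert adj[i] == pytest.approx(min(1.0, ps[i] * 25))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sla.holm_adjust([])
        with pytest.raises(ValueError):
            sla.holm_adjust([0.5, 1.2])


class TestKappa:
    def test_identical_sets(self):
        a = set(GENES[:5])
        assert sla.kappa_score(a, a, UNIVERSE) == pytest.approx(1.0)

    def test_hand_case_disjoint_halves(self):
        uni = {"g1", "g2", "g3", "g4"}
        assert sla.kappa_score({"g1", "g2"}, {"g3", "g4"}, uni) == pytest.approx(-1.0)

    def test_symmetry_and_sklearn_oracle(self, rng):
        for _ in range(20):
            a = set(rng.choice(GENES, 12, replace=False))
            b = set(rng.choice(GENES, 8, replace=False))
            k1 = sla.kappa_score(a, b, UNIVERSE)
            assert k1 == pytest.approx(sla.kappa_score(b, a, UNIVERSE))
            va = [g in a for g in GENES]
            vb = [g in b for g in GENES]
            assert k1 == pytest.approx(cohen_kappa_score(va, vb))

    def test_random_sets_near_zero(self, rng):
        ks = []
        for _ in range(200):
            a = set(rng.choice(GENES, 10, replace=False))
            b = set(rng.choice(GENES, 10, replace=False))
            ks.append(sla.kappa_score(a, b, UNIVERSE))
        assert abs(np.mean(ks)) < 0.05

    def test_degenerate_universe(self):
        with pytest.raises(ValueError):
            sla.kappa_score(UNIVERSE, UNIVERSE, UNIVERSE)


class TestEnrichDegList:
    def test_perfect_query(self, collection):
        res = sla.enrich_deg_list(GENES[:6], collection)
        by_name = {r.pathway: r for r in res}
        assert by_name["planted"].passes
        assert by_name["planted"].k == 6
        assert res[0].pathway == "planted"  # smallest p first
        assert all(r.k < 3 for n, r in by_name.items() if n != "planted")

    def test_family_wise_null_control(self, collection):
        """Uniform random queries: any-pass rate stays near the Holm level."""
        rng = np.random.default_rng(88)
        any_pass = sum(
            any(
                r.passes
                for r in sla.enrich_deg_list(
                    list(rng.choice(GENES, 10, replace=False)), collection
                )
            )
            for _ in range(200)
        )
        assert any_pass / 200 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_duplicate_pathways_grouped(self):
        sets = {"A": set(GENES[:8]), "B": set(GENES[:8]), "C": set(GENES[20:28])}
        coll = sla.GeneSetCollection(sets=sets, universe=UNIVERSE)
        res = sla.enrich_deg_list(GENES[:8], coll)
        groups = {r.pathway: r.group for r in res if r.passes}
        assert groups["A"] == groups["B"] != ""

    def test_outside_universe_dropped_with_warning(self, collection):
        with pytest.warns(UserWarning):
            res = sla.enrich_deg_list(GENES[:6] + ["not_a_gene"], collection)
        assert res[0].n == 6

    def test_restricted_universe_changes_K(self, collection):
        small = collection.restricted(set(GENES[:30]))
        assert small.universe == set(GENES[:30])
        assert all(m <= small.universe for m in small.sets.values())


class TestSharedPathways:
    def test_full_sharing(self):
        per = {f"D{i}": ["pw1", f"other{i}"] for i in range(6)}
        assert sla.shared_pathways(per, min_diseases=5) == [("pw1", 6)]

    def test_below_threshold_excluded(self):
        per = {f"D{i}": (["pw1"] if i < 4 else []) for i in range(6)}
        assert sla.shared_pathways(per, min_diseases=5) == []

    def test_planted_sharing_recovered(self, collection):
        """Pathway genes shifted in 5 of 6 diseases: sharing count >= 5
        reported in >= 90% of replicates."""
        ok = 0
        n_rep = 20
        for rep in range(n_rep):
            spec = sla.StudySpec(
                n_genes=60,
                n_samples=120,
                seed=7000 + rep,
                groups=sla.balanced_groups(120, tuple(f"D{i}" for i in range(6))),
            )
            mat, _ = sla.generate_study(spec)
            vals = mat.values.copy()
            meta = mat.sample_meta
            for d in [f"D{i}" for i in range(5)]:
                cols = [
                    c
                    for c in vals.columns
                    if meta.loc[c, "disease"] == d and meta.loc[c, "status"] == "case"
                ]
                vals.loc[list(collection.sets["planted"]), cols] += 2.0
            degs = sla.moderated_t_by_disease(sla.ExpressionMatrix(vals, meta))
            passing = {
                d: [
                    r.pathway
                    for r in sla.enrich_deg_list(
                        [x.gene_id for x in res if x.is_deg], collection
                    )
                    if r.passes
                ]
                for d, res in degs.items()
            }
            shared = dict(sla.shared_pathways(passing, min_diseases=5))
            ok += shared.get("planted", 0) >= 5
        assert ok >= 0.9 * n_rep

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sla.shared_pathways({})


class TestGmtIO:
    def test_roundtrip(self, collection, tmp_path):
        path = tmp_path / "sets.gmt"
        sla.write_gmt(collection, path)
        back = sla.read_gmt(path, universe=UNIVERSE)
        assert back.sets == collection.sets

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("just_one_column\n")
        with pytest.raises(ValueError):
            sla.read_gmt(path)
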