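"""Moderated-t differential expression on a simulated case/control study.

Plants 10 genes with a 2-SD case shift among 200, runs the empirical-Bayes
moderated t-test, and reports sensitivity and the false-positive rate.
"""

import switchla as sla

spec = sla.StudySpec(n_genes=200, n_samples=60, n_deg=10, deg_effect=2.0, seed=7)
matrix, truth = sla.generate_study(spec)

groups = {s: matrix.sample_meta.loc[s, "status"] for s in matrix.sample_ids}
results = sla.moderated_t_test(matrix, groups, alpha=0.05)

planted = {g for g, _ in truth.planted_degs}
called = {r.gene_id for r in results if r.is_deg}
tp = len(called & planted)
fp = len(called - planted)
print(f"planted DEGs recovered: {tp}/{len(planted)}")
print(f"false positives: {fp}/{len(results) - len(planted)} null genes")
top = min(results, key=lambda r: r.p)
print(
    f"strongest call: {top.gene_id}, moderated t = {top.moderated_t:.2f}, p = {top.p:.2e}"
)
# With a 2-SD effect at 30 samples per group the test recovers essentially
# every planted gene while the null false-positive rate stays near alpha;
# variance shrinkage toward the ensemble prior stabilises the per-gene t.
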