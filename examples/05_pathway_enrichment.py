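"""Hypergeometric pathway over-representation with Holm correction.

Tests a DEG list against a small pathway collection, applies the Holm
step-down adjustment, and groups redundant pathways by Cohen's kappa.
"""

import switchla as sla

genes = [f"g{i:04d}" for i in range(60)]
collection = sla.GeneSetCollection(
    sets={
        "cytokine_signalling": set(genes[0:8]),
        "cytokine_signalling_copy": set(genes[0:8]),  # redundant duplicate
        "phagocytosis": set(genes[20:28]),
        "ribosome": set(genes[40:52]),
    },
    universe=set(genes),
)

degs = genes[0:6] + [genes[20], genes[55]]  # mostly cytokine genes
results = sla.enrich_deg_list(degs, collection, min_genes=3, threshold=0.05)

for r in results:
    flag = "PASS" if r.passes else "    "
    print(
        f"{flag} {r.pathway:28s} hits {r.k}/{r.K}, p = {r.p:.2e}, "
        f"Holm p = {r.p_adj:.2e}, group = {r.group or '-'}"
    )
# The two duplicate cytokine pathways pass (6 of 8 members hit) and are
# merged into one kappa group (kappa = 1 >= 0.4); the others have too few
# hits. Pathway sizes K are counted against the 60-gene universe.

shared = sla.shared_pathways(
    {"AD": ["cytokine_signalling"], "PD": ["cytokine_signalling"], "MS": ["phagocytosis"]},
    min_diseases=2,
)
print(f"pathways shared by >= 2 diseases: {shared}")
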