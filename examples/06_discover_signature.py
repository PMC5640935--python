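"""Derive a metasynchronous-spread gene module from planted-signal data.

Plants 21 differential genes (19 up, 2 down) among 3000 noise genes,
screens every gene with an unpaired Mann-Whitney test, selects at
BH-adjusted p < 0.2, and evaluates the derived module's weighted-sum score
by ROC on an independent draw from the same generator.
"""

import numpy as np
import pandas as pd

from organotrope import (
    DiscoveryConfig,
    derive_module,
    evaluate_module,
    per_gene_differential,
)

rng = np.random.default_rng(8)
n_genes, n = 3000, 50
genes = [f"g{i:04d}" for i in range(n_genes)]
truth = {genes[i]: (+1 if i < 19 else -1) for i in range(21)}


def draw():
    x = rng.standard_normal((n_genes, 2 * n))
    for i, (g, d) in enumerate(truth.items()):
        x[i, :n] += d * 1.0  # one-SD effect
    cols = [f"case{j}" for j in range(n)] + [f"ref{j}" for j in range(n)]
    return pd.DataFrame(x, index=genes, columns=cols), cols[:n], cols[n:]


expr, cases, refs = draw()
results = per_gene_differential(expr, cases, refs)
module = derive_module(results, DiscoveryConfig(fdr_threshold=0.2))

sel = set(module.genes)
tp = sel & set(truth)
print(f"selected {len(module.members)} genes at FDR < 0.2: "
      f"{len(tp)}/21 planted recovered, {len(sel) - len(tp)} false positives")
up = sum(w > 0 for _, w in module.members)
print(f"directions: {up} up, {len(module.members) - up} down")

expr2, cases2, refs2 = draw()
held_out = evaluate_module(expr2, module, cases2, refs2)
resub = evaluate_module(expr, module, cases, refs, resubstitution=True)
print(f"resubstitution AUC: {resub['auc']:.2f} (optimistically biased)")
print(f"held-out AUC:       {held_out['auc']:.2f}")
print("\nAt FDR 0.2, roughly one selected gene in five is expected to be a")
print("false positive; the held-out AUC shows the module generalises anyway.")
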