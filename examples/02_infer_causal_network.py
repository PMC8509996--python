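"""Estimate one miRNA's causal biogenesis network from expression data.

Builds the prior whitelist for a single miRNA from binding sites and PPI
chains, learns the sparse acyclic structure over the penalty path
(lambda = 1..10, MCP), picks the BIC-optimal penalty, refits the structural
equation model by least squares and reports the significant signed edges.
"""

import numpy as np

from mirnet import bayesnet as bn
from mirnet.pipeline import call_sites
from mirnet.synth import make_loci, simulate_clip, simulate_expression, simulate_truth

gt = simulate_truth(seed=3)
gene, pre, mature, _ = simulate_expression(gt, n_samples=300, seed=4)
loci = make_loci(gt)
sites = call_sites(simulate_clip(gt, loci, seed=5), loci)
ppi = [(s, t) for (s, t) in gt.dag if s in set(gt.ppi_genes)]

locus = loci[0]
net = bn.assemble_candidate_network(sites, ppi, locus, "pri_to_pre")
data = bn.build_node_dataset(net, gene, pre, mature)
path = bn.estimate_dag_path(net, data)
best = bn.select_lambda(path, data)
fit = bn.fit_sem(best.B, data, lambda_used=best.lambda_,
                 mirna_id=locus.mirna_id, step="pri_to_pre")
assocs = bn.select_parameters(fit)

print(f"miRNA {locus.mirna_id}, step pri->pre")
print(f"candidate nodes: {len(net.nodes)}, allowed edges: {len(net.allowed_edges)}")
print(f"edge counts along the path: "
      f"{[int(np.count_nonzero(f.B)) for f in path]}")
print(f"BIC-selected penalty: lambda = {best.lambda_}")
print("\nsignificant edges (p < 0.05, precision >= 85%):")
for a in assocs:
    print(f"  {a.source:>6} -> {a.target:<10} weight {a.weight:+.2f} "
          f"({a.sign}, p = {a.pvalue:.2e})")
truth = {k: v for k, v in gt.dag.items() if k[1] == f"pre:{locus.mirna_id}"}
print(f"\nplanted regulators of this pre-miRNA: "
      f"{ {s: round(w, 2) for (s, _), w in truth.items()} }")
print("A positive weight marks an RBP promoting pri->pre processing, a "
      "negative weight a suppressor; the learner should match the planted "
      "signs and magnitudes.")
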