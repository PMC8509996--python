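"""End-to-end orchestration over the module chain.

These helpers wire the stages together on in-memory objects: CLIP reads ->
consensus + concurrence-filtered binding sites -> per-miRNA candidate
networks -> penalized DAG/SEM estimation -> signed associations ->
correlation screening -> per-miRNA feature tables and boosted models. The
CLI, the examples and the acceptance script all run through this module so
file-based and in-memory runs take the same code path.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from . import bayesnet, sites as sites_mod
from .bayesnet import PenaltySpec
from .expr import ExpressionMatrix
from .synth import GroundTruth, make_loci, simulate_clip, simulate_expression

__all__ = ["NetworkResult", "call_sites", "fit_networks", "causal_feature_sets",
           "superset_feature_sets", "PipelineRun", "run_synthetic_pipeline"]


@dataclass
class NetworkResult:
    """One miRNA/step network: prior, selected fit and significant edges."""

    net: bayesnet.CandidateNetwork
    fit: bayesnet.SEMFit | None
    assocs: list = field(default_factory=list)


def call_sites(clip_samples, loci, min_reads: int = 5, min_samples: int = 2,
               peaks_a=None, peaks_b=None, alpha: float = 0.05) -> list:
    """Consensus sites + concurrence, with the built-in caller as fallback.

    When no external peak sets are supplied, the Poisson caller is run per
    RBP on that RBP's pooled reads over each locus and its peaks stand in
    for caller A (caller B empty).
    """
    candidates = sites_mod.consensus_sites(
        clip_samples, loci, min_reads=min_reads, min_samples=min_samples
    )
    if peaks_a is not None or peaks_b is not None:
        return sites_mod.concurrence_filter(
            candidates, peaks_a or [], peaks_b or []
        )
    by_rbp = defaultdict(list)
    for s in clip_samples:
        by_rbp[s.rbp_id].extend(s.reads)
    out = []
    cand_by_rbp = defaultdict(list)
    for c in candidates:
        cand_by_rbp[c.rbp_id].append(c)
    for rbp, cands in sorted(cand_by_rbp.items()):
        peaks = []
        for locus in loci:
            peaks.extend(
                sites_mod.call_peaks_poisson(by_rbp[rbp], locus.pri, alpha=alpha)
            )
        out.extend(sites_mod.concurrence_filter(cands, peaks, []))
    return out


def fit_networks(
    binding_sites,
    ppi_edges,
    loci,
    gene_expr: ExpressionMatrix,
    pre_expr: ExpressionMatrix,
    mature_expr: ExpressionMatrix,
    pen: PenaltySpec | None = None,
    condition: str | None = None,
    alpha: float = 0.05,
    min_precision: float = 0.85,
    max_steps: int = 8,
) -> dict:
    """Estimate the causal network for every miRNA and both biogenesis steps.

    Returns {(mirna_id, step): NetworkResult}; empty candidate networks are
    recorded with ``fit=None``.
    """
    pen = pen or PenaltySpec()
    results: dict = {}
    for locus in loci:
        for step in ("pri_to_pre", "pre_to_mature"):
            net = bayesnet.assemble_candidate_network(
                binding_sites, ppi_edges, locus, step, max_steps=max_steps
            )
            if net.empty:
                results[(locus.mirna_id, step)] = NetworkResult(net, None, [])
                continue
            data = bayesnet.build_node_dataset(
                net, gene_expr, pre_expr, mature_expr, condition=condition
            )
            path = bayesnet.estimate_dag_path(net, data, pen)
            best = bayesnet.select_lambda(path, data)
            fit = bayesnet.fit_sem(
                best.B,
                data,
                lambda_used=best.lambda_,
                mirna_id=locus.mirna_id,
                step=step,
                condition=condition or "",
            )
            assocs = bayesnet.select_parameters(
                fit, alpha=alpha, min_precision=min_precision
            )
            results[(locus.mirna_id, step)] = NetworkResult(net, fit, assocs)
    return results


def causal_feature_sets(network_results: dict) -> dict:
    """Per-miRNA selected causal-net genes (union over both steps).

    The responsible RBPs are those with a significant edge into the miRNA
    target node; their back-chains are their ancestors in the selected-edge
    graph. The union of both, over both biogenesis steps, is the miRNA's
    causal feature set (targets excluded), ordered deterministically.
    """
    feats: dict = defaultdict(set)
    for (mirna, _step), res in network_results.items():
        target = res.net.target
        if not res.assocs:
            continue
        G = nx.DiGraph((a.source, a.target) for a in res.assocs)
        if target not in G:
            continue
        feats[mirna].update(nx.ancestors(G, target))
    return {m: sorted(v) for m, v in feats.items() if v}


def superset_feature_sets(network_results: dict) -> dict:
    """Per-miRNA full candidate (PPI-inclusive, pre-selection) gene sets."""
    feats: dict = defaultdict(set)
    for (mirna, _step), res in network_results.items():
        for node in res.net.nodes:
            if node != res.net.target:
                feats[mirna].add(node)
    return {m: sorted(v) for m, v in feats.items() if v}


def control_experiment(
    seed: int,
    n_rbps: int = 20,
    n_ppi: int = 60,
    n_mirnas: int = 10,
    n_samples: int = 300,
    min_samples: int = 100,
    cv_folds: int = 3,
    grid=None,
):
    """One seed of the negative-control study.

    The control condition uses private regulators per miRNA (2x as many
    RBPs as miRNAs) and a PPI universe much larger than the causal nets, so
    the swapped and PPI-superset arms are structurally distinct from the
    causal arm. Returns a dict of per-miRNA test accuracies for the three
    arms plus the paired t statistics.
    """
    from . import predict as predict_mod

    grid = grid or [
        predict_mod.BoostingConfig(n_trees=300, max_depth=3, learning_rate=0.1)
    ]
    run = run_synthetic_pipeline(
        seed=seed, n_rbps=n_rbps, n_ppi=n_ppi, n_mirnas=n_mirnas,
        n_samples=n_samples,
    )
    feats = causal_feature_sets(run.networks)
    sup = superset_feature_sets(run.networks)
    tables, sup_tables = [], []
    for m in sorted(feats):
        ft = predict_mod.build_feature_table(
            feats[m], m, run.gene_expr, run.mature_expr, min_samples=min_samples
        )
        fts = predict_mod.build_feature_table(
            sup[m], m, run.gene_expr, run.mature_expr, min_samples=min_samples
        )
        if isinstance(ft, predict_mod.FeatureTable) and isinstance(
            fts, predict_mod.FeatureTable
        ):
            tables.append(ft)
            sup_tables.append(fts)
    reps_o, reps_sw, t_sw, p_sw = predict_mod.control_swapped_nets(
        tables, seed=seed, grid=grid, cv_folds=cv_folds
    )
    _, reps_su, t_su, p_su = predict_mod.control_superset_features(
        tables, sup_tables, seed=seed, grid=grid, cv_folds=cv_folds
    )
    return {
        "mirnas": [ft.mirna_id for ft in tables],
        "causal": [r.accuracy for r in reps_o],
        "swapped": [r.accuracy for r in reps_sw],
        "superset": [r.accuracy for r in reps_su],
        "t_swapped": t_sw,
        "p_swapped": p_sw,
        "t_superset": t_su,
        "p_superset": p_su,
        "run": run,
    }


@dataclass
class PipelineRun:
    """Everything one synthetic end-to-end run produced."""

    gt: GroundTruth
    loci: list
    binding_sites: list
    networks: dict
    gene_expr: ExpressionMatrix
    pre_expr: ExpressionMatrix
    mature_expr: ExpressionMatrix

    def recovered_rbp_edges(self) -> set:
        """Significant RBP -> miRNA-node edges, in ground-truth naming."""
        edges = set()
        for (mirna, step), res in self.networks.items():
            for a in res.assocs:
                if a.target == res.net.target:
                    tgt = (
                        f"pre:{mirna}" if step == "pri_to_pre" else a.target
                    )
                    edges.add((a.source, tgt))
        return edges


def run_synthetic_pipeline(
    seed: int = 0,
    n_rbps: int = 5,
    n_ppi: int = 10,
    n_mirnas: int = 10,
    n_samples: int = 300,
    n_batches: int = 1,
    reads_per_true_site: float = 15,
    decoy_rate: float = 0.2,
    pen: PenaltySpec | None = None,
) -> PipelineRun:
    """Simulate inputs and run sites + network estimation end to end."""
    from .synth import simulate_truth

    gt = simulate_truth(
        n_rbps=n_rbps,
        n_ppi=n_ppi,
        n_mirnas=n_mirnas,
        n_batches=n_batches,
        seed=seed,
    )
    gene_expr, pre_expr, mature_expr, _sheet = simulate_expression(
        gt, n_samples=n_samples, n_batches=n_batches, seed=seed + 1
    )
    if n_batches > 1:
        from .expr import remove_batch_effects

        gene_expr = remove_batch_effects(gene_expr)
        pre_expr = remove_batch_effects(pre_expr)
        mature_expr = remove_batch_effects(mature_expr)
    loci = make_loci(gt)
    clip = simulate_clip(
        gt,
        loci,
        reads_per_true_site=reads_per_true_site,
        decoy_rate=decoy_rate,
        seed=seed + 2,
    )
    binding = call_sites(clip, loci)
    ppi_edges = [(s, t) for (s, t) in gt.dag if s in set(gt.ppi_genes)]
    networks = fit_networks(
        binding, ppi_edges, loci, gene_expr, pre_expr, mature_expr, pen=pen
    )
    return PipelineRun(
        gt=gt,
        loci=loci,
        binding_sites=binding,
        networks=networks,
        gene_expr=gene_expr,
        pre_expr=pre_expr,
        mature_expr=mature_expr,
    )
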