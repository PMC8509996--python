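"""Synthetic data emulating every input the pipeline consumes.

A ground truth is a layered signed DAG (PPI genes -> RBPs -> pre-miRNAs ->
mature miRNAs). Each miRNA gets one processing RBP (positive weight into its
pre-miRNA node) and one maturation RBP (positive weight into the mature
node, negative into the pre node — the functional sign convention the
screening step tests for), plus a moderate positive pre -> mature edge.
Expression is sampled ancestrally from the linear-Gaussian SEM, optionally
offset per batch, and shifted per row onto a non-negative scale (a constant
shift keeps the linear-Gaussian assumptions exactly satisfiable, unlike
exponentiation). CLIP reads are Poisson-distributed stacks at each true
binding position plus uniform decoy reads.

Default condition: 5 RBPs, 10 PPI genes, 10 miRNAs, 300 samples, edge
weights |U(0.5, 1.0)|, noise sd 0.25, two CLIP samples per RBP with ~10
reads per true site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expr import ExpressionMatrix
from .sites import ClipSample, GenomicInterval, build_pri_regions

__all__ = [
    "GroundTruth",
    "simulate_truth",
    "simulate_expression",
    "make_loci",
    "simulate_clip",
]


@dataclass
class GroundTruth:
    """A planted causal model over PPI genes, RBPs and miRNA nodes."""

    ppi_genes: list
    rbps: list
    mirna_ids: list
    dag: dict  # (source, target) -> signed weight
    binding_pairs: list  # (rbp, mirna, region) triples
    roles: dict = field(default_factory=dict)  # mirna -> {processing, maturation}
    batch_offsets: dict = field(default_factory=dict)
    noise_sd: float = 0.25
    rbp_noise_sd: float = 1.0  # RBPs' intrinsic (non-PPI) expression noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        G = nx.DiGraph(self.dag.keys())
        if not nx.is_directed_acyclic_graph(G):
            raise ValueError("planted dag contains a cycle")

    def pre_node(self, mirna: str) -> str:
        return f"pre:{mirna}"

    def mature_node(self, mirna: str) -> str:
        return f"{mirna}-mat"

    def rbp_mirna_edges(self) -> set:
        """Planted RBP -> miRNA-node edges (the recovery targets)."""
        nodes = set(self.rbps)
        return {(s, t) for s, t in self.dag if s in nodes}


def simulate_truth(
    n_rbps: int = 5,
    n_ppi: int = 10,
    n_mirnas: int = 10,
    edge_density: float = 0.3,
    weight_range=(0.5, 1.0),
    noise_sd: float = 0.25,
    n_batches: int = 1,
    seed: int = 0,
) -> GroundTruth:
    """Draw a layered ground-truth DAG.

    PPI -> RBP edges appear independently with probability ``edge_density``
    with weights uniform on +/-[weight_range], then rescaled per RBP so the
    summed squared input weight is 1 (comparable dynamic range across RBPs).
    Each miRNA is assigned a processing RBP (round-robin) and a distinct
    maturation RBP; their edge magnitudes are drawn from ``weight_range``
    with the signs fixed by role. The pre -> mature edge weight is weak,
    +U(0.1, 0.2). Deterministic under seed.
    """
    if min(n_rbps, n_ppi, n_mirnas) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    lo, hi = weight_range
    rng = np.random.default_rng(seed)
    ppi = [f"G{k}" for k in range(n_ppi)]
    rbps = [f"RBP{k}" for k in range(n_rbps)]
    mirnas = [f"mir{k}" for k in range(n_mirnas)]

    dag: dict = {}
    for r in rbps:
        drawn = []
        for g in ppi:
            if rng.random() < edge_density:
                w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                drawn.append((g, float(w)))
        # normalize each RBP's incoming PPI signal to unit variance so all
        # RBPs have a comparable dynamic range regardless of in-degree
        norm = np.sqrt(sum(w * w for _, w in drawn)) or 1.0
        for g, w in drawn:
            dag[(g, r)] = w / norm

    binding_pairs = []
    roles = {}
    for i, mir in enumerate(mirnas):
        if n_rbps >= 2 * n_mirnas:
            # enough RBPs for private regulators per miRNA (distinct nets)
            proc, mat = rbps[2 * i], rbps[2 * i + 1]
        elif n_rbps >= 2:
            proc, mat = rbps[i % n_rbps], rbps[(i + 1) % n_rbps]
        else:
            proc, mat = None, rbps[0]
        pre, mature = f"pre:{mir}", f"{mir}-mat"
        if proc is not None:
            dag[(proc, pre)] = float(rng.uniform(lo, hi))
            binding_pairs.append((proc, mir, "pri"))
        dag[(mat, pre)] = -float(rng.uniform(lo, hi))
        dag[(mat, mature)] = float(rng.uniform(lo, hi))
        # weak precursor->mature coupling: the mature pool is dominated by
        # the processing machinery, not by precursor abundance alone, and a
        # strong coupling would cancel the maturation RBP's direct effect
        # (net effect w_mature - w_pre_mature * |w_pre|)
        dag[(pre, mature)] = float(rng.uniform(0.1, 0.2))
        binding_pairs.append((mat, mir, "pre"))
        roles[mir] = {"processing": proc, "maturation": mat}

    offsets = {f"batch{j}": 3.0 * j for j in range(n_batches)}
    return GroundTruth(
        ppi_genes=ppi,
        rbps=rbps,
        mirna_ids=mirnas,
        dag=dag,
        binding_pairs=binding_pairs,
        roles=roles,
        batch_offsets=offsets,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_expression(
    gt: GroundTruth,
    n_samples: int = 300,
    n_batches: int = 1,
    seed: int = 0,
    shift_floor: float = 0.25,
    condition: str = "cond0",
    tissue: str = "tissue0",
):
    """Sample expression matrices from the planted SEM.

    Root nodes are N(0, 1); every child is the weighted sum of its parents
    plus Gaussian noise (sd ``gt.rbp_noise_sd`` for RBP nodes — regulators
    keep substantial intrinsic variation — and ``gt.noise_sd`` for miRNA
    nodes). Batch offsets (from ``gt.batch_offsets``, by sample
    block) are added to every row, then each row is shifted so its minimum
    equals ``shift_floor`` (>= 0). Returns (gene, pre, mature) expression
    matrices and a sample sheet (sample, batch, condition, tissue).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    G = nx.DiGraph()
    all_nodes = (
        list(gt.ppi_genes)
        + list(gt.rbps)
        + [gt.pre_node(m) for m in gt.mirna_ids]
        + [gt.mature_node(m) for m in gt.mirna_ids]
    )
    G.add_nodes_from(all_nodes)
    G.add_edges_from(gt.dag.keys())
    order = list(nx.topological_sort(G))

    rbp_set = set(gt.rbps)
    values = {}
    for node in order:
        parents = list(G.predecessors(node))
        if not parents:
            noise_scale = 1.0
        elif node in rbp_set:
            noise_scale = gt.rbp_noise_sd
        else:
            noise_scale = gt.noise_sd
        x = rng.normal(0.0, noise_scale, size=n_samples)
        for par in parents:
            x = x + gt.dag[(par, node)] * values[par]
        values[node] = x

    samples = [f"s{k:04d}" for k in range(n_samples)]
    batch_names = sorted(gt.batch_offsets) or ["batch0"]
    if n_batches > len(batch_names):
        batch_names = [f"batch{j}" for j in range(n_batches)]
    batch_names = batch_names[:max(1, n_batches)]
    batch_of = {s: batch_names[k % len(batch_names)] for k, s in enumerate(samples)}
    offset = np.array(
        [gt.batch_offsets.get(batch_of[s], 3.0 * batch_names.index(batch_of[s]))
         for s in samples]
    )

    def matrix(rows) -> ExpressionMatrix:
        if not rows:
            return ExpressionMatrix(
                pd.DataFrame(np.empty((0, n_samples)), columns=samples),
                batch=dict(batch_of),
                condition={s: condition for s in samples},
            )
        M = np.vstack([values[r] for r in rows]) + offset[None, :]
        M = M - M.min(axis=1, keepdims=True) + shift_floor
        df = pd.DataFrame(M, index=rows, columns=samples)
        return ExpressionMatrix(
            df,
            batch=dict(batch_of),
            condition={s: condition for s in samples},
        )

    gene_expr = matrix(list(gt.ppi_genes) + list(gt.rbps))
    pre_expr = matrix([gt.pre_node(m) for m in gt.mirna_ids])
    pre_expr.values.index = list(gt.mirna_ids)  # pre rows keyed by miRNA id
    mature_expr = matrix([gt.mature_node(m) for m in gt.mirna_ids])
    sheet = pd.DataFrame(
        {
            "sample": samples,
            "batch": [batch_of[s] for s in samples],
            "condition": condition,
            "tissue": tissue,
        }
    )
    return gene_expr, pre_expr, mature_expr, sheet


def make_loci(
    gt: GroundTruth,
    chrom: str = "chr1",
    pre_length: int = 80,
    spacing: int = 5000,
    flank: int = 1000,
):
    """Fabricate genomic coordinates for the planted miRNAs."""
    entries = []
    for i, mir in enumerate(gt.mirna_ids):
        start = flank + 500 + i * spacing
        entries.append(
            (mir, GenomicInterval(chrom, start, start + pre_length, "+"),
             (gt.mature_node(mir),))
        )
    return build_pri_regions(entries, flank=flank)


def simulate_clip(
    gt: GroundTruth,
    loci,
    reads_per_true_site: float = 15,
    decoy_rate: float = 0.2,
    n_samples_per_rbp: int = 2,
    read_length: int = 30,
    seed: int = 0,
) -> list:
    """CLIP read sets: Poisson stacks at true sites plus uniform decoys.

    Per RBP sample, every true (rbp, mirna, region) binding position gets
    Poisson(``reads_per_true_site``) reads (with +/-3 bp start jitter);
    decoys are Poisson(``decoy_rate`` per kb of pri region) uniform reads on
    every locus. Processing (pri) sites sit 400 bp upstream of the hairpin,
    maturation (pre) sites at the hairpin centre.
    """
    if n_samples_per_rbp < 2:
        raise ValueError("need >= 2 samples per RBP")
    rng = np.random.default_rng(seed)
    locus_of = {l.mirna_id: l for l in loci}
    pairs_of: dict = {}
    for rbp, mir, region in gt.binding_pairs:
        pairs_of.setdefault(rbp, []).append((mir, region))

    out = []
    for rbp in sorted(gt.rbps):
        for k in range(n_samples_per_rbp):
            reads = []
            for mir, region in pairs_of.get(rbp, []):
                locus = locus_of[mir]
                if region == "pre":
                    pos = (locus.pre.start + locus.pre.end) // 2 - read_length // 2
                else:
                    pos = max(locus.pri.start, locus.pre.start - 400)
                n_reads = rng.poisson(reads_per_true_site)
                for _ in range(n_reads):
                    start = max(locus.pri.start, pos + int(rng.integers(-3, 4)))
                    reads.append(
                        GenomicInterval(
                            locus.pri.chrom, start, start + read_length,
                            locus.pri.strand,
                        )
                    )
            for locus in loci:
                lam = decoy_rate * len(locus.pri) / 1000.0
                for _ in range(rng.poisson(lam)):
                    start = int(
                        rng.integers(locus.pri.start, locus.pri.end - read_length)
                    )
                    reads.append(
                        GenomicInterval(
                            locus.pri.chrom, start, start + read_length,
                            locus.pri.strand,
                        )
                    )
            out.append(
                ClipSample(
                    rbp_id=rbp,
                    sample_id=f"{rbp}_s{k}",
                    condition="cond0",
                    reads=reads,
                )
            )
    return out
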