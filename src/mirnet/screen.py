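"""Functional screening and validation of miRNA:RBP associations.

Network-derived associations are screened against expression correlations
(|r| >= 0.6 by default) with step-specific sign rules: an RBP processing
pri->pre should correlate positively with the pre-miRNA, while an RBP
driving maturation should correlate positively with the mature miRNA and
negatively with its precursor (signs mirrored for negatively associated
RBPs). Surviving combinations are re-tested across independent tissues,
compared against random miRNA:RBP pairs with Fisher's exact and binomial
tests, and miRNAs are clustered hierarchically with a shared-RBP
(intersection-over-union) reporting rule. A k-means utility quantifies how
well a feature subset separates two cell states.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .expr import ExpressionMatrix, pearson

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationRecord",
    "ClusterReport",
    "verify_associations",
    "cross_tissue_validation",
    "randomization_tests",
    "cluster_mirnas",
    "kmeans_state_separation",
]


@dataclass
class CombinationRecord:
    """A screened miRNA:RBP combination with its supporting correlations."""

    mirna_id: str
    rbp_id: str
    step: str
    sign: str = "positive"
    r_pre: float | None = None
    r_mature: float | None = None
    tissues_present: set = field(default_factory=set)


@dataclass
class ClusterReport:
    cluster_id: int
    member_mirnas: list
    shared_rbps: list
    shared_fraction: float


def _row(expr: ExpressionMatrix, key: str):
    if key not in expr.values.index:
        return None
    return expr.values.loc[key].to_numpy(dtype=float)


def _passes_sign_rule(step, sign, r_pre, r_mature, cutoff):
    """Step/sign-specific correlation rule for one combination."""
    flip = -1.0 if sign == "negative" else 1.0
    if step == "pri_to_pre":
        return r_pre is not None and flip * r_pre >= cutoff
    # maturation: +mature and -pre for positively associated RBPs
    return (
        r_mature is not None
        and r_pre is not None
        and flip * r_mature >= cutoff
        and flip * r_pre <= -cutoff
    )


def _mirna_of(assoc):
    return assoc.target.removeprefix("pre:").removesuffix("-mat")


def verify_associations(
    assocs,
    pre_expr: ExpressionMatrix,
    mature_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    cutoff: float = 0.6,
) -> list:
    """Screen RBP->miRNA associations by expression correlation sign rules.

    Only edges whose target is a miRNA node are screened (back-chain PPI
    edges pass through the network, not this filter). Associations with
    missing expression rows are skipped and logged.
    """
    out = []
    for a in assocs:
        mirna = _mirna_of(a)
        rbp = _row(gene_expr, a.source)
        pre = _row(pre_expr, mirna)
        mature = _row(mature_expr, a.target) if a.step == "pre_to_mature" else None
        if rbp is None or pre is None or (a.step == "pre_to_mature" and mature is None):
            logger.info("skipping %s->%s: missing expression row", a.source, a.target)
            continue
        r_pre = pearson(rbp, pre)
        r_mature = pearson(rbp, mature) if mature is not None else None
        if _passes_sign_rule(a.step, a.sign, r_pre, r_mature, cutoff):
            out.append(
                CombinationRecord(
                    mirna_id=mirna,
                    rbp_id=a.source,
                    step=a.step,
                    sign=a.sign,
                    r_pre=r_pre,
                    r_mature=r_mature,
                )
            )
    return out


def _combo_present(combo, exprs, cutoff) -> bool:
    """Does one combination meet its sign rule in one tissue's matrices?"""
    gene_expr, pre_expr, mature_expr = exprs
    rbp = _row(gene_expr, combo.rbp_id)
    pre = _row(pre_expr, combo.mirna_id)
    if rbp is None or pre is None:
        return False
    r_pre = pearson(rbp, pre)
    r_mature = None
    if combo.step == "pre_to_mature":
        mat_key = f"{combo.mirna_id}-mat"
        mature = _row(mature_expr, mat_key)
        if mature is None and mature_expr.values.index.size:
            # fall back to the mirna id itself if mature rows use it
            mature = _row(mature_expr, combo.mirna_id)
        if mature is None:
            return False
        r_mature = pearson(rbp, mature)
    return _passes_sign_rule(combo.step, combo.sign, r_pre, r_mature, cutoff)


def cross_tissue_validation(combos, tissue_exprs: dict, cutoff: float = 0.6) -> Counter:
    """Count, per combination, the tissues where its sign rule holds.

    ``tissue_exprs`` maps tissue -> (gene, pre, mature) ExpressionMatrix
    triple. Each combo's ``tissues_present`` is filled in place; the return
    value is the histogram {number of tissues present: combo count}.
    """
    if not tissue_exprs:
        raise ValueError("need at least one tissue dataset")
    hist: Counter = Counter()
    for combo in combos:
        present = {
            tissue
            for tissue, exprs in tissue_exprs.items()
            if _combo_present(combo, exprs, cutoff)
        }
        combo.tissues_present = present
        hist[len(present)] += 1
    return hist


def randomization_tests(
    combos,
    universe_mirnas,
    universe_rbps,
    n_random: int,
    tissue_exprs: dict,
    cutoff: float = 0.6,
    seed: int = 0,
    min_tissues: int = 1,
    step: str = "pre_to_mature",
):
    """Random-background significance tests for cross-tissue presence.

    Draws ``n_random`` miRNA:RBP pairs uniformly without replacement from
    the universe cross-product minus the observed pairs, evaluates the same
    sign rule across tissues, and returns (fisher_p, binomial_p_list) where
    the Fisher 2x2 table dichotomizes on presence in >= ``min_tissues``
    tissues and each observed combo gets a one-sided binomial p against the
    random-background per-tissue presence rate.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = np.random.default_rng(seed)
    observed_pairs = {(c.mirna_id, c.rbp_id) for c in combos}
    pool = [
        pair
        for pair in product(sorted(universe_mirnas), sorted(universe_rbps))
        if pair not in observed_pairs
    ]
    if n_random > len(pool):
        raise ValueError("n_random exceeds the available random pairs")
    pick = rng.choice(len(pool), size=n_random, replace=False)
    random_combos = [
        CombinationRecord(mirna_id=pool[k][0], rbp_id=pool[k][1], step=step)
        for k in sorted(pick)
    ]
    cross_tissue_validation(random_combos, tissue_exprs, cutoff)

    n_tissues = len(tissue_exprs)
    obs_hits = sum(1 for c in combos if len(c.tissues_present) >= min_tissues)
    rnd_hits = sum(1 for c in random_combos if len(c.tissues_present) >= min_tissues)
    table = [
        [obs_hits, len(combos) - obs_hits],
        [rnd_hits, len(random_combos) - rnd_hits],
    ]
    fisher_p = float(stats.fisher_exact(table).pvalue)

    # per-tissue presence rate in the random background
    p0 = sum(len(c.tissues_present) for c in random_combos) / (
        n_random * n_tissues
    )
    binom_ps = []
    for c in combos:
        k = len(c.tissues_present)
        if p0 == 0.0:
            binom_ps.append(1.0 if k == 0 else 0.0)
        else:
            binom_ps.append(
                float(
                    stats.binomtest(k, n_tissues, p0, alternative="greater").pvalue
                )
            )
    return fisher_p, binom_ps


def _shared_fraction(members, assoc_map) -> float:
    sets = [set(assoc_map.get(m, set())) for m in members]
    union = set().union(*sets)
    if not union:
        return 0.0
    inter = set(sets[0]).intersection(*sets[1:])
    return len(inter) / len(union)


def cluster_mirnas(
    mirna_expr: ExpressionMatrix, assoc_map: dict, shared_threshold: float = 0.8
) -> list:
    """Hierarchically cluster miRNAs; report groups sharing >=80% of RBPs.

    Average linkage on correlation distance (1 - r). A dendrogram node
    qualifies when the intersection-over-union of its members' RBP sets
    meets ``shared_threshold``; the maximal qualifying nodes (no qualifying
    ancestor) with >= 2 members are reported.
    """
    ids = list(mirna_expr.values.index)
    if len(ids) < 2:
        return []
    X = mirna_expr.values.to_numpy(dtype=float)
    r = np.corrcoef(X)
    D = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    root = to_tree(Z)

    reports: list = []

    def walk(node, ancestor_qualifies: bool) -> None:
        members = [ids[i] for i in node.pre_order()]
        qualifies = (
            len(members) >= 2
            and _shared_fraction(members, assoc_map) >= shared_threshold
        )
        if qualifies and not ancestor_qualifies:
            sets = [set(assoc_map.get(m, set())) for m in members]
            shared = sorted(set(sets[0]).intersection(*sets[1:]))
            reports.append(
                ClusterReport(
                    cluster_id=len(reports),
                    member_mirnas=sorted(members),
                    shared_rbps=shared,
                    shared_fraction=_shared_fraction(members, assoc_map),
                )
            )
        if not node.is_leaf():
            walk(node.left, ancestor_qualifies or qualifies)
            walk(node.right, ancestor_qualifies or qualifies)

    walk(root, False)
    reports.sort(key=lambda c: c.member_mirnas)
    for k, rep in enumerate(reports):
        rep.cluster_id = k
    return reports


def kmeans_state_separation(
    expr_subset: ExpressionMatrix, labels: dict, k: int = 2, seed: int = 0
) -> float:
    """Agreement between k-means sample clusters and known state labels.

    Samples are clustered on the feature rows of ``expr_subset``; agreement
    is the best fraction of correctly grouped samples over all assignments
    of cluster ids to states. Deterministic under ``seed``.
    """
    cols = list(expr_subset.values.columns)
    states = sorted({labels[c] for c in cols})
    if len(states) < 2:
        raise ValueError("both states must be present")
    if k > len(cols):
        raise ValueError("k exceeds the number of samples")
    X = expr_subset.values.to_numpy(dtype=float).T  # samples x features
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    truth = np.array([states.index(labels[c]) for c in cols])

    from itertools import permutations

    best = 0.0
    for perm in permutations(range(k), len(states)):
        mapped = np.array([perm[t] for t in truth])
        best = max(best, float(np.mean(mapped == assign)))
    return best
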