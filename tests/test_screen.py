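"""Functional screening: sign rules, cross-tissue counts, randomization,
miRNA clustering and cell-state separation."""

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from mirnet.bayesnet import SignedAssociation
from mirnet.expr import ExpressionMatrix
from mirnet.screen import (
    CombinationRecord,
    cluster_mirnas,
    cross_tissue_validation,
    kmeans_state_separation,
    randomization_tests,
    verify_associations,
)


def _expr(rows: dict, samples=None):
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


def _assoc(source, target, weight, step):
    return SignedAssociation(
        source=source,
        target=target,
        sign="positive" if weight > 0 else "negative",
        weight=weight,
        pvalue=0.001,
        step=step,
    )


def _coupled_fixture(r_mature=0.9, r_pre=-0.7, n=200, seed=0):
    """RBP vector plus pre/mature vectors with controlled correlations."""
    rng = np.random.default_rng(seed)
    rbp = rng.normal(size=n)

    def corr_with(r):
        noise = rng.normal(size=n)
        noise -= noise.mean()
        noise -= rbp * (rbp @ noise) / (rbp @ rbp)  # orthogonalize
        v = r * (rbp - rbp.mean()) / rbp.std() + np.sqrt(1 - r * r) * noise / noise.std()
        return v

    return rbp, corr_with(r_pre), corr_with(r_mature)


class TestVerifyAssociations:
    def test_maturation_rbp_with_stated_signs_kept(self):
        rbp, pre, mat = _coupled_fixture(0.9, -0.7)
        genes = _expr({"R": rbp})
        pres = _expr({"m1": pre})
        mats = _expr({"m1-mat": mat})
        out = verify_associations(
            [_assoc("R", "m1-mat", 0.8, "pre_to_mature")], pres, mats, genes
        )
        assert len(out) == 1
        assert out[0].r_mature == pytest.approx(0.9, abs=0.02)
        assert out[0].r_pre == pytest.approx(-0.7, abs=0.02)

    def test_below_cutoff_dropped(self):
        rbp, pre, mat = _coupled_fixture(0.5, -0.7)
        out = verify_associations(
            [_assoc("R", "m1-mat", 0.8, "pre_to_mature")],
            _expr({"m1": pre}),
            _expr({"m1-mat": mat}),
            _expr({"R": rbp}),
        )
        assert out == []

    def test_processing_rbp_positive_pre_kept(self):
        rbp, pre, _ = _coupled_fixture(0.9, 0.8)
        out = verify_associations(
            [_assoc("R", "pre:m1", 0.7, "pri_to_pre")],
            _expr({"m1": pre}),
            _expr({"m1-mat": rbp}),  # unused for this step
            _expr({"R": rbp}),
        )
        assert len(out) == 1 and out[0].step == "pri_to_pre"

    def test_negative_association_mirrored_rule(self):
        rbp, pre, _ = _coupled_fixture(0.9, -0.8)
        out = verify_associations(
            [_assoc("R", "pre:m1", -0.7, "pri_to_pre")],
            _expr({"m1": pre}),
            _expr({"m1-mat": rbp}),
            _expr({"R": rbp}),
        )
        assert len(out) == 1 and out[0].sign == "negative"

    def test_missing_row_skipped_not_raised(self):
        rbp, pre, mat = _coupled_fixture()
        out = verify_associations(
            [_assoc("ABSENT", "m1-mat", 0.8, "pre_to_mature")],
            _expr({"m1": pre}),
            _expr({"m1-mat": mat}),
            _expr({"R": rbp}),
        )
        assert out == []

    def test_survivors_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        n = 100
        assocs, genes, pres, mats = [], {}, {}, {}
        for k in range(12):
            rbp, pre, mat = _coupled_fixture(
                rng.uniform(0.3, 0.95), -rng.uniform(0.3, 0.95), n=n, seed=k
            )
            genes[f"R{k}"], pres[f"m{k}"], mats[f"m{k}-mat"] = rbp, pre, mat
            assocs.append(_assoc(f"R{k}", f"m{k}-mat", 0.5, "pre_to_mature"))
        ge, pe, me = _expr(genes), _expr(pres), _expr(mats)
        kept = [
            {(c.rbp_id, c.mirna_id) for c in verify_associations(assocs, pe, me, ge, cutoff=c)}
            for c in (0.3, 0.5, 0.7, 0.9)
        ]
        for a, b in zip(kept, kept[1:]):
            assert b <= a


class TestPlantedSignStructure:
    def test_planted_pairs_retained_decoys_rejected(self):
        """Strongly coupled planted regulators (weights 0.85-1.0, node noise
        0.2 — chosen so the population correlations clear the 0.6 cutoff
        with margin) are retained >=90% at n=200 while decoy RBPs claimed
        for foreign miRNAs are rejected."""
        from mirnet.synth import simulate_expression, simulate_truth

        kept_p = tot_p = kept_d = tot_d = 0
        for seed in range(5):
            gt = simulate_truth(
                n_rbps=10, n_ppi=10, n_mirnas=10,
                weight_range=(0.85, 1.0), noise_sd=0.2, seed=seed,
            )
            gene, pre, mature, _ = simulate_expression(gt, n_samples=200, seed=seed + 50)
            planted, decoys = [], []
            rng = np.random.default_rng(seed)
            for mir, roles in gt.roles.items():
                proc, mat = roles["processing"], roles["maturation"]
                planted.append(_assoc(proc, f"pre:{mir}", 0.9, "pri_to_pre"))
                planted.append(_assoc(mat, f"{mir}-mat", 0.9, "pre_to_mature"))
                others = [r for r in gt.rbps if r not in (proc, mat)]
                for r in rng.choice(others, size=2, replace=False):
                    decoys.append(_assoc(r, f"pre:{mir}", 0.9, "pri_to_pre"))
                    decoys.append(_assoc(r, f"{mir}-mat", 0.9, "pre_to_mature"))
            kept_p += len(verify_associations(planted, pre, mature, gene))
            tot_p += len(planted)
            kept_d += len(verify_associations(decoys, pre, mature, gene))
            tot_d += len(decoys)
        assert kept_p / tot_p >= 0.9
        assert kept_d / tot_d <= 0.1


class TestCrossTissue:
    def _tissues(self, present_in):
        """combo present (strong sign-consistent correlations) per tissue."""
        tissues = {}
        for t in range(3):
            seed = 100 + t
            if t in present_in:
                rbp, pre, mat = _coupled_fixture(0.9, -0.8, seed=seed)
            else:
                rbp, pre, mat = _coupled_fixture(0.1, -0.1, seed=seed)
            tissues[f"T{t}"] = (
                _expr({"R": rbp}), _expr({"m1": pre}), _expr({"m1-mat": mat})
            )
        return tissues

    def _combo(self):
        return CombinationRecord("m1", "R", "pre_to_mature", "positive")

    def test_all_tissues_bin(self):
        hist = cross_tissue_validation([self._combo()], self._tissues({0, 1, 2}))
        assert hist == Counter({3: 1})

    def test_nowhere_bin_zero(self):
        hist = cross_tissue_validation([self._combo()], self._tissues(set()))
        assert hist == Counter({0: 1})

    def test_histogram_matches_recount_oracle(self):
        tissues = self._tissues({0, 2})
        combos = [self._combo() for _ in range(4)]
        hist = cross_tissue_validation(combos, tissues)
        manual = Counter(len(c.tissues_present) for c in combos)
        assert hist == manual == Counter({2: 4})


class TestRandomization:
    def _setup(self, n_obs=8, seed=0):
        tissues = {}
        genes, pres, mats = {}, {}, {}
        rng = np.random.default_rng(seed)
        universe_m = [f"m{k}" for k in range(30)]
        universe_r = [f"R{k}" for k in range(20)]
        for t in range(2):
            g, p, ma = {}, {}, {}
            for r in universe_r:
                g[r] = rng.normal(size=50)
            for m in universe_m:
                p[m] = rng.normal(size=50)
                ma[f"{m}-mat"] = rng.normal(size=50)
            tissues[f"T{t}"] = (_expr(g), _expr(p), _expr(ma))
        combos = [
            CombinationRecord(f"m{k}", f"R{k}", "pre_to_mature", "positive")
            for k in range(n_obs)
        ]
        return combos, universe_m, universe_r, tissues

    def test_seeded_determinism(self):
        combos, um, ur, tissues = self._setup()
        a = randomization_tests(combos, um, ur, 150, tissues, seed=7)
        b = randomization_tests(combos, um, ur, 150, tissues, seed=7)
        assert a[0] == b[0] and a[1] == b[1]

    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 table (90/100 observed present, 5/100 random present):
        # Fisher p equals the exhaustive hypergeometric tail sum
        table = np.array([[90, 10], [5, 95]])
        got = stats.fisher_exact(table, alternative="two-sided").pvalue
        # enumerate all tables with the same margins
        N = table.sum(); row1 = table[0].sum(); col1 = table[:, 0].sum()
        probs = [
            stats.hypergeom.pmf(k, N, row1, col1)
            for k in range(max(0, row1 + col1 - N), min(row1, col1) + 1)
        ]
        p_obs = stats.hypergeom.pmf(table[0, 0], N, row1, col1)
        want = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert got == pytest.approx(want, rel=1e-9)

    def test_identical_distributions_fisher_near_one(self):
        combos, um, ur, tissues = self._setup()
        fisher_p, binom_ps = randomization_tests(
            combos, um, ur, 400, tissues, cutoff=0.9, seed=3
        )
        # with an extreme cutoff nothing is present anywhere: p == 1
        assert fisher_p == pytest.approx(1.0)
        assert all(p == 1.0 for p in binom_ps)


def _exhaustive_cut_oracle(values, assoc_map, threshold):
    """Collect qualifying clusters over every cut height; keep maximal."""
    ids = list(values.index)
    r = np.corrcoef(values.to_numpy())
    D = np.clip(1 - r, 0, 2)
    np.fill_diagonal(D, 0)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = sorted(set(Z[:, 2])) + [np.inf]
    seen = set()
    for h in heights:
        labels = fcluster(Z, t=h, criterion="distance")
        for lab in set(labels):
            members = tuple(sorted(ids[i] for i in np.flatnonzero(labels == lab)))
            if len(members) < 2:
                continue
            sets = [set(assoc_map.get(m, set())) for m in members]
            union = set().union(*sets)
            inter = set(sets[0]).intersection(*sets[1:])
            if union and len(inter) / len(union) >= threshold:
                seen.add(members)
    return {m for m in seen if not any(set(m) < set(o) for o in seen if o != m)}


class TestClusterMirnas:
    def test_identical_pair_single_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        m = ExpressionMatrix(pd.DataFrame([x, x + 1e-9], index=["m1", "m2"]))
        reports = cluster_mirnas(m, {"m1": {"A", "B"}, "m2": {"A", "B"}})
        assert len(reports) == 1
        assert reports[0].member_mirnas == ["m1", "m2"]
        assert reports[0].shared_fraction == 1.0

    def test_four_of_six_shared_not_reported(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        m = ExpressionMatrix(pd.DataFrame([x, x + 1e-9], index=["m1", "m2"]))
        amap = {"m1": {"A", "B", "C", "D", "E"}, "m2": {"A", "B", "C", "D", "F"}}
        assert cluster_mirnas(m, amap, shared_threshold=0.8) == []
        # 4/6 ~ 0.67 passes a 0.6 threshold
        assert len(cluster_mirnas(m, amap, shared_threshold=0.6)) == 1

    def test_matches_exhaustive_cut_oracle(self, rng):
        n_mir, n_samp = 12, 30
        base = rng.normal(size=(3, n_samp))
        rows, amap = [], {}
        rbp_pool = [f"R{i}" for i in range(6)]
        for k in range(n_mir):
            g = k % 3
            rows.append(base[g] + rng.normal(scale=0.4, size=n_samp))
            amap[f"m{k}"] = set(
                rng.choice(rbp_pool, size=rng.integers(2, 5), replace=False)
            )
        m = ExpressionMatrix(
            pd.DataFrame(rows, index=[f"m{k}" for k in range(n_mir)])
        )
        got = {tuple(c.member_mirnas) for c in cluster_mirnas(m, amap, 0.5)}
        want = _exhaustive_cut_oracle(m.values, amap, 0.5)
        assert got == want

    def test_single_mirna_no_clustering(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["m1"]))
        assert cluster_mirnas(m, {"m1": {"A"}}) == []


class TestKmeansSeparation:
    def test_separable_states_full_agreement(self, rng):
        a = rng.normal(0, 0.3, size=(5, 10))
        b = rng.normal(6, 0.3, size=(5, 10))
        m = ExpressionMatrix(
            pd.DataFrame(
                np.hstack([a, b]),
                index=[f"g{i}" for i in range(5)],
                columns=[f"s{i}" for i in range(20)],
            )
        )
        labels = {f"s{i}": ("tumor" if i >= 10 else "normal") for i in range(20)}
        assert kmeans_state_separation(m, labels, seed=0) == 1.0

    def test_homogeneous_group_near_chance(self):
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = ExpressionMatrix(
                pd.DataFrame(
                    rng.normal(size=(4, 30)),
                    index=[f"g{i}" for i in range(4)],
                    columns=[f"s{i}" for i in range(30)],
                )
            )
            labels = {f"s{i}": ("a" if rng.random() < 0.5 else "b") for i in range(30)}
            if len(set(labels.values())) < 2:
                continue
            rates.append(kmeans_state_separation(m, labels, seed=seed))
        # agreement is the max over two labelings, so chance level is ~0.5-0.6
        assert 0.5 <= np.mean(rates) < 0.75

    def test_seeded_determinism(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(4, 12)),
                index=list("abcd"),
                columns=[f"s{i}" for i in range(12)],
            )
        )
        labels = {f"s{i}": ("x" if i % 2 else "y") for i in range(12)}
        assert kmeans_state_separation(m, labels, seed=5) == kmeans_state_separation(
            m, labels, seed=5
        )

    def test_k_exceeding_samples_is_error(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"]))
        with pytest.raises(ValueError, match="k exceeds"):
            kmeans_state_separation(m, {"s1": "a", "s2": "b"}, k=5)
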