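import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sproutnet as sn
from sproutnet.exceptions import ContractError
from sproutnet.gsea_engine import _es_from_positions, rank_genes

from conftest import expression_matrix


def ranked(metrics, genes=None):
    genes = genes or [chr(ord("a") + i) for i in range(len(metrics))]
    return pd.DataFrame({"gene": genes, "metric": list(map(float, metrics)),
                         "flagged": False})


def es_oracle(metrics, hit_mask, weight=1.0):
    """Brute-force running-sum walk (independent of the implementation)."""
    metrics = np.asarray(metrics, dtype=float)
    n = len(metrics)
    n_hits = int(np.sum(hit_mask))
    denom = np.sum(np.abs(metrics[hit_mask]) ** weight)
    running = []
    total = 0.0
    for i in range(n):
        if hit_mask[i]:
            total += (np.abs(metrics[i]) ** weight / denom) if denom > 0 \
                else 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        running.append(total)
    running = np.array(running)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


class TestRankGenes:
    def test_self_correlation_ranks_first(self):
        m = expression_matrix({"a": [1, 5, 2, 8, 3, 9],
                               "b": [4, 4, 4, 5, 5, 4],
                               "c": [9, 1, 8, 2, 7, 1]}, normalized=True)
        rl = rank_genes(m, m.values.loc["a"].to_numpy())
        assert rl["gene"].iloc[0] == "a"
        assert rl["metric"].iloc[0] == pytest.approx(1.0)

    def test_two_class_sigma_floor(self):
        """Constant groups engage the sigma floor: (3-1)/(0.6+0.2) = 2.5."""
        m = expression_matrix(
            {"a": [3, 3, 3, 1, 1, 1]},
            condition={"s1": "A", "s2": "A", "s3": "A",
                       "s4": "B", "s5": "B", "s6": "B"}, normalized=True)
        rl = rank_genes(m, {"s1": "A", "s2": "A", "s3": "A",
                            "s4": "B", "s5": "B", "s6": "B"},
                        positive_class="A")
        assert rl["metric"].iloc[0] == pytest.approx(2.5)

    def test_reversing_classes_negates_metrics(self):
        m = expression_matrix({"a": [5, 6, 7, 1, 2, 3],
                               "b": [1, 1, 2, 8, 9, 9]},
                              condition={f"s{i}": ("A" if i < 3 else "B")
                                         for i in range(6)}, normalized=True)
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        up = rank_genes(m, labels, positive_class="A").set_index("gene")
        down = rank_genes(m, labels, positive_class="B").set_index("gene")
        for g in ("a", "b"):
            assert up.at[g, "metric"] == pytest.approx(-down.at[g, "metric"])

    def test_zero_variance_gene_flagged_zero(self):
        m = expression_matrix({"a": [2, 2, 2, 2, 2, 2],
                               "b": [1, 2, 3, 4, 5, 6]}, normalized=True)
        rl = rank_genes(m, np.arange(6.0)).set_index("gene")
        assert rl.at["a", "metric"] == 0.0
        assert bool(rl.at["a", "flagged"])


class TestEnrichmentScore:
    def test_top_gene_hand_walk(self):
        es, running, le = sn.enrichment_score(ranked([5, 4, 3, 2, 1]), ["a"])
        assert es == 1.0
        np.testing.assert_allclose(running, [1.0, 0.75, 0.5, 0.25, 0.0])
        assert le == ["a"]

    def test_bottom_gene_hand_walk(self):
        es, running, le = sn.enrichment_score(ranked([5, 4, 3, 2, 1]), ["e"])
        assert es == -1.0
        np.testing.assert_allclose(running, [-0.25, -0.5, -0.75, -1.0, 0.0])
        assert le == ["e"]

    def test_full_set_degenerate(self):
        es, _, le = sn.enrichment_score(ranked([5, 4, 3, 2, 1]),
                                        list("abcde"))
        assert es == 1.0
        assert le == list("abcde")

    def test_no_overlap_rejected(self):
        with pytest.raises(ContractError):
            sn.enrichment_score(ranked([3, 2, 1]), ["zzz"])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        """ES equals an independent running-sum enumeration to 1e-12 on
        random lists of <= 20 genes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        metrics = np.round(np.sort(rng.normal(0, 2, n))[::-1], 6)
        rl = ranked(metrics, [f"g{i:02d}" for i in range(n)])
        k = int(rng.integers(1, n))
        pos = np.sort(rng.choice(n, k, replace=False))
        members = [rl["gene"].iloc[i] for i in pos]
        es, running, _ = sn.enrichment_score(rl, members)
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        es_ref, running_ref = es_oracle(metrics, hit)
        np.testing.assert_allclose(running, running_ref, atol=1e-12)
        assert abs(es - es_ref) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_negating_and_reversing_negates_es(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        metrics = np.sort(rng.normal(0, 1, n) + 1e-4)[::-1]
        rl = ranked(metrics, [f"g{i}" for i in range(n)])
        members = [f"g{i}" for i in rng.choice(n, 4, replace=False)]
        es_fwd, _, _ = sn.enrichment_score(rl, members)
        flipped = ranked(-metrics[::-1], [f"g{i}" for i in reversed(range(n))])
        es_rev, _, _ = sn.enrichment_score(flipped, members)
        if abs(abs(es_fwd) - abs(es_rev)) > 1e-12:
            raise AssertionError((es_fwd, es_rev))
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12) or \
            abs(es_fwd) == pytest.approx(abs(es_rev), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_vectorized_null_matches_plain_walk(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        metrics = np.sort(rng.normal(0, 2, n))[::-1]
        rl = ranked(metrics, [f"g{i:02d}" for i in range(n)])
        k = int(rng.integers(1, n))
        pos = np.sort(rng.choice(n, k, replace=False))
        es_plain, _, _ = sn.enrichment_score(
            rl, [rl["gene"].iloc[i] for i in pos])
        es_vec = _es_from_positions(pos[None, :], np.abs(metrics), n)[0]
        # sign may differ only at an exact positive/negative tie
        assert abs(abs(es_plain) - abs(es_vec)) < 1e-9

    def test_leading_edge_sits_at_or_before_maximum(self):
        rng = np.random.default_rng(1)
        metrics = np.sort(rng.normal(1, 1, 30))[::-1]
        rl = ranked(metrics, [f"g{i:02d}" for i in range(30)])
        members = [f"g{i:02d}" for i in [0, 2, 5, 20]]
        es, running, le = sn.enrichment_score(rl, members)
        assert es > 0
        i_max = int(np.argmax(running))
        positions = [rl.index[rl["gene"] == g][0] for g in le]
        assert all(p <= i_max for p in positions)
        assert set(le) <= set(members)


class TestRunGsea:
    def make_matrix(self, seed=0, n_genes=30, n_samples=6):
        rng = np.random.default_rng(seed)
        rows = {f"g{i:02d}": rng.normal(5, 1, n_samples)
                for i in range(n_genes)}
        return expression_matrix(rows, normalized=True)

    def test_exhaustive_geneset_permutation_matches_enumeration(self):
        """Universe of 8 genes, set size 3: the permutation p equals exact
        enumeration over all C(8,3) member sets."""
        m = self.make_matrix(seed=5, n_genes=8)
        profile = np.random.default_rng(9).normal(size=6)
        coll = sn.GeneSetCollection({"s": ["g00", "g03", "g06"]})
        res = sn.run_gsea(m, profile, coll, n_perm=math.comb(8, 3), seed=0)
        rl = rank_genes(m, profile)
        metrics = rl["metric"].to_numpy()
        genes = rl["gene"].tolist()
        es_obs, _ = None, None
        null = []
        for combo in combinations(range(8), 3):
            hit = np.zeros(8, dtype=bool)
            hit[list(combo)] = True
            es, _ = es_oracle(metrics, hit)
            null.append(es)
            if {genes[i] for i in combo} == {"g00", "g03", "g06"}:
                es_obs = es
        null = np.array(null)
        assert res["es"].iloc[0] == pytest.approx(es_obs, abs=1e-12)
        if es_obs >= 0:
            matched = null[null >= 0]
            p_ref = (1 + (matched >= es_obs - 1e-15).sum()) / (1 + matched.size)
        else:
            matched = null[null < 0]
            p_ref = (1 + (matched <= es_obs + 1e-15).sum()) / (1 + matched.size)
        assert res["p_perm"].iloc[0] == pytest.approx(p_ref)

    def test_geneset_permutation_invariant_to_sample_order(self):
        m = self.make_matrix(seed=2)
        cols = m.sample_ids
        labels = {c: ("A" if i < 3 else "B") for i, c in enumerate(cols)}
        coll = sn.GeneSetCollection({"s": ["g01", "g05", "g09", "g12"]})
        res1 = sn.run_gsea(m, labels, coll, n_perm=100, seed=7,
                           positive_class="A")
        order = [cols[i] for i in (3, 1, 5, 0, 4, 2)]
        m2 = sn.ExpressionMatrix(m.values[order], m.condition, m.kind,
                                 normalized=True)
        res2 = sn.run_gsea(m2, labels, coll, n_perm=100, seed=7,
                           positive_class="A")
        pd.testing.assert_frame_equal(res1.drop(columns="leading_edge"),
                                      res2.drop(columns="leading_edge"))

    def test_random_set_p_is_calibrated(self):
        """p for a uniformly random set is ~Uniform over 200 seeds (KS)."""
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            m = self.make_matrix(seed=seed, n_genes=50)
            profile = rng.normal(size=6)
            members = [f"g{i:02d}" for i in rng.choice(50, 8, replace=False)]
            coll = sn.GeneSetCollection({"s": members})
            res = sn.run_gsea(m, profile, coll, n_perm=200, seed=seed + 1000)
            pvals.append(res["p_perm"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_cohort_module_detected(self):
        cohort, sig, _, truth = sn.generate_cohort(
            100, [f"EC{i:03d}" for i in range(35)],
            [f"M{i:03d}" for i in range(40)], beta=0.5, noise_sd=1.0,
            responder_effect=0.8, seed=12)
        scores = sn.endothelial_score(cohort, sig)
        rng = np.random.default_rng(0)
        universe = cohort.feature_ids
        sets = {"module": truth.module_sets["cohort_module"]}
        for i in range(6):
            sets[f"rand{i}"] = sorted(
                rng.choice(universe, 30, replace=False).tolist())
        res = sn.run_gsea(cohort, scores.reindex(cohort.sample_ids),
                          sn.GeneSetCollection(sets), n_perm=500, seed=3)
        res = res.set_index("set_name")
        assert res.at["module", "fdr_q"] < 0.05
        assert res.at["module", "es"] > 0

    def test_phenotype_permutation_runs_and_detects(self):
        cohort, sig, labels, truth = sn.generate_cohort(
            60, [f"EC{i:03d}" for i in range(10)],
            [f"M{i:03d}" for i in range(20)], beta=0.5, noise_sd=1.0,
            responder_effect=1.5, seed=4, n_background=60)
        pheno = {s: ("R" if labels[s] else "N") for s in cohort.sample_ids}
        coll = sn.GeneSetCollection(
            {"module": truth.module_sets["cohort_module"]})
        res = sn.run_gsea(cohort, pheno, coll, n_perm=200, seed=5,
                          perm_type="phenotype", positive_class="R")
        assert res["p_perm"].iloc[0] < 0.05


class TestAssociationMatrix:
    def test_planted_anticorrelation_is_significant_negative(self, default_run):
        """An upregulated regulator miRNA is negatively associated with the
        module of its downregulated targets."""
        truth = default_run["truth"]
        mir_l = default_run["mir_n"].to_log2()
        gene_l = default_run["gene_n"].to_log2()
        up_regs = [m for m, d in truth.mirna_direction.items() if d == "up"
                   if m in mir_l.feature_ids]
        mir_sub = sn.ExpressionMatrix(mir_l.values.loc[up_regs[:2]],
                                      dict(mir_l.condition), "mirna",
                                      normalized=True, log_scale=True)
        coll = sn.GeneSetCollection(
            {"down_module": truth.module_sets["planted_down_module"]})
        am = sn.mirna_association_matrix(mir_sub, gene_l, coll, n_perm=300,
                                         seed=1)
        cell_nes = am.nes.loc["down_module", up_regs[0]]
        cell_q = am.fdr_q.loc["down_module", up_regs[0]]
        assert cell_nes < 0
        assert cell_q < 0.05

    def test_duplicate_mirna_profiles_give_identical_columns(self):
        rng = np.random.default_rng(0)
        gene_m = expression_matrix(
            {f"g{i:02d}": rng.normal(5, 1, 6) for i in range(25)},
            normalized=True)
        gene_m.log_scale = True
        profile = rng.normal(5, 1, 6)
        mir_m = expression_matrix({"mA": profile, "mB": profile},
                                  kind="mirna", normalized=True)
        mir_m.log_scale = True
        coll = sn.GeneSetCollection(
            {"s1": [f"g{i:02d}" for i in range(0, 8)],
             "s2": [f"g{i:02d}" for i in range(10, 20)]})
        am = sn.mirna_association_matrix(mir_m, gene_m, coll, n_perm=100,
                                         seed=2)
        pd.testing.assert_series_equal(am.nes["mA"], am.nes["mB"],
                                       check_names=False)
        pd.testing.assert_series_equal(am.fdr_q["mA"], am.fdr_q["mB"],
                                       check_names=False)

    def test_single_random_set_rarely_significant(self):
        """A 1x1 association matrix from a random set is non-significant in
        >= 90% of 50 seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            gene_m = expression_matrix(
                {f"g{i:02d}": rng.normal(5, 1, 6) for i in range(40)},
                normalized=True)
            gene_m.log_scale = True
            mir_m = expression_matrix({"m1": rng.normal(5, 1, 6)},
                                      kind="mirna", normalized=True)
            mir_m.log_scale = True
            members = [f"g{i:02d}" for i in rng.choice(40, 10, replace=False)]
            coll = sn.GeneSetCollection({"s": members})
            am = sn.mirna_association_matrix(mir_m, gene_m, coll, n_perm=200,
                                             seed=seed)
            assert am.nes.shape == (1, 1)
            hits += bool((am.fdr_q < 0.05).iloc[0, 0])
        assert hits <= 5
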