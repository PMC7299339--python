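from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sproutnet as sn
from sproutnet.exceptions import ContractError

from conftest import expression_matrix


def hypergeom_enumeration(k, K, n, N):
    """Exhaustive enumeration over all C(N, n) draws (exact rational)."""
    population = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return Fraction(hits, total)


class TestHypergeometricTest:
    def test_zero_successes_gives_one(self):
        assert sn.hypergeometric_test(0, 5, 5, 10).p_upper == 1.0

    def test_all_successes_small_case(self):
        res = sn.hypergeometric_test(5, 5, 5, 10)
        assert res.p_exact == Fraction(1, 252)

    def test_half_case(self):
        assert sn.hypergeometric_test(1, 2, 2, 4).p_exact == Fraction(5, 6)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed):
        """Exact rational agreement with full enumeration for N <= 12."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 13))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        res = sn.hypergeometric_test(k, K, n, N)
        assert res.p_exact == hypergeom_enumeration(k, K, n, N)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_survival_function(self, seed):
        """Independent cross-check against scipy for N <= 25."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 26))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        res = sn.hypergeometric_test(k, K, n, N)
        assert res.p_upper == pytest.approx(
            stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ContractError):
            sn.hypergeometric_test(6, 5, 5, 10)
        with pytest.raises(ContractError):
            sn.hypergeometric_test(1, 11, 5, 10)


class TestEndothelialScore:
    SIG = [f"EC{i:03d}" for i in range(35)]

    def test_dominant_sample_ranks_first(self):
        rng = np.random.default_rng(0)
        values = {g: rng.normal(0, 1, 10) for g in self.SIG[:5]}
        for g in values:
            values[g][3] += 10.0     # sample 3 dominates every gene
        cohort = expression_matrix(
            values, condition={f"t{i}": "tumor" for i in range(10)},
            normalized=True)
        scores = sn.endothelial_score(cohort, self.SIG[:5])
        assert scores.index[0] == "t3"

    def test_constant_gene_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        values = {"EC000": np.full(10, 3.0),
                  "EC001": rng.normal(0, 1, 10)}
        cohort = expression_matrix(
            values, condition={f"t{i}": "tumor" for i in range(10)},
            normalized=True)
        with pytest.warns(UserWarning):
            scores = sn.endothelial_score(cohort, ["EC000", "EC001"],
                                          min_present_fraction=0.0)
        z = (values["EC001"] - values["EC001"].mean()) / values["EC001"].std(ddof=1)
        np.testing.assert_allclose(
            scores.reindex([f"t{i}" for i in range(10)]).to_numpy(), z,
            atol=1e-12)

    def test_no_signature_gene_present_rejected(self):
        cohort = expression_matrix(
            {"X": np.arange(10.0)},
            condition={f"t{i}": "tumor" for i in range(10)}, normalized=True)
        with pytest.raises(ContractError):
            sn.endothelial_score(cohort, ["absent"])

    def test_recovers_latent_score(self):
        cohort, sig, _, truth = sn.generate_cohort(
            100, self.SIG, [f"M{i:03d}" for i in range(40)], beta=0.5,
            noise_sd=1.0, responder_effect=0.8, seed=7)
        scores = sn.endothelial_score(cohort, sig)
        r = np.corrcoef(scores.reindex(truth.latent_score.index),
                        truth.latent_score)[0, 1]
        assert r > 0.9

    def test_invariant_to_per_gene_affine_rescaling(self):
        cohort, sig, _, _ = sn.generate_cohort(
            50, self.SIG, [f"M{i:03d}" for i in range(10)], beta=0.5,
            noise_sd=1.0, responder_effect=0.0, seed=3)
        scores = sn.endothelial_score(cohort, sig)
        rng = np.random.default_rng(5)
        scaled = cohort.values.mul(rng.uniform(0.5, 4.0, len(cohort.values)),
                                   axis=0)
        scaled = scaled.add(rng.normal(0, 10, len(cohort.values)), axis=0)
        cohort2 = sn.ExpressionMatrix(scaled, dict(cohort.condition), "gene",
                                      normalized=True)
        scores2 = sn.endothelial_score(cohort2, sig)
        np.testing.assert_allclose(scores.sort_index(), scores2.sort_index(),
                                   atol=1e-10)


class TestModuleScoreCorrelation:
    SIG = [f"EC{i:03d}" for i in range(35)]
    MOD = [f"M{i:03d}" for i in range(40)]

    def test_module_equal_to_signature_gives_r_one(self):
        cohort, sig, _, _ = sn.generate_cohort(
            60, self.SIG, self.MOD, beta=0.5, noise_sd=1.0,
            responder_effect=0.0, seed=1)
        scores = sn.endothelial_score(cohort, sig)
        r, p = sn.module_score_correlation(cohort, sig, scores)
        assert r == pytest.approx(1.0)

    def test_null_beta_calibrated(self):
        """At beta=0, |r| < 2/sqrt(n) in most runs (analytic null scale)."""
        n, hits = 100, 0
        for seed in range(40):
            cohort, sig, _, _ = sn.generate_cohort(
                n, self.SIG, self.MOD, beta=0.0, noise_sd=1.0,
                responder_effect=0.0, seed=seed, module_shared_noise_sd=0.0)
            scores = sn.endothelial_score(cohort, sig)
            r, _ = sn.module_score_correlation(cohort, self.MOD, scores)
            hits += abs(r) < 2 / np.sqrt(n)
        assert hits >= 32    # ~95% nominal with slack

    def test_positive_beta_detected(self):
        cohort, sig, _, _ = sn.generate_cohort(
            100, self.SIG, self.MOD, beta=0.5, noise_sd=1.0,
            responder_effect=0.0, seed=2)
        scores = sn.endothelial_score(cohort, sig)
        r, p = sn.module_score_correlation(cohort, self.MOD, scores)
        assert r > 0 and p < 0.01

    def test_too_few_module_genes_rejected(self):
        cohort, sig, _, _ = sn.generate_cohort(
            20, self.SIG, self.MOD, beta=0.5, noise_sd=1.0,
            responder_effect=0.0, seed=0)
        scores = sn.endothelial_score(cohort, sig)
        with pytest.raises(ContractError):
            sn.module_score_correlation(cohort, ["M000"], scores)


class TestDdctAnalysis:
    @staticmethod
    def card(rows, conds=("control", "control", "treated", "treated")):
        samples = [f"s{i}" for i in range(len(conds))]
        table = pd.DataFrame(rows, index=samples).T
        return table, dict(zip(samples, conds))

    def test_hand_formula_boundary_fails_strict_threshold(self):
        # target: dCt_control = 3, dCt_treated = 5 -> ddCt = 2, rq = 0.25
        table, cond = self.card({
            "ref": [20.0, 20.0, 20.0, 20.0],
            "tgt": [23.0, 23.0, 25.0, 25.0],
        })
        res = sn.ddct_analysis(table, cond, reference_assays=["ref"])
        assert res.at["tgt", "ddct"] == pytest.approx(2.0)
        assert res.at["tgt", "rq"] == pytest.approx(0.25)
        assert not res.at["tgt", "passes_threshold"]

    def test_negative_shift_passes(self):
        table, cond = self.card({
            "ref": [20.0, 20.0, 20.0, 20.0],
            "tgt": [23.0, 23.0, 20.0, 20.0],   # ddCt = -3 -> rq = 8
        })
        res = sn.ddct_analysis(table, cond, reference_assays=["ref"])
        assert res.at["tgt", "ddct"] == pytest.approx(-3.0)
        assert res.at["tgt", "rq"] == pytest.approx(8.0)
        assert res.at["tgt", "passes_threshold"]

    def test_rq_log_inversion_identity(self):
        table, cond, truth = sn.generate_ct_card(
            15, [f"miR-{i+1:03d}" for i in range(4)], shift_ddct=2.7,
            seed=3, noise_sd=0.4)
        res = sn.ddct_analysis(table, cond,
                               reference_assays=truth.reference_assays)
        np.testing.assert_allclose(res["rq"] * 2.0 ** res["ddct"], 1.0,
                                   rtol=1e-12)

    def test_cluster_order_covers_survivors(self):
        table, cond, truth = sn.generate_ct_card(
            20, [f"miR-{i+1:03d}" for i in range(6)], shift_ddct=4.0,
            seed=5, noise_sd=0.2)
        res = sn.ddct_analysis(table, cond,
                               reference_assays=truth.reference_assays)
        survivors = set(res.index[res["passes_threshold"]])
        assert set(res.attrs["cluster_order"]) == survivors

    def test_missing_condition_rejected(self):
        table, cond = self.card({"ref": [20.0] * 4, "tgt": [22.0] * 4},
                                conds=("control",) * 4)
        with pytest.raises(ContractError):
            sn.ddct_analysis(table, cond, reference_assays=["ref"])
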