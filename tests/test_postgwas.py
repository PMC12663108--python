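"""Variant selection, replication statistics, and risk scores."""

import math

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_dataset, toy_cohort, toy_genotypes
from uvbgweis.gweis import ModelSpec, run_gweis
from uvbgweis.postgwas import (
    build_risk_scores,
    clump_leads,
    evaluate_risk_scores,
    sign_concordance_test,
    stepwise_conditional_selection,
    variance_explained,
    _ld_r2,
)


def _stats_frame(ids, ps, chrom=None, pos=None):
    m = len(ids)
    return pd.DataFrame(
        {
            "chromosome": chrom if chrom is not None else ["1"] * m,
            "base_pair_location": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "variant_id": ids,
            "p_joint": ps,
        }
    )


def greedy_clump_oracle(ids, ps, r2, threshold):
    """Exhaustively coded independent greedy clumping (oracle)."""
    order = np.lexsort((np.arange(len(ids)), ps))
    alive = set(order.tolist())
    leads = []
    for i in order:
        if i not in alive:
            continue
        leads.append(ids[i])
        for j in list(alive):
            if j != i and r2[i, j] >= threshold:
                alive.discard(j)
        alive.discard(i)
    return leads


class TestClumping:
    def test_single_significant_variant_is_its_own_lead(self, rng):
        dos = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        g = toy_genotypes(dos)
        res = _stats_frame(["v0", "v1", "v2"], [1e-9, 0.5, 0.9])
        out = clump_leads(res, g, p_threshold=5e-8)
        assert out.ids == ["v0"]

    def test_identical_columns_collapse_to_smaller_p(self, rng):
        dos = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        dos[:, 1] = dos[:, 0]
        g = toy_genotypes(dos)
        res = _stats_frame(["v0", "v1"], [1e-9, 1e-12])
        out = clump_leads(res, g, p_threshold=5e-8)
        assert out.ids == ["v1"]
        assert out.removed["v1"] == ["v0"]

    def test_three_block_fixture_matches_greedy_oracle(self, rng):
        # 3 LD blocks of 4 via shared latent signals
        n, m = 400, 12
        base = rng.standard_normal((n, 3))
        dos = np.empty((n, m))
        for j in range(m):
            latent = 0.9 * base[:, j // 4] + 0.45 * rng.standard_normal(n)
            dos[:, j] = np.clip(np.round(latent + 1), 0, 2)
        g = toy_genotypes(dos)
        ps = rng.uniform(1e-12, 1e-9, m)
        ids = [f"v{j}" for j in range(m)]
        res = _stats_frame(ids, ps)
        out = clump_leads(res, g, p_threshold=5e-8, r2_threshold=0.1)
        r2 = _ld_r2(dos)
        assert out.ids == greedy_clump_oracle(np.array(ids), ps, r2, 0.1)
        # invariant: pairwise r2 between leads below the threshold
        lead_idx = [ids.index(v) for v in out.ids]
        for a in lead_idx:
            for b in lead_idx:
                if a != b:
                    assert r2[a, b] < 0.1
        # every clumped variant is linked to its lead
        for lead, removed in out.removed.items():
            for v in removed:
                assert r2[ids.index(lead), ids.index(v)] >= 0.1

    def test_no_significant_variants_empty(self, rng):
        dos = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        res = _stats_frame(["v0", "v1"], [0.5, 0.7])
        out = clump_leads(res, toy_genotypes(dos), p_threshold=5e-8)
        assert out.ids == []


class TestStepwiseSelection:
    def test_perfect_ld_pair_collapses_to_one(self, rng):
        n = 3000
        cohort = toy_cohort(n, seed=11)
        g0 = rng.binomial(2, 0.4, n).astype(float)
        dos = np.column_stack([g0, g0, rng.binomial(2, 0.3, n).astype(float)])
        y = 0.4 * g0 + rng.standard_normal(n)
        cohort["pheno_std"] = (y - y.mean()) / y.std()
        sel = stepwise_conditional_selection(toy_genotypes(dos), cohort)
        assert len(sel.ids) == 1 and sel.ids[0] in ("v0", "v1")

    def test_two_unlinked_causal_variants_both_selected(self, rng):
        n = 5000
        cohort = toy_cohort(n, seed=12)
        g0 = rng.binomial(2, 0.4, n).astype(float)
        g1 = rng.binomial(2, 0.3, n).astype(float)
        noise = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        dos = np.column_stack([g0, noise[:, 0], g1, noise[:, 1:]])
        y = 0.25 * g0 + 0.25 * g1 + rng.standard_normal(n)
        cohort["pheno_std"] = (y - y.mean()) / y.std()
        sel = stepwise_conditional_selection(toy_genotypes(dos), cohort)
        assert sorted(sel.ids) == ["v0", "v2"]
        assert np.all(sel.conditional_p < 5e-8)

    def test_null_genotypes_select_nothing(self, rng):
        n = 1000
        cohort = toy_cohort(n, seed=13)
        dos = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        sel = stepwise_conditional_selection(toy_genotypes(dos), cohort)
        assert sel.ids == []


class TestVarianceExplained:
    def test_arithmetic(self):
        out = variance_explained(np.array([0.0, 0.1]), np.array([0.3, 0.5]))
        assert out["variance_explained"].iloc[0] == 0.0
        assert out["variance_explained"].iloc[1] == pytest.approx(0.005)
        assert out.attrs["total"] == pytest.approx(0.005)

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.array([0.1]), np.array([1.0]))

    def test_matches_empirical_r2_for_independent_causals(self, rng):
        n, m = 10_000, 30
        f = rng.uniform(0.1, 0.5, m)
        dos = (rng.random((n, m)) < f).astype(float) + (rng.random((n, m)) < f)
        beta = rng.normal(0, 0.05, m)
        y = dos @ beta + rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        # marginal dosage-scale effects on the standardized trait
        betas_std = np.array(
            [np.polyfit(dos[:, j], y, 1)[0] for j in range(m)]
        )
        freqs = dos.mean(axis=0) / 2
        total = variance_explained(betas_std, freqs).attrs["total"]
        x = np.column_stack([dos, np.ones(n)])
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        r2_emp = 1 - resid @ resid / (y @ y)
        assert total == pytest.approx(r2_emp, rel=0.2)


class TestSignConcordance:
    def test_perfect_concordance_closed_form(self):
        out = sign_concordance_test(np.ones(10), np.ones(10))
        assert out.p_binom == pytest.approx(2 * 2**-10, rel=1e-12)
        assert out.n_concordant == 10

    def test_central_value_capped_at_one(self, rng):
        d = np.ones(10)
        r = np.concatenate([np.ones(5), -np.ones(5)])
        out = sign_concordance_test(d, r)
        assert out.p_binom == 1.0

    def test_matches_binomial_enumeration(self):
        # 17/20 concordant: doubled tail sum of exact binomial terms
        d = np.ones(20)
        r = np.concatenate([np.ones(17), -np.ones(3)])
        out = sign_concordance_test(d, r)
        tail = sum(math.comb(20, k) for k in range(17, 21)) / 2**20
        assert out.p_binom == pytest.approx(min(1.0, 2 * tail), rel=1e-9)

    def test_flip_symmetry(self, rng):
        d = rng.standard_normal(30)
        r = rng.standard_normal(30)
        a = sign_concordance_test(d, r)
        b = sign_concordance_test(d, -r)
        both = sign_concordance_test(-d, -r)
        assert a.n_concordant == a.n_total - b.n_concordant
        assert both.n_concordant == a.n_concordant
        assert both.p_binom == pytest.approx(a.p_binom, rel=1e-12)

    def test_zero_betas_excluded(self):
        out = sign_concordance_test(
            np.array([1.0, 0.0, -1.0]), np.array([1.0, 1.0, -1.0])
        )
        assert out.n_total == 2 and out.n_concordant == 2

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            sign_concordance_test(np.zeros(3), np.ones(3))


class TestRiskScores:
    def _weights(self, ids, bm, bg, bx):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "effect_allele": "G",
                "beta_marginal": bm,
                "beta_g": bg,
                "beta_gxe": bx,
            }
        )

    def test_zero_weights_zero_scores(self, rng):
        dos = rng.binomial(2, 0.3, size=(20, 3)).astype(float)
        g = toy_genotypes(dos)
        w = self._weights(["v0", "v1", "v2"], 0.0, 0.0, 0.0)
        s = build_risk_scores(g, w, np.ones(20))
        assert np.all(s["marginal_score"] == 0)
        assert np.all(s["interaction_score"] == 0)

    def test_no_interaction_reduces_to_main_effect(self, rng):
        dos = rng.binomial(2, 0.3, size=(10, 1)).astype(float)
        g = toy_genotypes(dos)
        w = self._weights(["v0"], 0.2, 0.3, 0.0)
        s = build_risk_scores(g, w, np.full(10, 50.0))
        np.testing.assert_allclose(s["interaction_score"], 0.3 * dos[:, 0])

    def test_hand_computed_fixture(self):
        dos = np.array([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        g = toy_genotypes(dos)
        w = self._weights(["v0", "v1", "v2"], [0.1, -0.2, 0.3],
                          [0.05, 0.1, -0.1], [0.01, 0.0, 0.002])
        e = np.array([2.0, 10.0])
        s = build_risk_scores(g, w, e)
        # by hand: marginal = dosage . beta_marginal
        np.testing.assert_allclose(s["marginal_score"], [0.4, 0.5])
        # interaction person 1: 0*0.05+1*0.1+2*(-0.1) + 2*(0*0.01+0+2*0.002)
        np.testing.assert_allclose(
            s["interaction_score"],
            [(-0.1) + 2 * 0.004, (0.1 - 0.1) + 10 * (0.02 + 0.002)],
        )

    def test_linear_in_weights(self, rng):
        dos = rng.binomial(2, 0.4, size=(30, 4)).astype(float)
        g = toy_genotypes(dos)
        e = rng.gamma(5, 20, 30)
        bm = rng.standard_normal(4)
        w1 = self._weights([f"v{j}" for j in range(4)], bm, bm, 0.1 * bm)
        w2 = self._weights([f"v{j}" for j in range(4)], 2 * bm, 2 * bm, 0.2 * bm)
        s1 = build_risk_scores(g, w1, e)
        s2 = build_risk_scores(g, w2, e)
        np.testing.assert_allclose(s2["marginal_score"], 2 * s1["marginal_score"])
        np.testing.assert_allclose(
            s2["interaction_score"], 2 * s1["interaction_score"]
        )

    def test_allele_mismatch_is_error(self, rng):
        dos = rng.binomial(2, 0.3, size=(10, 1)).astype(float)
        g = toy_genotypes(dos)
        w = self._weights(["v0"], 0.1, 0.1, 0.0)
        w["effect_allele"] = "T"
        with pytest.raises(ValueError, match="mismatch"):
            build_risk_scores(g, w, np.ones(10))


class TestEvaluateRiskScores:
    def test_true_score_positively_associated(self, rng):
        n = 5000
        g, cohort, truth = make_dataset(seed=51, n_samples=n, n_variants=60,
                                        n_causal_main=15, h2_target=0.3)
        w = pd.DataFrame(
            {
                "variant_id": truth["variant_id"],
                "effect_allele": "G",
                "beta_marginal": truth["beta_g"],
                "beta_g": truth["beta_g"],
                "beta_gxe": truth["beta_gxe"],
            }
        )
        scores = build_risk_scores(g, w, cohort["cwduvb"].to_numpy())
        out = evaluate_risk_scores(scores, cohort)
        marg = out.set_index("score").loc["marginal_score"]
        assert marg["slope_nmol_per_unit"] > 0
        assert marg["p"] < 0.05
        # decile contrast agrees in sign with the slope
        assert marg["top_vs_bottom_decile_nmol"] > 0

    def test_permuted_score_is_null(self, rng):
        n = 3000
        g, cohort, truth = make_dataset(seed=52, n_samples=n, n_variants=40,
                                        n_causal_main=10, h2_target=0.3)
        w = pd.DataFrame(
            {
                "variant_id": truth["variant_id"],
                "effect_allele": "G",
                "beta_marginal": truth["beta_g"],
                "beta_g": truth["beta_g"],
                "beta_gxe": truth["beta_gxe"],
            }
        )
        scores = build_risk_scores(g, w, cohort["cwduvb"].to_numpy())
        perm = rng.permutation(n)
        scores["marginal_score"] = scores["marginal_score"].to_numpy()[perm]
        scores["interaction_score"] = scores["interaction_score"].to_numpy()[perm]
        out = evaluate_risk_scores(scores, cohort)
        marg = out.set_index("score").loc["marginal_score"]
        assert abs(marg["slope_nmol_per_unit"]) < 2 * marg["se"]
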