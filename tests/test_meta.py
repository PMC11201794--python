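"""Meta-analysis engine: algebraic oracles, pooling invariants, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plasmameta import (
    GeneEffect,
    cochran_q,
    dl_pool,
    fisher_combine,
    forest_data,
    geometric_mean_score,
    hedges_g,
    one_sided_pvalues,
    run_meta,
    select_signature,
)
from plasmameta.meta import ZeroVarianceError, compute_effects
from plasmameta.preprocess import ExpressionMatrix
from tests.conftest import gene_level


def eff(g, var, gene="g", cohort="c", n=4):
    return GeneEffect(gene=gene, cohort=cohort, g=g, var_g=var, n_t=n, n_c=n)


class TestHedgesG:
    def test_hand_computed_chain(self):
        """treated=[2,2,3,3], control=[0,0,1,1]: d=3.4641, J=1-3/23,
        g=3.0123, var_g=1.0671 (frozen from hand computation of the
        formula chain d -> J -> g -> var)."""
        e = hedges_g([2, 2, 3, 3], [0, 0, 1, 1])
        assert e.g == pytest.approx(3.0123, abs=1e-4)
        assert e.var_g == pytest.approx(1.0671, abs=1e-4)

    def test_zero_effect(self):
        e = hedges_g([1, 2, 3], [2, 1, 3])
        assert e.g == 0.0
        assert e.var_g == pytest.approx(6 / 9)  # (n_t+n_c)/(n_t*n_c)

    def test_arm_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        t, c = rng.normal(1, 1, 5), rng.normal(0, 1, 6)
        a, b = hedges_g(t, c), hedges_g(c, t)
        assert a.g == pytest.approx(-b.g)
        assert a.var_g == pytest.approx(b.var_g)

    def test_zero_variance_flagged(self):
        with pytest.raises(ZeroVarianceError):
            hedges_g([1, 1, 1], [1, 1, 1])


class TestDlPool:
    def test_homogeneous_case(self):
        effects = [eff(0.8, 0.4, cohort=f"c{i}") for i in range(4)]
        es, se, tau2 = dl_pool(effects)
        assert es == pytest.approx(0.8)
        assert tau2 == 0.0
        assert se == pytest.approx(np.sqrt(0.4 / 4))

    def test_hand_computed_two_study(self):
        """g=[1,2], var=[0.5,0.5]: fixed mean 1.5, Q=1 <= k-1 so tau2=0,
        pooled 1.5, se=1/sqrt(4)=0.5."""
        es, se, tau2 = dl_pool([eff(1.0, 0.5, cohort="a"), eff(2.0, 0.5, cohort="b")])
        assert (es, tau2) == (pytest.approx(1.5), 0.0)
        assert se == pytest.approx(0.5)

    def test_huge_variance_study_ignored(self):
        es, _, _ = dl_pool([eff(1.0, 0.1, cohort="a"), eff(9.0, 1e6, cohort="b")])
        assert es == pytest.approx(1.0, abs=1e-3)

    def test_positive_tau2_hand_computed(self):
        """g=[0,3], var=[0.5,0.5]: w=[2,2], Q = 2*1.5^2*2 = 9,
        tau2 = (Q - 1)/(S1 - S2/S1) = 8/(4 - 8/4) = 4."""
        es, se, tau2 = dl_pool([eff(0.0, 0.5, cohort="a"), eff(3.0, 0.5, cohort="b")])
        assert tau2 == pytest.approx(4.0)
        assert es == pytest.approx(1.5)  # equal weights by symmetry

    def test_single_effect_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single-cohort"):
            es, se, tau2 = dl_pool([eff(1.2, 0.3)])
        assert (es, tau2) == (1.2, 0.0)

    def test_reduces_to_fixed_effects_when_homoscedastic_tau_zero(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0, 0.01, 5)
        v = rng.uniform(0.3, 0.8, 5)
        effects = [eff(gi, vi, cohort=f"c{i}") for i, (gi, vi) in enumerate(zip(g, v))]
        es, se, tau2 = dl_pool(effects)
        assert tau2 == 0.0
        w = 1 / v
        assert es == pytest.approx(np.sum(w * g) / np.sum(w), abs=1e-12)
        assert se == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_pooled_effect_within_range_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 8)
        g = rng.normal(0, 2, k)
        v = rng.uniform(0.05, 2.0, k)
        effects = [eff(gi, vi, cohort=f"c{i}") for i, (gi, vi) in enumerate(zip(g, v))]
        es, se, tau2 = dl_pool(effects)
        assert g.min() - 1e-12 <= es <= g.max() + 1e-12
        assert tau2 >= 0 and se > 0
        perm = [effects[i] for i in rng.permutation(k)]
        assert dl_pool(perm) == pytest.approx((es, se, tau2))


class TestCochranQ:
    def test_homogeneous_q_zero(self):
        q, p = cochran_q([eff(1.0, 0.5, cohort="a"), eff(1.0, 0.5, cohort="b")])
        assert (q, p) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_chi_squared_tail_oracle(self):
        q, p = cochran_q([eff(1.0, 0.5, cohort="a"), eff(2.0, 0.5, cohort="b")])
        assert q == pytest.approx(1.0)
        assert p == pytest.approx(stats.chi2.sf(1.0, 1), abs=1e-6)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_duplicate_at_fixed_mean_leaves_q(self):
        effects = [eff(1.0, 0.5, cohort="a"), eff(2.0, 0.5, cohort="b")]
        q0, _ = cochran_q(effects)
        q1, _ = cochran_q(effects + [eff(1.5, 0.5, cohort="c")])
        assert q1 == pytest.approx(q0)

    def test_needs_two_cohorts(self):
        with pytest.raises(ValueError, match="at least 2"):
            cochran_q([eff(1.0, 0.5)])


class TestDirectionalPvalues:
    def test_symmetry_at_zero(self):
        assert one_sided_pvalues(eff(0.0, 0.5)) == (0.5, 0.5)

    def test_normal_tail_oracle(self):
        p_up, p_down = one_sided_pvalues(eff(1.96, 1.0))
        assert p_up == pytest.approx(0.0250, abs=1e-4)
        assert p_up + p_down == 1.0

    def test_negation_swaps_directions(self):
        up1, down1 = one_sided_pvalues(eff(0.7, 0.3))
        up2, down2 = one_sided_pvalues(eff(-0.7, 0.3))
        assert up1 == pytest.approx(down2) and down1 == pytest.approx(up2)


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_chi_squared_oracle(self):
        x, p = fisher_combine([0.05, 0.05])
        assert x == pytest.approx(-4 * np.log(0.05), abs=1e-6)
        assert p == pytest.approx(0.0175, abs=1e-4)

    def test_monotone_in_inputs(self):
        _, p0 = fisher_combine([0.5, 0.2])
        _, p1 = fisher_combine([0.4, 0.2])
        assert p1 < p0

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            x, p = fisher_combine([0.0, 0.5])
        assert np.isfinite(x) and 0 <= p <= 1


class TestRunMeta:
    def test_scalar_and_vector_paths_agree(self, default_sim):
        """run_meta's vectorized internals equal the per-gene scalar API."""
        cohorts = gene_level(default_sim)
        meta = run_meta(cohorts, min_cohorts_measured=2).set_index("gene")
        rng = np.random.default_rng(0)
        for gene in rng.choice(meta.index, 10, replace=False):
            effects = [
                hedges_g(
                    c.arm_values("treated").loc[gene],
                    c.arm_values("control").loc[gene],
                    gene=gene, cohort=c.cohort_id,
                )
                for c in cohorts
            ]
            es, se, tau2 = dl_pool(effects)
            q, qp = cochran_q(effects)
            row = meta.loc[gene]
            assert row["es_pooled"] == pytest.approx(es, abs=1e-10)
            assert row["se_pooled"] == pytest.approx(se, abs=1e-10)
            assert row["tau2"] == pytest.approx(tau2, abs=1e-10)
            assert row["q_stat"] == pytest.approx(q, abs=1e-10)
            x_up, p_up = fisher_combine([one_sided_pvalues(e)[0] for e in effects])
            assert row["fisher_stat_up"] == pytest.approx(x_up, abs=1e-8)
            assert row["fisher_p_up"] == pytest.approx(p_up, abs=1e-10)

    def test_gene_missing_from_cohorts_filtered(self, default_sim):
        cohorts = gene_level(default_sim)
        trimmed = cohorts[0].matrix.data.drop(index=["G0001"])
        from plasmameta.preprocess import CohortDataset

        cohorts = [
            CohortDataset(ExpressionMatrix(trimmed), cohorts[0].groups, "c1"),
            *cohorts[1:],
        ]
        meta = run_meta(cohorts, min_cohorts_measured=5)
        assert "G0001" not in set(meta["gene"])
        assert (meta["k"] >= 5).all()

    def test_q_pvalues_uniform_under_null_large_arms(self):
        """At 10+10 per arm the chi-squared(k-1) reference for Q holds:
        KS distance to uniform < 0.05 over 2000 null genes."""
        from plasmameta import SyntheticConfig, generate_multicohort

        sim = generate_multicohort(
            SyntheticConfig(n_genes=2000, n_signature=0, probes_per_gene=1,
                            per_cohort_n=[(10, 10)] * 5, seed=3)
        )
        meta = run_meta(gene_level(sim), min_cohorts_measured=2)
        assert stats.kstest(meta["q_pvalue"], "uniform").statistic < 0.05

    def test_directional_consistency(self, default_sim):
        """When all per-cohort effects share one sign, both directional
        Fisher p-values cannot be tiny simultaneously."""
        meta = run_meta(gene_level(default_sim), min_cohorts_measured=2)
        both_small = (meta["fisher_p_up"] < 0.5 * 0.5**5) & (
            meta["fisher_p_down"] < 0.5 * 0.5**5
        )
        assert not both_small.any()


class TestSelectSignature:
    def row(self, **kw):
        base = dict(gene="g", k=5, es_pooled=1.5, se_pooled=0.3, tau2=0.0,
                    q_stat=1.0, q_pvalue=0.9, fisher_stat_up=30.0,
                    fisher_p_up=1e-4, fisher_fdr_up=1e-3, fisher_stat_down=0.1,
                    fisher_p_down=0.99, fisher_fdr_down=1.0)
        base.update(kw)
        return base

    def test_threshold_semantics(self):
        meta = pd.DataFrame([
            self.row(gene="sel"),
            self.row(gene="low_es", es_pooled=0.9, fisher_fdr_up=1e-6),
            self.row(gene="few_k", k=4),
            self.row(gene="high_fdr", fisher_fdr_up=0.2),
            self.row(gene="down_sel", es_pooled=-1.5, fisher_fdr_up=1.0,
                     fisher_fdr_down=1e-3),
        ])
        sig = select_signature(meta, es_min=1.0, fdr_max=0.05, min_cohorts=5)
        assert sig.directions == {"sel": "up", "down_sel": "down"}

    def test_fdr_boundary_inclusive(self):
        meta = pd.DataFrame([self.row(fisher_fdr_up=0.05)])
        assert len(select_signature(meta, min_cohorts=5)) == 1

    def test_planted_recovery(self, default_sim):
        meta = run_meta(gene_level(default_sim), min_cohorts_measured=2)
        sig = select_signature(meta, es_min=1.0, fdr_max=0.05, min_cohorts=5)
        planted = default_sim.truth.signature_genes
        recovered = set(sig.genes) & planted
        assert len(recovered) / len(planted) >= 0.9
        assert all(d == "up" for d in sig.directions.values())
        false = set(sig.genes) - planted
        assert len(false) <= max(2, 0.05 * len(sig.genes))


class TestGeometricMeanScore:
    def test_closed_form_two_genes(self):
        # linear values [1, 4] -> log2 [0, 2] -> score 1 = log2(geomean 2)
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0, 2.0]}, index=["a", "b"]))
        out = geometric_mean_score(m, ["a", "b"])
        assert out["score"].iloc[0] == pytest.approx(1.0)

    def test_singleton_signature(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [3.5], "s2": [4.5]}, index=["a"]))
        out = geometric_mean_score(m, ["a"])
        assert list(out["score"]) == [3.5, 4.5]

    def test_no_genes_present_errors(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["a"]))
        with pytest.raises(ValueError, match="no signature gene"):
            geometric_mean_score(m, ["zzz"])

    def test_treated_exceeds_control_on_planted_cohort(self, default_sim):
        cohort = gene_level(default_sim)[0]
        out = geometric_mean_score(
            cohort.matrix, sorted(default_sim.truth.signature_genes), cohort.groups
        )
        means = out.attrs["group_means"]
        assert means["treated"] > means["control"]


class TestForestData:
    def pooled_row(self, effects):
        es, se, tau2 = dl_pool(effects)
        return {"gene": "g", "es_pooled": es, "se_pooled": se, "tau2": tau2}

    def test_single_cohort_weight_one(self):
        effects = [eff(1.0, 0.5, cohort="a")]
        with pytest.warns(UserWarning):
            pooled = self.pooled_row(effects)
        out = forest_data("g", effects, pooled)
        assert out["weight"].iloc[0] == 1.0
        row, summary = out.iloc[0], out.iloc[-1]
        assert summary["g"] == pytest.approx(row["g"])
        assert summary["ci_low"] == pytest.approx(row["ci_low"])

    def test_homogeneous_equal_weights(self):
        effects = [eff(1.0, 0.4, cohort=f"c{i}") for i in range(4)]
        out = forest_data("g", effects, self.pooled_row(effects))
        assert np.allclose(out["weight"].iloc[:4], 0.25)

    def test_weights_match_brute_force(self):
        rng = np.random.default_rng(2)
        effects = [eff(g, v, cohort=f"c{i}") for i, (g, v) in
                   enumerate(zip(rng.normal(1, 1, 5), rng.uniform(0.2, 1.0, 5)))]
        pooled = self.pooled_row(effects)
        out = forest_data("g", effects, pooled)
        w = np.array([1 / (e.var_g + pooled["tau2"]) for e in effects])
        assert np.allclose(out["weight"].iloc[:5], w / w.sum(), atol=1e-10)
        assert out["weight"].iloc[:5].sum() == pytest.approx(1.0)

    def test_gene_mismatch_rejected(self):
        effects = [eff(1.0, 0.5, gene="g", cohort="a"), eff(1.0, 0.5, gene="g", cohort="b")]
        pooled = self.pooled_row(effects)
        with pytest.raises(ValueError, match="different gene"):
            forest_data("g", effects + [eff(1.0, 0.5, gene="other")], pooled)
        with pytest.raises(ValueError, match="not"):
            forest_data("other", [eff(1.0, 0.5, gene="other")], pooled)
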