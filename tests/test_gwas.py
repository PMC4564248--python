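"""VanRaden kinship, mixed-model association, multiple-testing thresholds
and the balanced-subset scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panelkit import gwas
from panelkit import qc
from panelkit import simulate as sm
from panelkit import structure as st
from panelkit import ld

from conftest import make_panel


class TestKinship:
    def test_three_sample_two_marker_hand_product(self):
        # genotypes (allele counts): s0=(0,2), s1=(1,1), s2=(2,0)
        calls = np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8)
        panel = make_panel(calls)
        # p = 0.5 for both markers; Z = G - 1; denom = 2 * (0.25 + 0.25) = 1
        z = calls.astype(float) - 1.0
        expected = z @ z.T
        got = gwas.vanraden_kinship(panel).to_numpy()
        assert np.allclose(got, expected, atol=1e-12)

    def test_identical_samples_share_diagonal_value(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, 500).astype(np.int8)
        other = rng.integers(0, 3, size=(30, 500)).astype(np.int8)
        calls = np.vstack([base, base, other])
        k = gwas.vanraden_kinship(make_panel(calls)).to_numpy()
        assert k[0, 1] == pytest.approx(k[0, 0], abs=1e-9)
        assert k[0, 1] == pytest.approx(k[1, 1], abs=1e-9)

    def test_unrelated_panel_mean_offdiagonal_near_zero(self):
        cfg = sm.SimConfig(
            seed=13, k_true=1, pop_sizes=(200,), n_admixed=0, f_div=(0.0,),
            selfing=(0.0,), n_markers=1000, rate_failed=0, rate_false=0,
            rate_duplicated=0, rate_null_allele=0, clone_group_sizes=(),
            sports=(), traits=(),
        )
        panel, _, _ = sm.simulate_panel(cfg)
        k = gwas.vanraden_kinship(panel).to_numpy()
        off = k[np.triu_indices(len(k), 1)]
        assert abs(off.mean()) < 0.02

    def test_kinship_symmetric_psd_and_marker_order_invariant(self, analysis):
        apanel, _, _ = analysis
        k = gwas.vanraden_kinship(apanel).to_numpy()
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-8
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(apanel.marker_ids))
        k2 = gwas.vanraden_kinship(apanel.subset(markers=perm)).to_numpy()
        assert np.allclose(k, k2, atol=1e-12)


class TestMlmScan:
    def _null_panel(self, seed=2, n=120, m=60):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, m)
        calls = ((rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p)).astype(np.int8)
        return make_panel(calls), rng

    def test_identity_kinship_reduces_to_ols(self):
        """With K = I and no structure, per-marker p-values match the
        ordinary least-squares F test."""
        panel, rng = self._null_panel()
        y = pd.Series(rng.integers(0, 2, panel.n_samples).astype(float), index=panel.sample_ids)
        kin = pd.DataFrame(np.eye(panel.n_samples), index=panel.sample_ids, columns=panel.sample_ids)
        res = gwas.mlm_scan(y, panel, kinship=kin, maf_min=0.0, min_success=0.0)
        g = st.additive_code(panel)
        yv = y.to_numpy()
        n = len(yv)
        for j in range(0, panel.n_markers, 7):
            x = np.column_stack([np.ones(n), g[:, j]])
            beta, res_ss, *_ = np.linalg.lstsq(x, yv, rcond=None)
            resid = yv - x @ beta
            rss = resid @ resid
            s2 = rss / (n - 2)
            xtx_inv = np.linalg.inv(x.T @ x)
            f = beta[1] ** 2 / (s2 * xtx_inv[1, 1])
            p_ols = sps.f.sf(f, 1, n - 2)
            assert res.table["p"].iloc[j] == pytest.approx(p_ols, abs=1e-8)

    def test_null_type_one_error_calibrated(self):
        panel, rng = self._null_panel(seed=3, n=150, m=1000)
        y = pd.Series(rng.integers(0, 2, panel.n_samples).astype(float), index=panel.sample_ids)
        res = gwas.mlm_scan(y, panel, maf_min=0.0, min_success=0.0)
        frac = (res.table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_recessive_marker_is_scan_minimum(self, analysis):
        apanel, phen, truth = analysis
        g = st.additive_code(apanel)
        hits = 0
        total = 0
        for trait in ("glabrous_fruit", "yellow_flesh"):
            y = phen.trait(trait)
            res = gwas.mlm_scan(y, apanel, q=truth.q.reindex(apanel.sample_ids))
            causal = truth.causal_markers[trait]
            top = res.table["p"].idxmin()
            total += 1
            if top == causal:
                hits += 1
            else:
                r2 = ld.r2_pair(
                    g[:, apanel.marker_index(causal)], g[:, apanel.marker_index(top)]
                )
                hits += r2 > 0.8
        assert hits == total

    def test_h2_in_unit_interval_and_zero_under_identity_kinship(self):
        panel, rng = self._null_panel(seed=4, n=100, m=300)
        y = pd.Series(rng.integers(0, 2, panel.n_samples).astype(float), index=panel.sample_ids)
        kin = pd.DataFrame(
            np.eye(panel.n_samples), index=panel.sample_ids, columns=panel.sample_ids
        )
        vals = []
        for s in range(5):
            yy = pd.Series(
                np.random.default_rng(s).integers(0, 2, panel.n_samples).astype(float),
                index=panel.sample_ids,
            )
            res = gwas.mlm_scan(yy, panel, kinship=kin, maf_min=0.0, min_success=0.0)
            assert 0.0 <= res.h2 <= 1.0
            vals.append(res.h2)
        assert np.median(vals) < 0.05

    def test_p_value_invariant_to_allele_swap(self):
        panel, rng = self._null_panel(seed=5, n=80, m=20)
        y = pd.Series(rng.integers(0, 2, panel.n_samples).astype(float), index=panel.sample_ids)
        res1 = gwas.mlm_scan(y, panel, maf_min=0.0, min_success=0.0)
        res2 = gwas.mlm_scan(y, panel.swap_alleles(["m3", "m7"]), maf_min=0.0, min_success=0.0)
        assert np.allclose(
            res1.table["p"].to_numpy(), res2.table["p"].to_numpy(), atol=1e-10, equal_nan=True
        )


class TestThresholds:
    def test_bonferroni_matches_panel_scale_value(self):
        # 4,271 tests at alpha 0.01 -> -log10 threshold 5.63 (2 dp)
        assert gwas.bonferroni_neglog10(4271, 0.01) == pytest.approx(5.63, abs=0.005)

    def test_single_test_cutoff_is_alpha(self):
        assert gwas.bonferroni_neglog10(1, 0.01) == pytest.approx(-np.log10(0.01))

    def test_by_rejections_match_bruteforce_stepup(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        alpha = 0.05
        m = 4
        c_m = sum(1.0 / i for i in range(1, m + 1))
        # brute force: largest i with p_(i) <= i*alpha/(m*c(m))
        order = np.argsort(p)
        k_star = 0
        for i in range(1, m + 1):
            if p[order[i - 1]] <= i * alpha / (m * c_m):
                k_star = i
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_star]] = True
        got = gwas.by_rejections(p, alpha)
        assert np.array_equal(got, expected)

    def test_by_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(0, 1e-4, 5), rng.uniform(0, 1, 200)])
        flags, *_ = multipletests(p, alpha=0.01, method="fdr_by")[:1]
        assert np.array_equal(gwas.by_rejections(p, 0.01), flags)

    def test_flag_sets_monotone_in_alpha(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 100) ** 3
        small = gwas.by_rejections(p, 0.01)
        large = gwas.by_rejections(p, 0.1)
        assert (large | small == large).all()


class TestBalancedSubsetScan:
    def test_null_trait_has_no_consensus(self, analysis):
        apanel, _, _ = analysis
        rng = np.random.default_rng(8)
        y = pd.Series(
            (rng.random(apanel.n_samples) < 0.25).astype(float), index=apanel.sample_ids
        )
        res = gwas.balanced_subset_scan(y, apanel, n_subsets=5, n_controls=60, seed=9)
        assert res.consensus == []

    def test_planted_obligate_het_marker_in_consensus(self, analysis):
        apanel, phen, truth = analysis
        y = phen.trait("flat_fruit")
        res = gwas.balanced_subset_scan(y, apanel, n_subsets=5, n_controls=60, seed=10)
        assert truth.causal_markers["flat_fruit"] in res.consensus

    def test_single_subset_reduces_to_one_scan(self, analysis):
        apanel, phen, _ = analysis
        y = phen.trait("flat_fruit")
        res = gwas.balanced_subset_scan(y, apanel, n_subsets=1, n_controls=60, seed=11)
        assert len(res.results) == 1
        single = res.results[0]
        sig = (single.table["neglog10p"] > single.bonferroni_neglog10).fillna(False)
        assert set(res.consensus) == set(sig.index[sig])
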