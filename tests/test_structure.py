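"""Diversity, IBS-UPGMA, PCA, VIF pruning, admixture Gibbs, Evanno ΔK,
population assignment and Weir-Cockerham Fst."""

import numpy as np
import pandas as pd
import pytest

from panelkit import structure as st
from panelkit import simulate as sm
from panelkit.calls import HET, HOM_A, HOM_B, NO_CALL

from conftest import make_panel


class TestDiversity:
    def test_printed_panel_means_give_f_027(self):
        # mean Ho 0.286 and He 0.39 imply F = (He-Ho)/He = 0.27 (2 dp)
        assert st.fixation_index(0.286, 0.39) == pytest.approx(0.27, abs=0.005)

    def test_f_zero_when_ho_equals_he(self):
        assert st.fixation_index(0.4, 0.4) == 0.0

    def test_no_heterozygotes_gives_f_one(self):
        col = [HOM_A] * 50 + [HOM_B] * 50
        d = st.diversity_summary(make_panel(np.array(col)[:, None]))
        assert d.per_marker["ho"].iloc[0] == 0.0
        assert d.per_marker["he"].iloc[0] == pytest.approx(0.5)
        assert d.per_marker["f"].iloc[0] == pytest.approx(1.0)


class TestIBSUpgma:
    def test_allele_draw_enumeration(self):
        # [AA,AB] vs [AA,BB]: per-locus match prob (1 + 0.5)/2 = 0.75
        panel = make_panel([[HOM_A, HET], [HOM_A, HOM_B]])
        sim = st.ibs_matrix(panel)
        assert sim[0, 1] == pytest.approx(0.75)

    def test_het_vs_het_is_half(self):
        panel = make_panel([[HET], [HET]])
        assert st.ibs_matrix(panel)[0, 1] == pytest.approx(0.5)

    def test_self_distance_zero(self, study):
        panel, _, _, _ = study
        dist, _ = st.ibs_upgma(panel.subset(samples=panel.sample_ids[:4]))
        assert np.allclose(np.diag(dist), 0.0)

    def test_toy_upgma_merge_heights(self):
        dist = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = st.upgma_tree(dist, ["A", "B", "C"])
        # A,B join at height 0.1; C joins at 0.3
        assert tree.height == pytest.approx(0.3)
        inner = [c for c in tree.children if c.children is not None][0]
        assert inner.height == pytest.approx(0.1)
        assert sorted(inner.leaf_names()) == ["A", "B"]

    def test_tree_is_ultrametric(self, study):
        panel, _, _, _ = study
        sub = panel.subset(samples=panel.sample_ids[:25])
        _, tree = st.ibs_upgma(sub)

        def depths(node, acc):
            if node.children is None:
                yield acc
            else:
                for c in node.children:
                    yield from depths(c, acc + (node.height - c.height))

        d = list(depths(tree, 0.0))
        assert max(d) - min(d) < 1e-9


class TestPCA:
    def test_heterozygote_high_coding(self):
        # calls AA,AA,AB,BB with A major -> codes 1,1,2,0
        panel = make_panel(np.array([[HOM_A], [HOM_A], [HET], [HOM_B]]))
        codes = st.heterozygote_high_code(panel)[:, 0]
        assert list(codes) == [1.0, 1.0, 2.0, 0.0]

    def test_monomorphic_marker_contributes_nothing(self):
        calls = np.column_stack(
            [np.full(10, HOM_A), np.array([HOM_A] * 5 + [HOM_B] * 5)]
        ).astype(np.int8)
        res = st.pca_numeric(make_panel(calls), n_components=2)
        assert res.explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_pc1_separates_two_planted_populations(self):
        cfg = sm.SimConfig(
            seed=8, k_true=2, pop_sizes=(100, 100), n_admixed=0,
            f_div=(0.2, 0.2), selfing=(0.0, 0.0), n_markers=500,
            rate_failed=0, rate_false=0, rate_duplicated=0, rate_null_allele=0,
            clone_group_sizes=(), sports=(), traits=(),
        )
        panel, _, truth = sm.simulate_panel(cfg)
        res = st.pca_numeric(panel, n_components=2)
        label = (truth.pop_labels == "POP1").astype(float)
        r = np.corrcoef(res.scores["PC1"], label)[0, 1]
        assert abs(r) > 0.9


class TestVifPrune:
    def test_uncorrelated_markers_untouched(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        panel = make_panel(calls)
        assert st.vif_prune(panel) == panel.marker_ids

    def test_duplicated_marker_removed(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=200).astype(np.int8)
        other = rng.integers(0, 3, size=(200, 3)).astype(np.int8)
        calls = np.column_stack([col, other, col])
        panel = make_panel(calls)
        kept = st.vif_prune(panel)
        assert len(kept) == 4
        assert ("m0" in kept) != ("m4" in kept)

    def test_window_matches_bruteforce_iterative_oracle(self):
        rng = np.random.default_rng(2)
        n = 300
        base = rng.normal(size=n)
        x = np.column_stack(
            [
                base + 0.3 * rng.normal(size=n),
                base + 0.3 * rng.normal(size=n),
                rng.normal(size=n),
                base + 0.5 * rng.normal(size=n),
                rng.normal(size=n),
            ]
        )
        calls = np.clip(np.round(1 + x / 2), 0, 2).astype(np.int8)
        panel = make_panel(calls)
        kept = st.vif_prune(panel, window=5, step=5, vif_max=2.0)

        # brute-force: iteratively drop the worst-VIF column via regression
        g = calls.astype(float)
        keep = list(range(5))
        while len(keep) >= 2:
            vifs = []
            for j in keep:
                others = [o for o in keep if o != j]
                a = np.column_stack([np.ones(n), g[:, others]])
                beta, *_ = np.linalg.lstsq(a, g[:, j], rcond=None)
                resid = g[:, j] - a @ beta
                sst = ((g[:, j] - g[:, j].mean()) ** 2).sum()
                r2 = 1 - resid @ resid / sst
                vifs.append(1 / (1 - r2) if r2 < 1 else np.inf)
            worst = int(np.argmax(vifs))
            if vifs[worst] <= 2.0:
                break
            keep.pop(worst)
        assert kept == [f"m{j}" for j in keep]


class TestAdmixtureGibbs:
    def test_k1_is_degenerate_binomial_model(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(60, 120)).astype(np.int8)
        panel = make_panel(calls)
        run = st.admixture_gibbs(panel, 1, burnin=100, iters=300, seed=4)
        assert np.allclose(run.q.to_numpy(), 1.0)
        # trace hovers below the binomial log-likelihood at empirical freqs
        g = calls.astype(float)
        p_hat = np.clip(g.mean(axis=0) / 2, 1e-9, 1 - 1e-9)
        n_b = g.sum(axis=0)
        n_tot = 2.0 * len(calls)
        ll_hat = float(np.sum(n_b * np.log(p_hat) + (n_tot - n_b) * np.log(1 - p_hat)))
        gap = ll_hat - run.mean_loglik
        assert 0 <= gap < 2.0 * panel.n_markers

    def test_two_separated_pops_assigned_at_q08(self):
        cfg = sm.SimConfig(
            seed=9, k_true=2, pop_sizes=(80, 80), n_admixed=0,
            f_div=(0.25, 0.25), selfing=(0.1, 0.1), n_markers=400,
            rate_failed=0, rate_false=0, rate_duplicated=0, rate_null_allele=0,
            clone_group_sizes=(), sports=(), traits=(),
        )
        panel, _, truth = sm.simulate_panel(cfg)
        run = st.admixture_gibbs(panel, 2, burnin=150, iters=500, seed=5)
        labels = st.assign_populations(run.q)
        ct = pd.crosstab(truth.pop_labels, labels)
        correct = ct.max(axis=1).sum()
        assert correct / panel.n_samples >= 0.95

    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(40, 60)).astype(np.int8)
        panel = make_panel(calls)
        a = st.admixture_gibbs(panel, 2, burnin=50, iters=100, seed=11)
        b = st.admixture_gibbs(panel, 2, burnin=50, iters=100, seed=11)
        assert np.array_equal(a.loglik_trace, b.loglik_trace)
        assert a.q.equals(b.q)

    def test_duplicate_sample_gets_same_admixture(self):
        cfg = sm.SimConfig(
            seed=10, k_true=2, pop_sizes=(60, 60), n_admixed=30,
            f_div=(0.2, 0.2), selfing=(0.0, 0.0), n_markers=300,
            rate_failed=0, rate_false=0, rate_duplicated=0, rate_null_allele=0,
            clone_group_sizes=(), sports=(), traits=(),
        )
        panel, _, _ = sm.simulate_panel(cfg)
        from panelkit.calls import GenotypeMatrix

        dup = GenotypeMatrix(
            panel.sample_ids + ["dup"],
            panel.marker_ids,
            np.vstack([panel.calls, panel.calls[-1][None, :]]),
        )
        run = st.admixture_gibbs(dup, 2, burnin=150, iters=400, seed=12)
        q = run.q.to_numpy()
        assert np.abs(q[-1] - q[-2]).max() < 0.05


class TestEvanno:
    def _runs_from_table(self, table, sds):
        runs = []
        for k, (l, sd) in enumerate(zip(table, sds), start=1):
            for rep, offset in enumerate((-sd / np.sqrt(2), sd / np.sqrt(2))):
                trace = np.full(10, l + offset)
                runs.append(
                    st.StructureRun(k, rep, 0, 10, trace, pd.DataFrame(np.ones((1, k))), np.ones((k, 1)))
                )
        return runs

    def test_linear_likelihood_gives_zero_delta_k(self):
        runs = self._runs_from_table([-1000, -900, -800, -700], [5, 5, 5, 5])
        table = st.evanno_delta_k(runs)
        assert np.allclose(table["delta_k"].dropna(), 0.0)

    def test_hand_arithmetic_toy_table(self):
        # L = -1000, -800, -790, -788 with sd 5:
        # dK(2) = |(-790) - 2(-800) + (-1000)|/5 = 38; dK(3) = 1.6
        runs = self._runs_from_table([-1000, -800, -790, -788], [5, 5, 5, 5])
        table = st.evanno_delta_k(runs)
        assert table.loc[2, "delta_k"] == pytest.approx(38.0, rel=1e-6)
        assert table.loc[3, "delta_k"] == pytest.approx(1.6, rel=1e-6)
        assert st.select_k(table) == 2


class TestAssign:
    def test_threshold_rules(self):
        q = pd.DataFrame(
            [[0.85, 0.15], [0.5, 0.5], [0.8, 0.2]], index=["a", "b", "c"], columns=["Q1", "Q2"]
        )
        labels = st.assign_populations(q, 0.8)
        # strictly-greater rule: exactly 0.8 is admixed
        assert list(labels) == ["Q1", "ADM", "ADM"]


def wc_single_locus_oracle(counts1, counts2):
    """Weir-Cockerham theta for one biallelic locus and two populations,
    from the published component formulas evaluated directly."""
    r = 2
    ns, ps, hs = [], [], []
    for aa, ab, bb in (counts1, counts2):
        n = aa + ab + bb
        ns.append(n)
        ps.append((ab + 2 * bb) / (2 * n))
        hs.append(ab / n)
    ns, ps, hs = map(np.array, (ns, ps, hs))
    n_bar = ns.mean()
    nc = (r * n_bar - (ns**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (ns * ps).sum() / (r * n_bar)
    s2 = (ns * (ps - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (ns * hs).sum() / (r * n_bar)
    a = (n_bar / nc) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a / (a + b + c)


class TestFst:
    def test_single_locus_matches_closed_form(self):
        # p = 0.2 vs 0.8, 50 diploids each, HWE-ish genotype counts
        c1, c2 = (32, 16, 2), (2, 16, 32)
        pop1 = np.array([HOM_A] * 32 + [HET] * 16 + [HOM_B] * 2, dtype=np.int8)[:, None]
        pop2 = np.array([HOM_A] * 2 + [HET] * 16 + [HOM_B] * 32, dtype=np.int8)[:, None]
        theta = st.fst_weir_cockerham([pop1, pop2])
        assert theta == pytest.approx(wc_single_locus_oracle(c1, c2), rel=1e-12)

    def test_identical_frequencies_give_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=1000)
        def draw(n):
            return (rng.random((n, 1000)) < p).astype(np.int8) + (
                rng.random((n, 1000)) < p
            ).astype(np.int8)
        theta = st.fst_weir_cockerham([draw(100), draw(100)])
        assert abs(theta) < 0.01

    def test_matrix_symmetric_zero_diagonal(self, study):
        panel, _, _, truth = study
        fst = st.pairwise_fst(panel, truth.pop_labels)
        assert np.allclose(fst.values, fst.values.T)
        assert np.allclose(np.diag(fst.values), 0.0)
        assert (fst.values[np.triu_indices(len(fst), 1)] > 0.05).all()
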