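"""Diversity summaries, IBS-UPGMA trees, PCA, LD pruning, admixture-model
clustering with Evanno ΔK model selection, and Weir–Cockerham Fst.

The clustering is a Gibbs sampler for the classical admixture model: each
of the two allele copies an individual carries at a marker originates from
one of K ancestral clusters; clusters have independent Beta(1,1) allele
frequencies and individuals have Dirichlet-distributed admixture vectors q
summing to 1.  This is a deliberately simplified sampler (independent
cluster frequencies, no linkage model) that recovers cluster structure and
admixture proportions on panel-scale data; it is not a reimplementation of
any particular published software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .calls import HET, HOM_A, HOM_B, NO_CALL, GenotypeMatrix, PanelError

# ---------------------------------------------------------------------------
# numeric genotype coders
# ---------------------------------------------------------------------------


def additive_code(panel: GenotypeMatrix) -> np.ndarray:
    """Minor-allele count coding 0/1/2 (float, NaN for no-call).

    The minor allele is determined per marker from called genotypes; at
    MAF exactly 0.5 the array B allele counts.  This is the conventional
    coding for LD, kinship and association statistics.
    """
    g = panel.calls.astype(float)
    g[g == NO_CALL] = np.nan
    with np.errstate(invalid="ignore"):
        p_b = np.nanmean(g, axis=0) / 2.0
    flip = p_b > 0.5
    g[:, flip] = 2.0 - g[:, flip]
    return g


def heterozygote_high_code(panel: GenotypeMatrix) -> np.ndarray:
    """Ordinal coding used for PCA: heterozygote = 2, most frequent
    homozygote = 1, least frequent homozygote = 0 (NaN for no-call)."""
    calls = panel.calls
    out = np.full(calls.shape, np.nan)
    n_aa = (calls == HOM_A).sum(axis=0)
    n_bb = (calls == HOM_B).sum(axis=0)
    major_hom = np.where(n_aa >= n_bb, HOM_A, HOM_B)
    minor_hom = np.where(n_aa >= n_bb, HOM_B, HOM_A)
    out[calls == HET] = 2.0
    out[calls == major_hom[None, :]] = 1.0
    out[calls == minor_hom[None, :]] = 0.0
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    per_sample_ho: pd.Series
    per_marker: pd.DataFrame  # ho, he, f
    mean_ho: float
    mean_he: float
    mean_f: float


def fixation_index(ho: float, he: float) -> float:
    """Fixation index F = (He − Ho) / He; positive under heterozygote
    deficit (inbreeding/selfing), 0 at Hardy–Weinberg proportions."""
    if he == 0:
        return float("nan")
    return (he - ho) / he


def diversity_summary(panel: GenotypeMatrix) -> DiversitySummary:
    calls = panel.calls
    called = calls != NO_CALL
    per_sample_ho = pd.Series(
        (calls == HET).sum(axis=1) / called.sum(axis=1), index=panel.sample_ids
    )
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = (calls == HET).sum(axis=0) / n_called
        p_b = ((calls == HET).sum(axis=0) + 2 * (calls == HOM_B).sum(axis=0)) / (2 * n_called)
    he = 2 * p_b * (1 - p_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(he > 0, (he - ho) / he, np.nan)
    per_marker = pd.DataFrame({"ho": ho, "he": he, "f": f}, index=panel.marker_ids)
    return DiversitySummary(
        per_sample_ho=per_sample_ho,
        per_marker=per_marker,
        mean_ho=float(np.nanmean(ho)),
        mean_he=float(np.nanmean(he)),
        mean_f=float(np.nanmean(f)),
    )


# ---------------------------------------------------------------------------
# IBS distance and UPGMA
# ---------------------------------------------------------------------------


def ibs_matrix(panel: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state similarity per pair: the probability that alleles
    drawn at random, one from each individual, are identical, averaged
    over co-called markers.  Same homozygote 1, hom vs het 0.5, het vs
    het 0.5, opposite homozygotes 0.  Self-similarity is set to 1
    (self-distance 0 by convention)."""
    calls = panel.calls
    called = calls != NO_CALL
    n = panel.n_samples
    sim = np.eye(n)
    for i in range(n):
        both = called[i] & called[i + 1 :]
        gi = calls[i]
        gj = calls[i + 1 :]
        s = 1.0 - np.abs(gi - gj) / 2.0
        s = np.where((gi == HET) & (gj == HET), 0.5, s)
        n_both = both.sum(axis=1)
        if (n_both == 0).any():
            j = int(np.nonzero(n_both == 0)[0][0]) + i + 1
            raise PanelError(
                f"samples {panel.sample_ids[i]!r} and {panel.sample_ids[j]!r} share no called markers"
            )
        vals = (s * both).sum(axis=1) / n_both
        sim[i, i + 1 :] = vals
        sim[i + 1 :, i] = vals
    return sim


@dataclass
class TreeNode:
    height: float
    name: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    def newick(self) -> str:
        return self._nwk(parent_height=self.height) + ";"

    def _nwk(self, parent_height: float) -> str:
        bl = parent_height - self.height
        if self.children is None:
            return f"{self.name}:{bl:.10g}"
        inner = ",".join(c._nwk(self.height) for c in self.children)
        return f"({inner}):{bl:.10g}"

    def leaf_names(self) -> list[str]:
        if self.children is None:
            return [self.name]  # type: ignore[list-item]
        return [n for c in self.children for n in c.leaf_names()]


def upgma_tree(dist: np.ndarray, ids: list[str]) -> TreeNode:
    """Average-linkage (UPGMA) tree from a symmetric distance matrix.

    Node heights are half the merge distance, so the tree is ultrametric;
    ties are resolved deterministically for a fixed input order.
    """
    if len(ids) < 3:
        raise PanelError("UPGMA needs at least 3 samples")
    z = average(squareform(dist, checks=False))
    nodes: dict[int, TreeNode] = {i: TreeNode(0.0, name=ids[i]) for i in range(len(ids))}
    for k, (a, b, d, _) in enumerate(z):
        nodes[len(ids) + k] = TreeNode(d / 2.0, children=(nodes[int(a)], nodes[int(b)]))
    return nodes[len(ids) + len(z) - 1]


def ibs_upgma(panel: GenotypeMatrix) -> tuple[np.ndarray, TreeNode]:
    """1 − IBS distance matrix and its UPGMA tree."""
    sim = ibs_matrix(panel)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return dist, upgma_tree(dist, panel.sample_ids)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame
    explained: np.ndarray  # variance fractions


def pca_numeric(panel: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA on heterozygote-high coded genotypes (het=2 / major hom=1 /
    minor hom=0), missing imputed to the marker mean, columns centered,
    no scaling; components by SVD."""
    if panel.n_samples < 2:
        raise PanelError("PCA needs at least 2 samples")
    x = heterozygote_high_code(panel)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    var = s**2
    explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    cols = [f"PC{i+1}" for i in range(k)]
    return PCAResult(pd.DataFrame(scores, index=panel.sample_ids, columns=cols), explained)


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------


def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column regressed on the others (multiple R^2)."""
    m = x.shape[1]
    vifs = np.empty(m)
    for j in range(m):
        y = x[:, j]
        others = np.delete(x, j, axis=1)
        if others.shape[1] == 0 or np.allclose(y.var(), 0):
            vifs[j] = 1.0
            continue
        a = np.column_stack([np.ones(len(y)), others])
        beta, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    panel: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 10.0,
) -> list[str]:
    """Sliding-window variance-inflation-factor pruning of markers.

    Within each window of ``window`` markers (advancing by ``step``), the
    marker with the largest VIF (on additive 0/1/2 coding, mean-imputed) is
    removed iteratively until all remaining VIFs are <= ``vif_max``.
    Removed markers stay removed.  Returns the retained marker ids in
    input order.
    """
    g = additive_code(panel)
    col_mean = np.nanmean(g, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]

    m = panel.n_markers
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        in_win = np.nonzero(keep[start : start + window])[0] + start
        if len(in_win) >= 2:
            while True:
                vifs = _window_vifs(g[:, in_win])
                worst = int(np.argmax(vifs))
                if vifs[worst] <= vif_max:
                    break
                keep[in_win[worst]] = False
                in_win = np.delete(in_win, worst)
                if len(in_win) < 2:
                    break
        if start + window >= m:
            break
        start += step
    return [mid for mid, k in zip(panel.marker_ids, keep) if k]


# ---------------------------------------------------------------------------
# admixture-model Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class StructureRun:
    k: int
    seed: int
    burnin: int
    iters: int
    loglik_trace: np.ndarray  # length burnin + iters
    q: pd.DataFrame  # posterior-mean admixture, samples x K
    freqs: np.ndarray  # posterior-mean cluster B-allele frequencies, K x markers

    @property
    def mean_loglik(self) -> float:
        """Mean post-burn-in data log-likelihood (used for Evanno ΔK)."""
        return float(self.loglik_trace[self.burnin :].mean())


try:  # optional acceleration of the Gibbs inner loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _gibbs_sweep(alleles, mask, u, q, p, b_counts, tot_counts, memb):  # pragma: no cover - jit
    n, m, _ = alleles.shape
    kk = q.shape[1]
    w = np.empty(kk)
    for i in range(n):
        for j in range(m):
            for c in range(2):
                if not mask[i, j, c]:
                    continue
                a = alleles[i, j, c]
                s = 0.0
                for t in range(kk):
                    like = p[t, j] if a == 1 else 1.0 - p[t, j]
                    w[t] = q[i, t] * like
                    s += w[t]
                r = u[i, j, c] * s
                acc = 0.0
                z = kk - 1
                for t in range(kk):
                    acc += w[t]
                    if r <= acc:
                        z = t
                        break
                if a == 1:
                    b_counts[z, j] += 1.0
                tot_counts[z, j] += 1.0
                memb[i, z] += 1.0


def _alleles_from_calls(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand genotypes to two allele copies in {0,1}; mask marks observed."""
    n, m = calls.shape
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    alleles[:, :, 0] = (calls == HOM_B).astype(np.int8)
    alleles[:, :, 1] = ((calls == HOM_B) | (calls == HET)).astype(np.int8)
    mask = np.repeat((calls != NO_CALL)[:, :, None], 2, axis=2)
    return alleles, mask


def admixture_gibbs(
    panel: GenotypeMatrix,
    k: int,
    burnin: int = 500,
    iters: int = 2000,
    seed: int = 0,
    alpha: float = 1.0,
) -> StructureRun:
    """Gibbs sampler for the admixture model with K clusters.

    Alternates (a) per-allele-copy ancestry assignments given admixture
    vectors and cluster frequencies, (b) cluster allele frequencies from
    their Beta(1,1) conditional, and (c) per-individual admixture vectors
    from their Dirichlet(alpha) conditional.  Label switching across the
    chain is resolved by greedily matching cluster frequency vectors to
    those of the first post-burn-in iteration (Hungarian assignment).
    Returns posterior means and the data log-likelihood trace.
    """
    if k < 1:
        raise PanelError("K must be >= 1")
    if k > panel.n_samples:
        raise PanelError("K larger than the number of samples")
    rng = np.random.default_rng(seed)
    alleles, mask = _alleles_from_calls(panel.calls)
    n, m, _ = alleles.shape
    is_b = alleles.astype(bool)

    p = rng.uniform(0.2, 0.8, size=(k, m))
    q = rng.dirichlet(np.full(k, alpha), size=n)

    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, m))
    trace = np.empty(burnin + iters)
    ref_p: np.ndarray | None = None
    n_keep = 0

    for it in range(burnin + iters):
        # per-allele-copy ancestry: P(z=j | allele) ∝ q_ij p_jm^a (1-p_jm)^(1-a)
        u = rng.random((n, m, 2))
        b_counts = np.zeros((k, m))
        tot_counts = np.zeros((k, m))
        memb = np.zeros((n, k))
        _gibbs_sweep(alleles, mask, u, q, p, b_counts, tot_counts, memb)

        # cluster frequencies and admixture vectors from their conditionals
        p = rng.beta(1.0 + b_counts, 1.0 + tot_counts - b_counts)
        gamma = rng.gamma(alpha + memb)
        q = gamma / gamma.sum(axis=1, keepdims=True)

        # observed-data log-likelihood at current (q, p)
        pa = q @ p  # n x m prob a random copy is allele B
        pa = np.clip(pa, 1e-12, 1 - 1e-12)
        ll_alleles = np.where(is_b, np.log(pa)[:, :, None], np.log(1 - pa)[:, :, None])
        trace[it] = float(ll_alleles[mask].sum())

        if it >= burnin:
            if ref_p is None:
                ref_p = p.copy()
                perm = np.arange(k)
            else:
                cost = np.abs(p[:, None, :] - ref_p[None, :, :]).sum(axis=2)
                row, col = linear_sum_assignment(cost)
                perm = np.empty(k, dtype=int)
                perm[col] = row
            q_sum += q[:, perm]
            p_sum += p[perm]
            n_keep += 1

    q_mean = q_sum / n_keep
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    qdf = pd.DataFrame(q_mean, index=panel.sample_ids, columns=[f"Q{j+1}" for j in range(k)])
    return StructureRun(k, seed, burnin, iters, trace, qdf, p_sum / n_keep)


def evanno_delta_k(runs: list[StructureRun]) -> pd.DataFrame:
    """Evanno ΔK table from replicate runs over a range of K.

    L(K) is the mean over replicates of the mean post-burn-in data
    log-likelihood; ΔK = |L(K+1) − 2 L(K) + L(K−1)| / sd(L(K)) with the sd
    taken over replicates.  ΔK is defined only at interior K with nonzero
    replicate spread; the selected K is the argmax of ΔK.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.mean_loglik)
    ks = sorted(by_k)
    if len(ks) < 3 or any(len(v) < 2 for v in by_k.values()):
        raise PanelError("Evanno ΔK needs >=3 consecutive K with >=2 replicates each")
    rows = []
    for i, k in enumerate(ks):
        vals = np.array(by_k[k])
        lk = vals.mean()
        sd = vals.std(ddof=1)
        dk = np.nan
        if 0 < i < len(ks) - 1 and sd > 0:
            l_lo = np.mean(by_k[ks[i - 1]])
            l_hi = np.mean(by_k[ks[i + 1]])
            dk = abs(l_hi - 2 * lk + l_lo) / sd
        rows.append({"K": k, "L": lk, "sd": sd, "delta_k": dk})
    return pd.DataFrame(rows).set_index("K")


def select_k(delta_table: pd.DataFrame) -> int:
    dk = delta_table["delta_k"].dropna()
    if dk.empty:
        raise PanelError("ΔK undefined at every interior K")
    return int(dk.idxmax())


def assign_populations(q: pd.DataFrame, q_min: float = 0.8) -> pd.Series:
    """Label each sample with its cluster if max q strictly exceeds
    ``q_min``, else 'ADM' (admixed)."""
    arr = q.to_numpy()
    best = arr.argmax(axis=1)
    labels = [
        q.columns[b] if arr[i, b] > q_min else "ADM" for i, b in enumerate(best)
    ]
    return pd.Series(labels, index=q.index, name="population")


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------


def _wc_components(
    calls_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components a, b, c per marker for r
    populations of biallelic genotypes (NO_CALL allowed)."""
    r = len(calls_by_pop)
    m = calls_by_pop[0].shape[1]
    ns = np.zeros((r, m))
    ps = np.zeros((r, m))
    hs = np.zeros((r, m))
    for i, calls in enumerate(calls_by_pop):
        called = calls != NO_CALL
        ns[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps[i] = ((calls == HET).sum(axis=0) + 2 * (calls == HOM_B).sum(axis=0)) / (
                2 * np.maximum(ns[i], 1)
            )
            hs[i] = (calls == HET).sum(axis=0) / np.maximum(ns[i], 1)
    n_bar = ns.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * n_bar - (ns**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (ns * ps).sum(axis=0) / (r * n_bar)
        s2 = (ns * (ps - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (ns * hs).sum(axis=0) / (r * n_bar)
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
    return a, b, c


def fst_weir_cockerham(calls_by_pop: list[np.ndarray]) -> float:
    """Multi-locus Weir–Cockerham θ: ratio of summed variance components
    across markers (sum of a over sum of a+b+c), monomorphic/unusable
    markers contributing zero to both sums."""
    a, b, c = _wc_components(calls_by_pop)
    denom = a + b + c
    ok = np.isfinite(a) & np.isfinite(denom) & (denom != 0)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def pairwise_fst(panel: GenotypeMatrix, labels: pd.Series) -> pd.DataFrame:
    """Pairwise multi-locus Weir–Cockerham Fst between labeled clusters;
    samples labeled 'ADM' are excluded.  Symmetric with zero diagonal."""
    labels = labels.reindex(panel.sample_ids)
    pops = sorted(set(labels.dropna()) - {"ADM"})
    if len(pops) < 2:
        raise PanelError("need at least two non-admixed clusters for Fst")
    idx_by_pop = {
        p: [panel.sample_index(s) for s in labels.index[labels == p]] for p in pops
    }
    for p, idx in idx_by_pop.items():
        if len(idx) < 2:
            raise PanelError(f"cluster {p!r} has fewer than 2 samples")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            theta = fst_weir_cockerham(
                [panel.calls[idx_by_pop[pa]], panel.calls[idx_by_pop[pb]]]
            )
            out.loc[pa, pb] = out.loc[pb, pa] = theta
    return out
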