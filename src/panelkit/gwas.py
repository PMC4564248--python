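"""Mixed-linear-model genome-wide association for binary Mendelian traits.

The scan uses the Q+K model: admixture proportions enter as fixed
covariates and a VanRaden genomic relationship matrix supplies the
random-effect covariance,

    y = X beta + g delta + u + e,   u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I).

Variance components are estimated once by REML on the null model (the
"P3D" convention) through the spectral decomposition of K, then every
marker is tested by a generalized-least-squares F test with those
components fixed.  Binary traits are analyzed on the linear scale, the
usual practice for Mendelian traits in plant GWAS.

For severely unbalanced traits (for example a rare dominant allele in
obligate heterozygosity) a balanced-subset resampling scan is provided:
all minority-class samples plus a fresh random draw of controls per
subset, with markers scored by the number of subsets in which they pass
the Bonferroni threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .calls import GenotypeMatrix, PanelError
from .structure import additive_code

# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def vanraden_kinship(panel: GenotypeMatrix, maf_min: float = 0.05) -> pd.DataFrame:
    """VanRaden genomic relationship matrix G = Z Zᵀ / (2 Σ p(1−p)).

    Z is the allele-count matrix column-centered by 2p (missing calls
    imputed to 2p).  On this scale unrelated pairs are near 0 and a pair
    of identical fully inbred genotypes approaches 2 ("scaled at 2").
    """
    g = additive_code(panel)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    keep = np.minimum(p, 1 - p) >= maf_min
    if keep.sum() == 0:
        raise PanelError("no polymorphic markers above the MAF floor for kinship")
    g = g[:, keep]
    p = p[keep]
    denom = 2.0 * float((p * (1 - p)).sum())
    if denom <= 0:
        raise PanelError("all selected markers are monomorphic")
    z = np.where(np.isnan(g), 0.0, g - 2 * p)
    k = z @ z.T / denom
    return pd.DataFrame(k, index=panel.sample_ids, columns=panel.sample_ids)


# ---------------------------------------------------------------------------
# REML via spectral decomposition
# ---------------------------------------------------------------------------


def _reml_null(y: np.ndarray, x0: np.ndarray, k: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """REML variance components for y = X0 b + u + e with u ~ N(0, sg² K).

    Returns (sigma_g2, sigma_e2, eigenvalues, eigenvectors) with the
    decomposition K = U diag(lam) Uᵀ.  Optimizes the REML log-likelihood
    over delta = sigma_e²/sigma_g² on a log grid refined by Brent search.
    """
    n, p = x0.shape
    lam, u = np.linalg.eigh(k)
    lam = np.maximum(lam, 0.0)
    yt = u.T @ y
    xt = u.T @ x0

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (lam + delta)
        xtwx = xt.T @ (xt * w[:, None])
        try:
            beta = np.linalg.solve(xtwx, xt.T @ (yt * w))
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - xt @ beta
        rss = float(r @ (r * w))
        if rss <= 0:
            return np.inf
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * np.log(rss / (n - p))
            + np.log(lam + delta).sum()
            + logdet_xtwx
            + (n - p)
        )
        return -ll

    grid = np.linspace(-10, 10, 41)
    vals = np.array([neg_reml(g) for g in grid])
    # on a flat stretch (e.g. K = I makes REML independent of delta) prefer
    # the largest delta: undetermined variance goes to the residual term
    j = len(vals) - 1 - int(np.argmin(vals[::-1]))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))

    w = 1.0 / (lam + delta)
    xtwx = xt.T @ (xt * w[:, None])
    beta = np.linalg.solve(xtwx, xt.T @ (yt * w))
    r = yt - xt @ beta
    sigma_g2 = float(r @ (r * w)) / (n - p)
    sigma_e2 = sigma_g2 * delta
    return sigma_g2, sigma_e2, lam, u


@dataclass
class AssociationResult:
    table: pd.DataFrame  # marker, p, neglog10p, effect, maf, n
    sigma_g2: float
    sigma_e2: float
    h2: float
    bonferroni_neglog10: float
    by_threshold_p: float  # largest rejected p under B-Y (0 if none)
    r2_top: float
    n_samples: int
    alpha: float


def mlm_scan(
    y: pd.Series,
    panel: GenotypeMatrix,
    q: pd.DataFrame | None = None,
    kinship: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    min_success: float = 0.9,
    alpha: float = 0.01,
) -> AssociationResult:
    """Q+K mixed-model association scan for a binary trait.

    ``y`` is a 0/1 Series indexed by sample id; only samples both
    phenotyped and genotyped are used.  ``q`` supplies admixture
    proportions (the last column is dropped to avoid collinearity with
    the intercept); ``kinship`` defaults to VanRaden on the same panel.
    Markers below ``maf_min`` or with genotyping success below
    ``min_success`` within the used samples are skipped (reported NaN).
    """
    y = y.dropna()
    samples = [s for s in panel.sample_ids if s in set(y.index)]
    if len(samples) < 3:
        raise PanelError("fewer than 3 phenotyped+genotyped samples")
    yv = y.loc[samples].to_numpy(dtype=float)
    if np.all(yv == yv[0]):
        raise PanelError("phenotype is constant")
    sub = panel.subset(samples=samples)
    g = additive_code(sub)
    n = len(samples)

    x0 = np.ones((n, 1))
    if q is not None:
        qm = q.reindex(samples).to_numpy(dtype=float)
        if qm.shape[1] > 1:
            x0 = np.column_stack([x0, qm[:, :-1]])
    if kinship is None:
        kinship = vanraden_kinship(sub)
    k = kinship.reindex(index=samples, columns=samples).to_numpy(dtype=float)

    sigma_g2, sigma_e2, lam, u = _reml_null(yv, x0, k)
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if (sigma_g2 + sigma_e2) > 0 else 0.0
    delta = sigma_e2 / sigma_g2 if sigma_g2 > 0 else np.inf
    if np.isfinite(delta):
        w = 1.0 / (lam + delta)
    else:  # no genetic variance: plain OLS weights
        w = np.ones(n)
    yt = u.T @ yv
    x0t = u.T @ x0

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    success = 1.0 - np.isnan(g).mean(axis=0)
    testable = (maf >= maf_min) & (success >= min_success)

    m = sub.n_markers
    pvals = np.full(m, np.nan)
    effects = np.full(m, np.nan)
    fitted_top = None
    p_cols = x0.shape[1] + 1
    for j in range(m):
        if not testable[j]:
            continue
        gj = g[:, j]
        mean_j = np.nanmean(gj)
        gj = np.where(np.isnan(gj), mean_j, gj)
        xt = np.column_stack([x0t, u.T @ gj])
        xtwx = xt.T @ (xt * w[:, None])
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            continue
        beta = xtwx_inv @ (xt.T @ (yt * w))
        r = yt - xt @ beta
        rss = float(r @ (r * w))
        dof = n - p_cols
        if dof <= 0 or rss <= 0:
            continue
        s2 = rss / dof
        se = np.sqrt(s2 * xtwx_inv[-1, -1])
        if se == 0:
            continue
        fstat = (beta[-1] / se) ** 2
        pvals[j] = float(stats.f.sf(fstat, 1, dof))
        effects[j] = float(beta[-1])

    if np.all(np.isnan(pvals)):
        raise PanelError("no testable markers")
    top = int(np.nanargmin(pvals))
    gj = g[:, top]
    gj = np.where(np.isnan(gj), np.nanmean(gj), gj)
    xt = np.column_stack([x0t, u.T @ gj])
    xtwx = xt.T @ (xt * w[:, None])
    beta = np.linalg.solve(xtwx, xt.T @ (yt * w))
    fitted = u @ (xt @ beta)
    r2_top = float(np.corrcoef(fitted, yv)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0

    m_tests = int(testable.sum())
    bonf, by_p = significance_thresholds(pvals[testable], alpha)

    table = pd.DataFrame(
        {
            "p": pvals,
            "neglog10p": -np.log10(pvals),
            "effect": effects,
            "maf": maf,
            "n": (~np.isnan(g)).sum(axis=0),
        },
        index=sub.marker_ids,
    )
    return AssociationResult(
        table=table,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        bonferroni_neglog10=bonf,
        by_threshold_p=by_p,
        r2_top=r2_top,
        n_samples=n,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# multiple-testing thresholds
# ---------------------------------------------------------------------------


def bonferroni_neglog10(m: int, alpha: float = 0.01) -> float:
    """−log10 of the Bonferroni per-test cutoff alpha/m."""
    if m < 1:
        raise PanelError("need at least one test")
    return float(-np.log10(alpha / m))


def by_rejections(p_values: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Benjamini–Yekutieli step-up rejection flags (any-dependence FDR).

    With c(m) = Σ 1/i, rejects the i smallest p-values where i is the
    largest index with p_(i) <= i·alpha/(m·c(m)).
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    flags = np.zeros(len(p), dtype=bool)
    if m == 0:
        return flags
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(np.where(ok, p, np.inf))
    sorted_p = p[order][:m]
    crit = np.arange(1, m + 1) * alpha / (m * c_m)
    passing = np.nonzero(sorted_p <= crit)[0]
    if len(passing):
        k = passing.max()
        flags[order[: k + 1]] = True
    return flags


def significance_thresholds(p_values: np.ndarray, alpha: float = 0.01) -> tuple[float, float]:
    """(Bonferroni −log10 cutoff, largest p rejected under B–Y or 0)."""
    p = np.asarray(p_values, dtype=float)
    m = int((~np.isnan(p)).sum())
    bonf = bonferroni_neglog10(max(m, 1), alpha)
    flags = by_rejections(p, alpha)
    by_p = float(np.nanmax(np.where(flags, p, np.nan))) if flags.any() else 0.0
    return bonf, by_p


# ---------------------------------------------------------------------------
# balanced-subset resampling scan for rare unbalanced traits
# ---------------------------------------------------------------------------


@dataclass
class SubsetScanResult:
    counts: pd.Series  # per marker: number of subsets significant (Bonferroni)
    consensus: list[str]  # markers significant in every subset
    n_subsets: int
    results: list[AssociationResult] = field(repr=False, default_factory=list)


def balanced_subset_scan(
    y: pd.Series,
    panel: GenotypeMatrix,
    q: pd.DataFrame | None = None,
    kinship: pd.DataFrame | None = None,
    n_subsets: int = 15,
    n_controls: int = 100,
    control_pool: list[str] | None = None,
    alpha: float = 0.01,
    seed: int = 0,
    maf_min: float = 0.05,
) -> SubsetScanResult:
    """Repeated case–control scans for a rare-minority binary trait.

    Each subset contains every minority-class sample plus ``n_controls``
    controls drawn without replacement (seeded) from ``control_pool``
    (default: all majority-class samples).  A marker's score is the
    number of subsets in which it passes the per-subset Bonferroni
    threshold at ``alpha``; the consensus set is the markers significant
    in all subsets.
    """
    y = y.dropna().astype(int)
    cases = [s for s in y.index if y[s] == 1 and s in set(panel.sample_ids)]
    controls_all = [s for s in y.index if y[s] == 0 and s in set(panel.sample_ids)]
    if len(cases) > len(controls_all):
        cases, controls_all = controls_all, cases
    if not cases:
        raise PanelError("minority phenotype class is empty")
    pool = control_pool if control_pool is not None else controls_all
    pool = [s for s in pool if s in set(controls_all)]
    if len(pool) < n_controls:
        raise PanelError(f"control pool has {len(pool)} < {n_controls} samples")

    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=panel.marker_ids, dtype=int)
    tested_all = pd.Series(True, index=panel.marker_ids)
    results = []
    for _ in range(n_subsets):
        controls = list(rng.choice(pool, n_controls, replace=False))
        subset_samples = [s for s in panel.sample_ids if s in set(cases) | set(controls)]
        sub = panel.subset(samples=subset_samples)
        res = mlm_scan(
            y.loc[subset_samples], sub, q=q, kinship=kinship, alpha=alpha, maf_min=maf_min
        )
        results.append(res)
        sig = res.table["neglog10p"] > res.bonferroni_neglog10
        sig = sig.fillna(False)
        counts[sig.index[sig]] += 1
        tested = res.table["p"].notna()
        tested_all &= tested.reindex(tested_all.index, fill_value=False)
    consensus = [m for m in panel.marker_ids if counts[m] == n_subsets]
    return SubsetScanResult(counts, consensus, n_subsets, results)
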