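"""Linkage disequilibrium: genotypic r², structure/kinship-corrected r²,
intra/inter-chromosomal summaries, decay-curve fitting, and block calling.

Because gametic phase is unknown in an outbred panel, LD is measured as
the squared Pearson correlation of genotypic allele counts (0/1/2).  The
corrected variant removes LD that is explained by population structure
(fixed covariates S, typically admixture proportions) and/or relatedness
(a kinship-derived covariance V): genotype vectors are replaced by their
generalized-least-squares residuals and correlated under the inner
product induced by V⁻¹.  With V = I and S = intercept the corrected
statistic reduces exactly to the classical r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .calls import GenotypeMatrix, MarkerInfo, PanelError
from .structure import additive_code


def r2_pair(g1: np.ndarray, g2: np.ndarray, min_complete: int = 10) -> float:
    """Squared Pearson correlation of two allele-count vectors on
    pairwise-complete samples; NaN if either vector is constant after
    completion or fewer than ``min_complete`` samples remain."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < min_complete:
        return float("nan")
    x, y = g1[ok], g2[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_matrix(g: np.ndarray, min_complete: int = 10) -> np.ndarray:
    """All-pairs genotypic r² with pairwise-complete handling of missing
    calls (columns are markers)."""
    df = pd.DataFrame(g)
    corr = df.corr(min_periods=min_complete).to_numpy()
    return corr**2


def _gls_residual(g: np.ndarray, s: np.ndarray, vinv_chol) -> np.ndarray:
    """Residual of g on covariates S under the covariance whose Cholesky
    solve is given; ordinary residual when vinv_chol is None."""
    if vinv_chol is None:
        vs = s
        vg = g
    else:
        vs = cho_solve(vinv_chol, s)
        vg = cho_solve(vinv_chol, g)
    beta = np.linalg.solve(s.T @ vs, s.T @ vg)
    return g - s @ beta


def r2_corrected(
    g1: np.ndarray,
    g2: np.ndarray,
    s: np.ndarray | None = None,
    v: np.ndarray | None = None,
    ridge: float = 0.0,
) -> float:
    """Structure/kinship-corrected genotypic r².

    Parameters
    ----------
    g1, g2
        Allele-count vectors (no missing values; impute first).
    s
        Fixed covariates for population structure (an intercept column is
        added if absent).  ``None`` means intercept only.
    v
        Relatedness covariance (e.g. a kinship matrix); must be symmetric
        positive definite, optionally stabilized with ``ridge`` added to
        the diagonal.  ``None`` means identity.

    Returns the squared correlation of the GLS residuals of the two
    vectors under the V⁻¹ inner product, clipped to [0, 1].
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise PanelError("corrected r2 requires complete (imputed) genotype vectors")
    n = len(g1)
    if s is None:
        s = np.ones((n, 1))
    else:
        s = np.asarray(s, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        if not np.any(np.all(s == s[0, :], axis=0) & (s[0, :] != 0)):
            s = np.column_stack([np.ones(n), s])
    chol = None
    if v is not None:
        vv = np.asarray(v, dtype=float) + ridge * np.eye(n)
        try:
            chol = cho_factor(vv)
        except np.linalg.LinAlgError as exc:
            raise PanelError(
                "kinship covariance is singular; pass a ridge term (ridge=...)"
            ) from exc
    e1 = _gls_residual(g1, s, chol)
    e2 = _gls_residual(g2, s, chol)
    if chol is None:
        w1, w2 = e1, e2
    else:
        w1 = cho_solve(chol, e1)
        w2 = cho_solve(chol, e2)
    num = float(e1 @ w2)
    d1 = float(e1 @ w1)
    d2 = float(e2 @ w2)
    if d1 <= 0 or d2 <= 0:
        return float("nan")
    return float(np.clip(num * num / (d1 * d2), 0.0, 1.0))


# ---------------------------------------------------------------------------
# summaries and decay
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    degree: int
    coefficients: np.ndarray  # numpy polyfit order (highest degree first)
    crossing_bp: float | None  # smallest distance where the fit <= 0.2
    mean_intra_r2: float
    mean_inter_r2: float
    bin_centers: np.ndarray
    bin_means: np.ndarray


def fit_decay(
    distances: np.ndarray,
    r2: np.ndarray,
    degree: int = 2,
    bin_bp: int = 50_000,
    threshold: float = 0.2,
) -> tuple[np.ndarray, float | None, np.ndarray, np.ndarray]:
    """Polynomial fit of binned mean r² against distance and the smallest
    distance at which the fitted curve drops to ``threshold``.

    The crossing is searched only inside the observed distance range; if
    the fit never reaches the threshold there, the crossing is None.
    """
    ok = np.isfinite(distances) & np.isfinite(r2)
    distances, r2 = distances[ok], r2[ok]
    if len(distances) == 0:
        raise PanelError("no pairs to fit")
    bins = np.floor(distances / bin_bp).astype(int)
    df = pd.DataFrame({"bin": bins, "r2": r2}).groupby("bin")["r2"].mean()
    centers = (df.index.to_numpy() + 0.5) * bin_bp
    means = df.to_numpy()
    deg = min(degree, max(1, len(means) - 1))
    coeffs = np.polyfit(centers, means, deg)
    poly = np.poly1d(coeffs - np.append(np.zeros(deg), threshold))
    lo, hi = centers.min(), centers.max()
    crossing: float | None = None
    fitted = np.poly1d(coeffs)
    if fitted(lo) <= threshold:
        crossing = float(lo)
    else:
        roots = poly.roots
        real = roots[np.isreal(roots)].real
        in_range = real[(real >= lo) & (real <= hi)]
        if len(in_range):
            crossing = float(in_range.min())
    return coeffs, crossing, centers, means


def ld_summaries(
    panel: GenotypeMatrix,
    info: MarkerInfo,
    maf_min: float = 0.01,
    max_nocall: float = 0.05,
    max_pairs: int = 200_000,
    degree: int = 2,
    bin_bp: int = 50_000,
    seed: int = 0,
    min_complete: int = 10,
) -> DecayFit:
    """Intra/inter-chromosomal r² summary and decay fit for one panel
    (typically one subpopulation).

    Markers failing the within-panel frequency test (MAF < ``maf_min``) or
    the no-call cutoff (> ``max_nocall``) are discarded first.  All
    intra-chromosomal pairs are used up to ``max_pairs`` (beyond that, a
    seeded subsample); inter-chromosomal pairs are subsampled to the same
    cap.
    """
    rng = np.random.default_rng(seed)
    g = additive_code(panel)
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)
    nc = np.isnan(g).mean(axis=0)
    keep = (maf >= maf_min) & (nc <= max_nocall)
    if keep.sum() < 2:
        raise PanelError("fewer than 2 markers pass the LD frequency filters")
    ids = [m for m, k in zip(panel.marker_ids, keep) if k]
    g = g[:, keep]
    tab = info.table.reindex(ids)
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos"].to_numpy()

    mm = len(ids)
    iu, ju = np.triu_indices(mm, k=1)
    intra = chrom[iu] == chrom[ju]
    intra_idx = np.nonzero(intra)[0]
    inter_idx = np.nonzero(~intra)[0]
    if len(intra_idx) == 0:
        raise PanelError("no intra-chromosomal pairs")
    if len(intra_idx) > max_pairs:
        intra_idx = rng.choice(intra_idx, max_pairs, replace=False)
    if len(inter_idx) > max_pairs:
        inter_idx = rng.choice(inter_idx, max_pairs, replace=False)

    def pair_r2(idx: np.ndarray) -> np.ndarray:
        return np.array(
            [r2_pair(g[:, iu[t]], g[:, ju[t]], min_complete) for t in idx]
        )

    r2_intra = pair_r2(intra_idx)
    r2_inter = pair_r2(inter_idx) if len(inter_idx) else np.array([])
    dist = np.abs(pos[iu[intra_idx]] - pos[ju[intra_idx]]).astype(float)

    coeffs, crossing, centers, means = fit_decay(dist, r2_intra, degree, bin_bp)
    return DecayFit(
        degree=degree,
        coefficients=coeffs,
        crossing_bp=crossing,
        mean_intra_r2=float(np.nanmean(r2_intra)),
        mean_inter_r2=float(np.nanmean(r2_inter)) if len(r2_inter) else float("nan"),
        bin_centers=centers,
        bin_means=means,
    )


# ---------------------------------------------------------------------------
# block calling
# ---------------------------------------------------------------------------


@dataclass
class LDBlock:
    chrom: int
    start: int
    end: int
    n_markers: int
    median_r2: float
    marker_ids: list[str]


def _median_pairwise(r2: np.ndarray, lo: int, hi: int) -> float:
    sub = r2[lo:hi, lo:hi]
    vals = sub[np.triu_indices(hi - lo, k=1)]
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if len(vals) else float("nan")


def ld_blocks(
    panel: GenotypeMatrix,
    info: MarkerInfo,
    r2_min: float = 0.5,
    min_markers: int = 3,
    min_complete: int = 10,
) -> tuple[list[LDBlock], dict[int, pd.DataFrame]]:
    """High-LD blocks by greedy extension.

    Per chromosome (markers ordered by position), a run starting at each
    marker is extended while the median of all pairwise r² inside the run
    stays >= ``r2_min`` and the entering marker's median r² against the
    current run stays >= ``r2_min`` (the second condition keeps a strong
    block from dragging equilibrium flankers along on the strength of its
    internal pairs); maximal non-nested runs with >= ``min_markers``
    markers are reported.  Also returns the full intra-chromosomal r²
    matrix per chromosome for heat-map export.
    """
    g = additive_code(panel)
    tab = info.table.reindex(panel.marker_ids)
    blocks: list[LDBlock] = []
    matrices: dict[int, pd.DataFrame] = {}
    for chrom, sub in tab.groupby("chrom", sort=True):
        order = sub.sort_values("pos")
        ids = list(order.index)
        idx = [panel.marker_ids.index(m) for m in ids]
        pos = order["pos"].to_numpy()
        r2 = r2_matrix(g[:, idx], min_complete)
        matrices[int(chrom)] = pd.DataFrame(r2, index=ids, columns=ids)
        m = len(ids)
        runs: list[tuple[int, int]] = []
        for start in range(m):
            end = start + 1
            best = None
            while end <= m:
                if end - start >= 2:
                    entering = r2[end - 1, start : end - 1]
                    entering = entering[np.isfinite(entering)]
                    if len(entering) == 0 or np.median(entering) < r2_min:
                        break
                    if _median_pairwise(r2, start, end) < r2_min:
                        break
                if end - start >= min_markers:
                    best = (start, end)
                end += 1
            if best:
                runs.append(best)
        # drop nested runs
        maximal = [
            (s, e)
            for s, e in runs
            if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in runs)
        ]
        for s, e in sorted(set(maximal)):
            blocks.append(
                LDBlock(
                    chrom=int(chrom),
                    start=int(pos[s]),
                    end=int(pos[e - 1]),
                    n_markers=e - s,
                    median_r2=_median_pairwise(r2, s, e),
                    marker_ids=ids[s:e],
                )
            )
    return blocks, matrices
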