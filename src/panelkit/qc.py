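"""Marker QC: A–E performance classification, call-rate sample filtering,
per-marker statistics and selection of the analysis marker set.

Array markers are sorted into five performance classes:

* **A** — well-behaved polymorphic: no-call < 5% and all three genotype
  classes observed;
* **B** — suspected null allele / preferential annealing: 5–50% of samples
  with normalized intensity R < 0.2, the remaining samples still showing
  at least two genotype classes;
* **C** — suspected duplicated locus: one homozygote cluster absent with a
  marked heterozygote excess and no-call < 5%;
* **D** — false (monomorphic) marker: a single genotype class, no-call < 5%;
* **E** — failed: no-call > 50%, or GenTrain < 0.4, or GenCall-10% < 0.2.

Classification precedence is E, D, A, B, C; anything unmatched falls back
to E.  Rules that need metadata the caller did not supply (intensity or
clustering scores) are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import HET, HOM_A, HOM_B, NO_CALL, GenotypeMatrix, MarkerInfo

#: heterozygote excess needed (ho > he + HET_EXCESS) before a one-homozygote
#: marker is called a duplicated locus rather than sampling noise
HET_EXCESS = 0.2

CLASSES = ("A", "B", "C", "D", "E")


def genotype_counts(panel: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker counts of AA / AB / BB / no-call."""
    out = {}
    for name, code in (("n_AA", HOM_A), ("n_AB", HET), ("n_BB", HOM_B), ("n_NC", NO_CALL)):
        out[name] = (panel.calls == code).sum(axis=0)
    return pd.DataFrame(out, index=panel.marker_ids)


def classify_markers(panel: GenotypeMatrix, info: MarkerInfo | None = None) -> pd.Series:
    """Assign each marker one of the classes A–E.

    Returns a Series of single-character class labels indexed by marker id.
    """
    counts = genotype_counts(panel)
    n = panel.n_samples
    nc_frac = counts["n_NC"].to_numpy() / n
    n_called = (counts[["n_AA", "n_AB", "n_BB"]].sum(axis=1)).to_numpy()
    present = (counts[["n_AA", "n_AB", "n_BB"]].to_numpy() > 0)
    n_classes = present.sum(axis=1)

    gentrain = np.full(panel.n_markers, np.nan)
    gencall10 = np.full(panel.n_markers, np.nan)
    low_frac = np.zeros(panel.n_markers)
    have_low = False
    if info is not None:
        tab = info.table.reindex(panel.marker_ids)
        if "gentrain" in tab.columns:
            gentrain = tab["gentrain"].to_numpy(dtype=float)
        if "gencall10" in tab.columns:
            gencall10 = tab["gencall10"].to_numpy(dtype=float)
        if info.low_intensity is not None:
            have_low = True
            low_frac = info.low_intensity.mean(axis=0)

    labels = np.full(panel.n_markers, "", dtype="<U1")

    with np.errstate(invalid="ignore"):
        failed_scores = (gentrain < 0.4) | (gencall10 < 0.2)
    is_e = (nc_frac > 0.5) | failed_scores
    labels[is_e] = "E"

    open_ = labels == ""
    is_d = open_ & (n_classes == 1) & (nc_frac < 0.05)
    labels[is_d] = "D"

    open_ = labels == ""
    is_a = open_ & (n_classes == 3) & (nc_frac < 0.05)
    labels[is_a] = "A"

    if have_low:
        open_ = labels == ""
        cand = np.nonzero(open_ & (low_frac >= 0.05) & (low_frac <= 0.5))[0]
        for j in cand:
            good = ~info.low_intensity[:, j]  # type: ignore[union-attr]
            col = panel.calls[good, j]
            col = col[col != NO_CALL]
            if np.unique(col).size >= 2:
                labels[j] = "B"

    open_ = labels == ""
    n_hom_present = present[:, [0, 2]].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(n_called > 0, counts["n_AB"].to_numpy() / np.maximum(n_called, 1), 0.0)
        p_b = np.where(
            n_called > 0,
            (counts["n_AB"].to_numpy() + 2 * counts["n_BB"].to_numpy())
            / (2 * np.maximum(n_called, 1)),
            0.0,
        )
    he = 2 * p_b * (1 - p_b)
    is_c = (
        open_
        & (n_hom_present == 1)
        & (present[:, 1])
        & (ho > he + HET_EXCESS)
        & (nc_frac < 0.05)
    )
    labels[is_c] = "C"

    labels[labels == ""] = "E"
    return pd.Series(labels, index=panel.marker_ids, name="marker_class")


def class_counts(classes: pd.Series) -> pd.Series:
    """Counts per class A–E in fixed order (sums to the number of markers)."""
    return classes.value_counts().reindex(CLASSES, fill_value=0)


def filter_samples(
    panel: GenotypeMatrix, call_rate_delta: float = 0.1
) -> tuple[GenotypeMatrix, pd.Series, list[str]]:
    """Drop samples whose call rate falls below mean(call rate) − delta.

    The mean is computed once on the full panel, not iterated.  Returns the
    filtered panel, all per-sample call rates, and the removed sample ids.
    """
    rates = panel.sample_call_rates()
    threshold = rates.mean() - call_rate_delta
    keep = rates[rates >= threshold].index.tolist()
    removed = [s for s in panel.sample_ids if s not in set(keep)]
    return panel.subset(samples=keep), rates, removed


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy–Weinberg test p-value for one biallelic marker.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (two-sided exact conditional test).  Computed with log-factorials so it
    is stable for panel-scale sample sizes.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return float("nan")
    n_a_alleles = 2 * n_aa + n_ab
    n_b_alleles = 2 * n_bb + n_ab
    rare = min(n_a_alleles, n_b_alleles)
    if rare == 0:
        return 1.0

    lf = [0.0] * (2 * n + 1)
    for i in range(2, 2 * n + 1):
        lf[i] = lf[i - 1] + math.log(i)

    common = 2 * n - rare

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            lf[n]
            - lf[het]
            - lf[hom_rare]
            - lf[hom_common]
            + het * math.log(2)
            + lf[rare]
            + lf[common]
            - lf[2 * n]
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    mx = max(logs.values())
    probs = {h: math.exp(v - mx) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_ab]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def marker_stats(panel: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, observed/expected heterozygosity, exact HWE p,
    call rate and called count.  All frequencies use called genotypes only.
    """
    counts = genotype_counts(panel)
    n_called = counts[["n_AA", "n_AB", "n_BB"]].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_b = (counts["n_AB"] + 2 * counts["n_BB"]) / (2 * n_called)
    maf = np.minimum(p_b, 1 - p_b)
    ho = counts["n_AB"] / n_called
    he = 2 * p_b * (1 - p_b)
    hwe = [
        hwe_exact_p(int(a), int(h), int(b)) if nc > 0 else float("nan")
        for a, h, b, nc in zip(counts["n_AA"], counts["n_AB"], counts["n_BB"], n_called)
    ]
    return pd.DataFrame(
        {
            "maf": maf,
            "ho": ho,
            "he": he,
            "hwe_p": hwe,
            "call_rate": n_called / panel.n_samples,
            "n_called": n_called,
        },
        index=panel.marker_ids,
    )


@dataclass
class QCResult:
    classes: pd.Series
    stats: pd.DataFrame
    analysis_markers: list[str]


def select_markers(
    stats: pd.DataFrame,
    classes: pd.Series,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-4,
) -> list[str]:
    """Analysis marker set: class A, MAF >= maf_min, HWE exact p >= alpha.

    Markers at exactly MAF = maf_min are retained ("lower than" discarded);
    the HWE discard uses strict p < alpha.
    """
    keep = (
        (classes == "A")
        & (stats["maf"] >= maf_min)
        & ~(stats["hwe_p"] < hwe_alpha)
        & stats["hwe_p"].notna()
    )
    return list(stats.index[keep])


def run_qc(
    panel: GenotypeMatrix,
    info: MarkerInfo | None = None,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-4,
    call_rate_delta: float = 0.1,
) -> tuple[GenotypeMatrix, QCResult]:
    """Full QC pass: sample filter, classification, stats, marker selection."""
    filtered, _, _ = filter_samples(panel, call_rate_delta)
    classes = classify_markers(filtered, info)
    stats = marker_stats(filtered)
    selected = select_markers(stats, classes, maf_min, hwe_alpha)
    return filtered, QCResult(classes, stats, selected)
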