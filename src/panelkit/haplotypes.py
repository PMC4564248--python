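"""EM haplotype phasing of trait-associated marker sets and per-haplotype
chi-square trait tests.

Phasing uses haplotype-frequency EM (gene counting): haplotype population
frequencies are the parameters, each individual's unphased multilocus
genotype defines the set of ordered haplotype pairs compatible with it
(missing genotypes are unobserved and expand the compatible set), and EM
alternates posterior pair weights with frequency updates.  For marker
sets larger than one EM window, windows are phased separately and ligated
through their overlapping markers (partition–ligation), keeping the
candidate haplotypes whose joint frequencies are consistent across the
overlap.  On small instances (<= ~8 markers) the result matches a
full-enumeration EM, which the test suite checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import HET, HOM_A, HOM_B, NO_CALL, GenotypeMatrix, PanelError

log = logging.getLogger(__name__)

Hap = tuple[int, ...]  # alleles in {0,1} = {A,B}

MAX_WINDOW = 12
MAX_CANDIDATES = 128  # candidate haplotypes kept per ligation step


def _compatible_pairs(geno: np.ndarray) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs consistent with one genotype vector.

    Heterozygous sites contribute a factor 2 (phase), missing sites a
    factor 3 (genotype unknown).  Pairs are returned with h1 <= h2.
    """
    site_pairs: list[list[tuple[int, int]]] = []
    for g in geno:
        if g == HOM_A:
            site_pairs.append([(0, 0)])
        elif g == HOM_B:
            site_pairs.append([(1, 1)])
        elif g == HET:
            site_pairs.append([(0, 1), (1, 0)])
        else:
            site_pairs.append([(0, 0), (0, 1), (1, 0), (1, 1)])
    pairs = set()
    for combo in itertools.product(*site_pairs):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def _em(
    pair_lists: list[list[tuple[Hap, Hap]]],
    haps: list[Hap],
    rng: np.random.Generator,
    starts: int,
    iters: int,
    tol: float = 1e-10,
) -> tuple[dict[Hap, float], float, list[np.ndarray]]:
    """Haplotype-frequency EM over a fixed candidate haplotype set.

    Returns (frequencies, best log-likelihood, per-start loglik traces).
    The log-likelihood is non-decreasing within each start.
    """
    index = {h: i for i, h in enumerate(haps)}
    pair_idx = [
        np.array([[index[a], index[b]] for a, b in pl], dtype=int) for pl in pair_lists
    ]
    het_pair = [np.array([a != b for a, b in pl]) for pl in pair_lists]
    n = len(pair_lists)
    best_f = None
    best_ll = -np.inf
    traces = []
    for s in range(starts):
        if s == 0:
            f = np.full(len(haps), 1.0 / len(haps))
        else:
            f = rng.dirichlet(np.ones(len(haps)))
        trace = []
        prev = -np.inf
        for _ in range(iters):
            new = np.zeros(len(haps))
            ll = 0.0
            for i in range(n):
                pi = pair_idx[i]
                w = f[pi[:, 0]] * f[pi[:, 1]]
                w = np.where(het_pair[i], 2 * w, w)
                tot = w.sum()
                if tot <= 0:
                    w = np.ones(len(w))
                    tot = w.sum()
                ll += np.log(tot)
                w = w / tot
                np.add.at(new, pi[:, 0], w)
                np.add.at(new, pi[:, 1], w)
            f = new / (2 * n)
            trace.append(ll)
            if ll - prev < tol and len(trace) > 2:
                break
            prev = ll
        traces.append(np.array(trace))
        if trace[-1] > best_ll:
            best_ll = trace[-1]
            best_f = f.copy()
    freqs = {h: float(best_f[i]) for h, i in index.items() if best_f[i] > 1e-12}
    return freqs, float(best_ll), traces


def _best_pairs(
    pair_lists: list[list[tuple[Hap, Hap]]], freqs: dict[Hap, float]
) -> list[tuple[Hap, Hap]]:
    """Most probable compatible pair per individual under the frequencies."""
    out = []
    for pl in pair_lists:
        best, best_w = None, -1.0
        for a, b in pl:
            w = freqs.get(a, 0.0) * freqs.get(b, 0.0) * (2.0 if a != b else 1.0)
            if w > best_w:
                best, best_w = (a, b), w
        out.append(best)  # type: ignore[arg-type]
    return out


@dataclass
class HaplotypeSet:
    marker_ids: list[str]
    sample_ids: list[str]
    pairs: list[tuple[Hap, Hap]]  # most probable reconstruction per sample
    frequencies: pd.Series  # EM haplotype frequencies (sum to 1)
    loglik: float
    heterozygosity: float  # fraction of samples whose two haplotypes differ

    def haplotype_strings(self) -> pd.Series:
        return self.frequencies.rename(index=hap_to_string)


def hap_to_string(h: Hap) -> str:
    return "".join("AB"[a] for a in h)


def phase_em(
    panel: GenotypeMatrix,
    markers: list[str] | None = None,
    starts: int = 20,
    iters: int = 100,
    window: int = 6,
    overlap: int = 3,
    seed: int = 0,
) -> HaplotypeSet:
    """Phase a small set of markers into haplotypes by windowed EM.

    Markers are taken in the given order (sort by position first for
    genomic marker sets).  Windows of ``window`` markers overlapping by
    ``overlap`` are phased independently and ligated left to right; each
    ligation keeps the top ``MAX_CANDIDATES`` combined haplotypes by
    frequency, always retaining enough candidates to cover every sample.
    """
    if window > MAX_WINDOW:
        raise PanelError(f"window {window} exceeds cap {MAX_WINDOW}")
    if overlap >= window:
        raise PanelError("overlap must be smaller than window")
    sub = panel if markers is None else panel.subset(markers=markers)
    m = sub.n_markers
    if m == 0:
        raise PanelError("no markers to phase")
    calls = sub.calls
    poly = [(calls[:, j][calls[:, j] != NO_CALL].std() > 0) for j in range(m)]
    if not any(poly):
        raise PanelError("no polymorphic markers to phase")
    rng = np.random.default_rng(seed)
    n = sub.n_samples

    def phase_span(lo: int, hi: int, cand: list[Hap] | None = None):
        genos = [calls[i, lo:hi] for i in range(n)]
        if cand is None:
            # direct enumeration: only for spans no longer than one window
            pair_lists = [_compatible_pairs(g) for g in genos]
        else:
            # restrict to pairs drawn from the candidate set; a sample whose
            # genotype no candidate pair explains contributes a forced pair
            cset = sorted(set(cand))
            pair_lists = []
            for g in genos:
                fl = [
                    (a, b)
                    for ia, a in enumerate(cset)
                    for b in cset[ia:]
                    if _pair_consistent(g, a, b)
                ]
                if not fl:
                    fl = [_forced_pair(g, cset)]
                pair_lists.append(fl)
        haps = sorted({h for pl in pair_lists for p in pl for h in p})
        freqs, ll, _ = _em(pair_lists, haps, rng, starts, iters)
        return pair_lists, freqs, ll

    if m <= window:
        pair_lists, freqs, ll = phase_span(0, m)
    else:
        step = window - overlap
        starts_pos = list(range(0, m - window + 1, step))
        if starts_pos[-1] + window < m:
            starts_pos.append(m - window)
        # phase the first window, then extend by ligation
        _, freqs, ll = phase_span(0, window)
        cur_hi = window
        cur_haps = _top_candidates(freqs)
        for wlo in starts_pos[1:]:
            whi = wlo + window
            _, wfreqs, _ = phase_span(wlo, whi)
            wh = _top_candidates(wfreqs)
            ov = cur_hi - wlo
            combined = sorted(
                {
                    a + b[ov:]
                    for a in cur_haps
                    for b in wh
                    if a[len(a) - ov :] == b[:ov]
                }
            )
            pair_lists, freqs, ll = phase_span(0, whi, cand=combined)
            cur_hi = whi
            cur_haps = _top_candidates(freqs)
        # final pass over the full span with the surviving candidates
        pair_lists, freqs, ll = phase_span(0, m, cand=_top_candidates(freqs))

    pairs = _best_pairs(pair_lists, freqs)
    for i, (a, b) in enumerate(pairs):
        _assert_consistent(calls[i], a, b, sub.sample_ids[i])
    het = float(np.mean([a != b for a, b in pairs]))
    # keep tuple keys as plain object index (not a MultiIndex)
    fser = pd.Series(
        list(freqs.values()), index=pd.Index(list(freqs.keys()), tupleize_cols=False)
    ).sort_values(ascending=False)
    fser = fser / fser.sum()
    return HaplotypeSet(
        marker_ids=sub.marker_ids,
        sample_ids=sub.sample_ids,
        pairs=pairs,
        frequencies=fser,
        loglik=ll,
        heterozygosity=het,
    )


def _pair_consistent(geno: np.ndarray, h1: Hap, h2: Hap) -> bool:
    for g, a, b in zip(geno, h1, h2):
        if g != NO_CALL and a + b != g:
            return False
    return True


def _forced_pair(geno: np.ndarray, candidates: list[Hap]) -> tuple[Hap, Hap]:
    """Deterministic compatible pair for a sample no candidate pair covers:
    take the candidate consistent at the most sites as one haplotype and
    derive the other from the genotype (copying the first at missing
    sites)."""

    def n_ok(h: Hap) -> int:
        return sum(
            1
            for g, a in zip(geno, h)
            if g == NO_CALL or (g - a) in (0, 1)
        )

    a = max(candidates, key=n_ok)
    b = tuple(
        int(a_j) if g == NO_CALL else int(min(max(g - a_j, 0), 1))
        for g, a_j in zip(geno, a)
    )
    a2 = tuple(
        int(a_j) if g == NO_CALL else int(g - b_j)
        for g, a_j, b_j in zip(geno, a, b)
    )
    return (a2, b) if a2 <= b else (b, a2)


def _top_candidates(freqs: dict[Hap, float], cap: int = MAX_CANDIDATES) -> list[Hap]:
    ranked = sorted(freqs, key=lambda h: (-freqs[h], h))
    return ranked[:cap]
    ranked = sorted(freqs, key=lambda h: -freqs[h])
    return ranked[:cap]


def _assert_consistent(geno: np.ndarray, h1: Hap, h2: Hap, sample: str) -> None:
    for g, a, b in zip(geno, h1, h2):
        if g == NO_CALL:
            continue
        if a + b != g:
            raise PanelError(
                f"phased pair inconsistent with genotype for sample {sample!r}"
            )


def marker_heterozygosity(hapset: HaplotypeSet) -> float:
    """Alternative per-marker heterozygosity of the reconstruction: the
    mean, over markers, of the fraction of samples whose two haplotypes
    carry different alleles there."""
    arr1 = np.array([p[0] for p in hapset.pairs])
    arr2 = np.array([p[1] for p in hapset.pairs])
    return float((arr1 != arr2).mean())


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeAssoc:
    haplotype: str
    frequency: float
    n_class0: int
    n_class1: int
    chi2: float
    p: float


def haplotype_assoc(
    hapset: HaplotypeSet,
    phenotype: pd.Series,
    freq_min: float = 0.05,
    copies: bool = False,
) -> list[HaplotypeAssoc]:
    """Chi-square trait test per frequent haplotype.

    For each haplotype with frequency > ``freq_min``: count carriers
    (samples with >= 1 copy; with ``copies=True`` count haplotype copies
    instead) in each phenotype class and test the two counts against an
    equal split with a 1-df goodness-of-fit chi-square (no Yates
    correction).  Samples without a phenotype are ignored.
    """
    phen = phenotype.dropna().astype(int)
    out: list[HaplotypeAssoc] = []
    for hap, freq in hapset.frequencies.items():
        if freq <= freq_min:
            continue
        counts = [0, 0]
        for sid, (a, b) in zip(hapset.sample_ids, hapset.pairs):
            if sid not in phen.index:
                continue
            n_copies = (a == hap) + (b == hap)
            if n_copies == 0:
                continue
            counts[phen[sid]] += n_copies if copies else 1
        total = counts[0] + counts[1]
        if total == 0:
            log.info("haplotype %s has no phenotyped carriers; skipped", hap_to_string(hap))
            continue
        expected = total / 2.0
        chi2 = sum((c - expected) ** 2 / expected for c in counts)
        p = float(stats.chi2.sf(chi2, df=1))
        out.append(
            HaplotypeAssoc(
                haplotype=hap_to_string(hap),
                frequency=float(freq),
                n_class0=counts[0],
                n_class1=counts[1],
                chi2=float(chi2),
                p=p,
            )
        )
    return out
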