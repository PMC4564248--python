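"""Clone-group detection and sport-mutation localization.

Germplasm collections carry many duplicated genotypes: replicates,
synonyms, and sports (somatic mutants of a cultivar, propagated by
grafting).  Pairs of accessions sharing more than a threshold fraction of
identical genotype calls (default 98%) are linked, and connected
components of that graph form clone groups; one representative per group
is retained for population-level analyses.

Sports differ from their parent cultivar in a localized chromosomal
region, with a characteristic signature: the derived accession shows an
excess of missing calls in the region, and the calls that do differ are
heterozygous in the complete accession but homozygous in the one with the
missing data — consistent with a hemizygous deletion or rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .calls import HET, NO_CALL, GenotypeMatrix, MarkerInfo


def pairwise_identity(
    panel: GenotypeMatrix, min_overlap: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of co-called markers with identical genotype, per sample pair.

    Returns ``(identity, n_overlap)``; pairs with fewer than ``min_overlap``
    co-called markers get identity NaN (incomparable).  The diagonal is 1.
    """
    calls = panel.calls
    called = calls != NO_CALL
    n = panel.n_samples
    identity = np.full((n, n), np.nan)
    overlap = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(identity, 1.0)
    np.fill_diagonal(overlap, called.sum(axis=1))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        same = (calls[i] == calls[i + 1 :]) & both
        n_both = both.sum(axis=1)
        n_same = same.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(n_both >= min_overlap, n_same / np.maximum(n_both, 1), np.nan)
        identity[i, i + 1 :] = ident
        identity[i + 1 :, i] = ident
        overlap[i, i + 1 :] = n_both
        overlap[i + 1 :, i] = n_both
    return identity, overlap


@dataclass
class CloneGroup:
    members: list[str]
    representative: str
    min_identity: float


def group_clones(
    panel: GenotypeMatrix,
    identity: np.ndarray,
    threshold: float = 0.98,
) -> tuple[list[CloneGroup], GenotypeMatrix, list[str]]:
    """Single-linkage clone groups at the identity threshold.

    Groups are connected components of the graph with an edge wherever
    identity >= threshold; the representative kept in the deduplicated
    panel is the member with the highest call rate (ties broken by
    lexicographic id).  Returns (groups of size >= 2, deduplicated panel,
    removed sample ids).
    """
    ids = panel.sample_ids
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    pairs = np.argwhere(np.triu(identity >= threshold, k=1))
    g.add_edges_from(map(tuple, pairs))
    call_rates = panel.sample_call_rates()

    groups: list[CloneGroup] = []
    removed: list[str] = []
    keep: set[str] = set()
    for comp in nx.connected_components(g):
        members = sorted(ids[i] for i in comp)
        if len(members) == 1:
            keep.add(members[0])
            continue
        # representative: highest call rate, ties -> lexicographically smallest id
        best_rate = max(call_rates[m] for m in members)
        rep = min(m for m in members if call_rates[m] == best_rate)
        idx = [panel.sample_index(m) for m in members]
        sub = identity[np.ix_(idx, idx)]
        off = sub[np.triu_indices(len(idx), k=1)]
        groups.append(CloneGroup(members, rep, float(np.nanmin(off))))
        keep.add(rep)
        removed.extend(m for m in members if m != rep)
    dedup = panel.subset(samples=[s for s in ids if s in keep])
    return groups, dedup, sorted(removed)


def group_size_histogram(groups: list[CloneGroup]) -> pd.Series:
    sizes = pd.Series([len(g.members) for g in groups], dtype=int)
    return sizes.value_counts().sort_index()


@dataclass
class SportRegion:
    sample_low_missing: str  # the complete (parental-like) accession
    sample_high_missing: str  # the derived accession with missing data
    chrom: int
    start: int
    end: int
    n_differences: int
    n_excess_missing: int


def scan_sport_regions(
    panel: GenotypeMatrix,
    info: MarkerInfo,
    pair: tuple[str, str],
    window: int = 25,
    min_diff: int = 3,
    min_missing_frac: float = 0.2,
    min_direction_frac: float = 0.8,
) -> list[SportRegion]:
    """Locate candidate sport-mutation regions between two clone-like samples.

    Slides a window of ``window`` consecutive markers along each chromosome
    and flags windows where (a) at least ``min_diff`` co-called genotypes
    differ, (b) one member's no-call fraction exceeds the other's by at
    least ``min_missing_frac``, and (c) at least ``min_direction_frac`` of
    the differing loci are heterozygous in the low-missing member and
    homozygous in the high-missing member.  Overlapping flagged windows are
    merged into regions.
    """
    ia = panel.sample_index(pair[0])
    ib = panel.sample_index(pair[1])
    tab = info.table.reindex(panel.marker_ids)
    regions: list[SportRegion] = []
    for chrom, sub in tab.groupby("chrom", sort=True):
        order = sub.sort_values("pos")
        idx = np.array([panel.marker_index(m) for m in order.index])
        pos = order["pos"].to_numpy()
        a = panel.calls[ia, idx]
        b = panel.calls[ib, idx]
        m = len(idx)
        if m < window:
            spans = [(0, m)] if m else []
        else:
            spans = [(s, s + window) for s in range(0, m - window + 1)]
        flagged: list[tuple[int, int, int]] = []  # (lo, hi, direction)
        for lo, hi in spans:
            wa, wb = a[lo:hi], b[lo:hi]
            both = (wa != NO_CALL) & (wb != NO_CALL)
            diff = both & (wa != wb)
            n_diff = int(diff.sum())
            if n_diff < min_diff:
                continue
            miss_a = float((wa == NO_CALL).mean())
            miss_b = float((wb == NO_CALL).mean())
            if abs(miss_a - miss_b) < min_missing_frac:
                continue
            direction = 1 if miss_b > miss_a else -1  # 1: b is the derived sample
            low, high = (wa, wb) if direction == 1 else (wb, wa)
            het_to_hom = diff & (low == HET) & ((high == 0) | (high == 2))
            if het_to_hom.sum() / n_diff < min_direction_frac:
                continue
            flagged.append((lo, hi, direction))
        # merge overlapping windows with the same direction
        for direction in (1, -1):
            wins = [(lo, hi) for lo, hi, d in flagged if d == direction]
            if not wins:
                continue
            wins.sort()
            merged = [list(wins[0])]
            for lo, hi in wins[1:]:
                if lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            for lo, hi in merged:
                wa, wb = a[lo:hi], b[lo:hi]
                both = (wa != NO_CALL) & (wb != NO_CALL)
                n_diff = int((both & (wa != wb)).sum())
                n_excess = int(abs((wa == NO_CALL).sum() - (wb == NO_CALL).sum()))
                low_s, high_s = (pair[0], pair[1]) if direction == 1 else (pair[1], pair[0])
                regions.append(
                    SportRegion(
                        sample_low_missing=low_s,
                        sample_high_missing=high_s,
                        chrom=int(chrom),
                        start=int(pos[lo]),
                        end=int(pos[hi - 1]),
                        n_differences=n_diff,
                        n_excess_missing=n_excess,
                    )
                )
    return regions
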