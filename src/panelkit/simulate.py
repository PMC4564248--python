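"""Synthetic SNP-array genotype panels with planted truth.

The generator emulates the statistical structure of a large clonally
propagated fruit-tree germplasm panel genotyped on a ~9K SNP array:

* three ancestral populations diverged from a common allele-frequency
  pool under a Balding–Nichols model (per-population divergence F_div),
  plus admixed individuals with Dirichlet admixture vectors;
* block-structured LD, induced by drawing each individual's chromosomes
  block-wise from small per-population haplotype pools rather than from
  a recombination model — cheap and tunable, but explicitly not a
  population-genetic model of recombination history;
* excess homozygosity from partial selfing (per-population inbreeding);
* array artifacts in the proportions such arrays show: null-allele
  markers (low-intensity no-calls in part of the panel), duplicated-locus
  markers (collapsed paralogs showing heterozygote excess), failed and
  monomorphic markers;
* clone groups (near-identical copies) and sports — clone pairs differing
  only in a localized region with a missing-data + het→hom signature;
* binary Mendelian traits (dominant, recessive, or obligate-heterozygote)
  driven by planted causal loci.

Every planted feature is recorded in a :class:`SyntheticTruth` object so
the analysis modules can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calls import HET, HOM_A, HOM_B, NO_CALL, GenotypeMatrix, MarkerInfo, PanelError, PhenotypeTable

#: chromosome length shares of a compact ~230 Mbp fruit-tree genome
_CHROM_SHARES = np.array([48, 27, 22, 26, 18, 30, 22, 21], dtype=float)


@dataclass
class TraitSpec:
    name: str
    mode: str  # "recessive" | "dominant" | "obligate_het"
    causal_marker: str | None = None  # chosen by the simulator if None
    penetrance: float = 1.0
    misclassification: float = 0.02
    maf_range: tuple[float, float] = (0.25, 0.5)


@dataclass
class SportSpec:
    chrom: int = 6
    start: int = 1
    length: int = 5_400_000
    missing_rate: float = 0.4
    het_to_hom_rate: float = 0.8


@dataclass
class SimConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    k_true: int = 3
    pop_sizes: tuple[int, ...] = (60, 40, 25)
    n_admixed: int = 75
    f_div: tuple[float, ...] = (0.15, 0.15, 0.18)
    selfing: tuple[float, ...] = (0.3, 0.6, 0.3)
    admix_alpha: float = 0.3
    n_chromosomes: int = 8
    total_bp: int = 230_000_000
    n_markers: int = 2000
    block_markers_mean: float = 8.0
    pool_size: int = 8
    # artifact rates = fraction of markers per planted class (remainder A)
    rate_null_allele: float = 0.028
    rate_duplicated: float = 0.095
    rate_false: float = 0.095
    rate_failed: float = 0.25
    clone_group_sizes: tuple[int, ...] = (3, 2, 2)
    clone_noise: float = 0.005
    sports: tuple[SportSpec, ...] = (SportSpec(),)
    traits: tuple[TraitSpec, ...] = (
        TraitSpec("glabrous_fruit", "recessive"),
        TraitSpec("yellow_flesh", "recessive"),
        # rare dominant allele in obligate heterozygosity: carriers are
        # heterozygous, the causal allele stays at low frequency
        TraitSpec("flat_fruit", "obligate_het", maf_range=(0.08, 0.2)),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise PanelError("k_true must be >= 1")
        if len(self.pop_sizes) != self.k_true or len(self.f_div) != self.k_true:
            raise PanelError("pop_sizes and f_div must have k_true entries")
        for r in (
            self.rate_null_allele,
            self.rate_duplicated,
            self.rate_false,
            self.rate_failed,
            self.clone_noise,
            self.admix_alpha,
            *self.f_div,
            *self.selfing,
        ):
            if r < 0 or (r > 1 and r != self.admix_alpha):
                raise PanelError(f"rate out of [0,1]: {r}")
        n_cloned = sum(self.clone_group_sizes)
        if n_cloned > sum(self.pop_sizes) + self.n_admixed:
            raise PanelError("more clone copies than samples")

    def chromosome_lengths(self) -> np.ndarray:
        shares = _CHROM_SHARES[: self.n_chromosomes]
        if self.n_chromosomes > len(_CHROM_SHARES):
            shares = np.ones(self.n_chromosomes)
        return np.round(shares / shares.sum() * self.total_bp).astype(np.int64)


@dataclass
class SyntheticTruth:
    q: pd.DataFrame  # true admixture per sample (K columns)
    pop_labels: pd.Series  # "POP1".."POPK" or "ADM"
    marker_class: pd.Series  # planted class A-E per marker
    clone_groups: list[list[str]] = field(default_factory=list)
    sport_regions: list[dict] = field(default_factory=list)
    causal_markers: dict[str, str] = field(default_factory=dict)
    trait_modes: dict[str, str] = field(default_factory=dict)


def _make_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = config.chromosome_lengths()
    counts = np.round(lengths / lengths.sum() * config.n_markers).astype(int)
    counts[-1] += config.n_markers - counts.sum()
    rows = []
    i = 0
    for c, (ln, ct) in enumerate(zip(lengths, counts), start=1):
        pos = np.sort(rng.choice(np.arange(1, ln + 1), size=ct, replace=False))
        for p in pos:
            rows.append({"marker": f"M{i:05d}", "chrom": c, "pos": int(p)})
            i += 1
    return pd.DataFrame(rows).set_index("marker")


def _blocks(chrom_sizes: list[int], mean_len: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition each chromosome's marker indices into consecutive blocks
    with geometric lengths."""
    blocks = []
    offset = 0
    for n in chrom_sizes:
        j = 0
        while j < n:
            ln = int(rng.geometric(1.0 / mean_len))
            ln = max(1, min(ln, n - j))
            blocks.append(np.arange(offset + j, offset + j + ln))
            j += ln
        offset += n
    return blocks


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, MarkerInfo, SyntheticTruth]:
    """Simulate the base panel (no artifacts, clones or traits yet).

    Ancestral allele frequencies are Uniform(0.05, 0.95); population
    frequencies are Balding–Nichols draws
    Beta(p(1−F)/F, (1−p)(1−F)/F); LD comes from per-population,
    per-block haplotype pools of ``pool_size`` haplotypes; admixed
    individuals draw each block's ancestry from their Dirichlet admixture
    vector; partial selfing duplicates gamete blocks to create excess
    homozygosity.
    """
    rng = np.random.default_rng(config.seed)
    mapdf = _make_map(config, rng)
    m = config.n_markers
    k = config.k_true

    p_anc = rng.uniform(0.05, 0.95, size=m)
    p_pop = np.empty((k, m))
    for j in range(k):
        f = config.f_div[j]
        if f <= 0:
            p_pop[j] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_pop[j] = rng.beta(a, b)

    chrom_sizes = mapdf.groupby("chrom").size().sort_index().tolist()
    blocks = _blocks(chrom_sizes, config.block_markers_mean, rng)
    # Per-pop per-block haplotype pools; LD comes from the limited pool
    # size.  Pool allele counts are stochastically rounded to match the
    # population frequency (rather than Bernoulli-sampled), so the pools
    # add block structure without adding extra drift on top of the
    # Balding-Nichols divergence.
    h = config.pool_size

    def make_pool(j: int, bl: np.ndarray) -> np.ndarray:
        target = h * p_pop[j, bl]
        counts = np.floor(target + 0.5).astype(int)
        ranks = rng.random((h, len(bl))).argsort(axis=0)
        return ranks < counts

    pools = [[make_pool(j, bl) for bl in blocks] for j in range(k)]
    # a marker whose pools fixed for the same allele in every population
    # would be monomorphic panel-wide; redraw one population's pool column
    # (the one with the least extreme frequency) until it segregates
    for b, bl in enumerate(blocks):
        col_sum = sum(pools[j][b].sum(axis=0) for j in range(k))
        fixed = (col_sum == 0) | (col_sum == k * config.pool_size)
        for t in np.nonzero(fixed)[0]:
            m_idx = bl[t]
            j = int(np.argmin(np.abs(p_pop[:, m_idx] - 0.5)))
            p = min(max(p_pop[j, m_idx], 0.05), 0.95)
            for _ in range(100):
                draw = rng.random(config.pool_size) < p
                if 0 < draw.sum() < config.pool_size:
                    pools[j][b][:, t] = draw
                    break

    n_pure = sum(config.pop_sizes)
    n = n_pure + config.n_admixed
    q_true = np.zeros((n, k))
    labels = []
    i = 0
    for j, sz in enumerate(config.pop_sizes):
        q_true[i : i + sz, j] = 1.0
        labels += [f"POP{j+1}"] * sz
        i += sz
    if config.n_admixed:
        q_true[i:] = rng.dirichlet(np.full(k, config.admix_alpha), size=config.n_admixed)
        labels += ["ADM"] * config.n_admixed

    selfing = np.array(config.selfing)
    sample_selfing = q_true @ selfing

    geno = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        g1 = np.empty(m, dtype=np.int8)
        g2 = np.empty(m, dtype=np.int8)
        anc1 = rng.choice(k, size=len(blocks), p=q_true[i])
        anc2 = rng.choice(k, size=len(blocks), p=q_true[i])
        pick1 = rng.integers(config.pool_size, size=len(blocks))
        pick2 = rng.integers(config.pool_size, size=len(blocks))
        clone_block = rng.random(len(blocks)) < sample_selfing[i]
        for b, bl in enumerate(blocks):
            g1[bl] = pools[anc1[b]][b][pick1[b]]
            if clone_block[b]:
                g2[bl] = g1[bl]
            else:
                g2[bl] = pools[anc2[b]][b][pick2[b]]
        geno[i] = g1 + g2

    sample_ids = [f"S{i:04d}" for i in range(n)]
    panel = GenotypeMatrix(sample_ids, list(mapdf.index), geno)

    info_tab = mapdf.copy()
    info_tab["gentrain"] = rng.uniform(0.5, 0.95, size=m)
    info_tab["gencall10"] = rng.uniform(0.3, 0.9, size=m)
    info = MarkerInfo(info_tab, low_intensity=np.zeros((n, m), dtype=bool))

    truth = SyntheticTruth(
        q=pd.DataFrame(q_true, index=sample_ids, columns=[f"POP{j+1}" for j in range(k)]),
        pop_labels=pd.Series(labels, index=sample_ids),
        marker_class=pd.Series("A", index=mapdf.index),
    )
    return panel, info, truth


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _choose_causal(
    panel: GenotypeMatrix,
    spec: TraitSpec,
    rng: np.random.Generator,
    used: set[str],
    allowed: set[str] | None = None,
) -> str:
    calls = panel.calls
    with np.errstate(invalid="ignore"):
        g = calls.astype(float)
        g[g == NO_CALL] = np.nan
        p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    het = (calls == HET).mean(axis=0)
    lo, hi = spec.maf_range
    ok = (maf >= lo) & (maf <= hi)
    if spec.mode == "obligate_het":
        minor_hom_frac = np.minimum(
            (calls == HOM_A).mean(axis=0), (calls == HOM_B).mean(axis=0)
        )
        ok &= (het >= 0.1) & (minor_hom_frac <= 0.05)
    cand = [
        mid
        for mid, o in zip(panel.marker_ids, ok)
        if o and mid not in used and (allowed is None or mid in allowed)
    ]
    if not cand:
        raise PanelError(f"no eligible causal marker for trait {spec.name!r}")
    return cand[int(rng.integers(len(cand)))]


def simulate_traits(
    panel: GenotypeMatrix,
    truth: SyntheticTruth,
    trait_specs: tuple[TraitSpec, ...],
    seed: int = 0,
) -> PhenotypeTable:
    """Binary Mendelian phenotypes from planted causal loci.

    Recessive: phenotype 1 iff homozygous for the minor allele at the
    causal marker; dominant: 1 iff carrying the minor allele;
    obligate-heterozygote: 1 iff heterozygous.  Penetrance and a symmetric
    misclassification rate are applied on top; no-call at the causal
    marker leaves the sample unphenotyped.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    used: set[str] = set(truth.causal_markers.values())
    # causal loci must sit on clean (planted class A) markers so that the
    # association scan can see them after QC
    allowed = set(truth.marker_class.index[truth.marker_class == "A"])
    for spec in trait_specs:
        marker = spec.causal_marker or _choose_causal(panel, spec, rng, used, allowed)
        used.add(marker)
        jj = panel.marker_index(marker)
        col = panel.calls[:, jj].astype(float)
        called = col != NO_CALL
        if len(np.unique(col[called])) < 2:
            raise PanelError(f"causal marker {marker!r} is monomorphic")
        g = col.copy()
        p_b = np.nanmean(np.where(called, g, np.nan)) / 2.0
        minor_hom = HOM_B if p_b <= 0.5 else HOM_A
        if spec.mode == "recessive":
            pheno = (col == minor_hom).astype(float)
        elif spec.mode == "dominant":
            pheno = ((col == minor_hom) | (col == HET)).astype(float)
        elif spec.mode == "obligate_het":
            pheno = (col == HET).astype(float)
        else:
            raise PanelError(f"unknown trait mode {spec.mode!r}")
        expressed = rng.random(len(pheno)) < spec.penetrance
        pheno = np.where(expressed, pheno, 0.0)
        flip = rng.random(len(pheno)) < spec.misclassification
        pheno = np.where(flip, 1.0 - pheno, pheno)
        pheno[~called] = np.nan
        cols[spec.name] = pheno
        truth.causal_markers[spec.name] = marker
        truth.trait_modes[spec.name] = spec.mode
    return PhenotypeTable(pd.DataFrame(cols, index=panel.sample_ids))


# ---------------------------------------------------------------------------
# artifacts, clones and sports
# ---------------------------------------------------------------------------


def inject_artifacts(
    panel: GenotypeMatrix,
    info: MarkerInfo,
    truth: SyntheticTruth,
    config: SimConfig,
) -> tuple[GenotypeMatrix, MarkerInfo, SyntheticTruth]:
    """Plant array artifacts, clone groups and sport regions.

    Marker artifacts (disjoint marker sets, planted class recorded):

    * null allele (class B): 5–50% of samples get a low-intensity flag and
      a no-call; the rest keep >= 2 genotype classes;
    * duplicated locus (class C): the minor homozygote class is collapsed
      into heterozygotes and a share of major homozygotes follows,
      emulating superimposed paralogous signals;
    * false marker (class D): forced monomorphic, calls left otherwise;
    * failed marker (class E): > 50% no-call and/or sub-threshold
      GenTrain / GenCall-10% scores.

    Clone groups copy existing samples with small random genotyping noise;
    sport regions then modify one member of a clone pair inside a
    configured window (het calls become homozygous, a share of calls go
    missing).
    """
    rng = np.random.default_rng(config.seed + 1)
    calls = panel.calls.copy()
    n, m = calls.shape
    tab = info.table.copy()
    low = (
        info.low_intensity.copy()
        if info.low_intensity is not None
        else np.zeros((n, m), dtype=bool)
    )
    classes = truth.marker_class.copy()

    g = calls.astype(float)
    g[g == NO_CALL] = np.nan
    with np.errstate(invalid="ignore"):
        p_b = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p_b, 1 - p_b)

    n_b = int(round(config.rate_null_allele * m))
    n_c = int(round(config.rate_duplicated * m))
    n_d = int(round(config.rate_false * m))
    n_e = int(round(config.rate_failed * m))

    taken = np.zeros(m, dtype=bool)

    def draw(count: int, eligible: np.ndarray) -> np.ndarray:
        pool = np.nonzero(eligible & ~taken)[0]
        if len(pool) < count:
            raise PanelError("not enough eligible markers for requested artifact rates")
        sel = rng.choice(pool, size=count, replace=False)
        taken[sel] = True
        return sel

    idx_b = draw(n_b, maf >= 0.1)
    idx_c = draw(n_c, maf >= 0.2)
    idx_d = draw(n_d, np.ones(m, dtype=bool))
    idx_e = draw(n_e, np.ones(m, dtype=bool))

    for j in idx_b:
        frac = rng.uniform(0.08, 0.45)
        hit = rng.random(n) < frac
        low[hit, j] = True
        calls[hit, j] = NO_CALL
        classes.iloc[j] = "B"

    for j in idx_c:
        col = calls[:, j]
        minor_hom = HOM_B if p_b[j] <= 0.5 else HOM_A
        major_hom = HOM_A if minor_hom == HOM_B else HOM_B
        col[col == minor_hom] = HET
        maj = np.nonzero(col == major_hom)[0]
        conv = maj[rng.random(len(maj)) < 0.6]
        col[conv] = HET
        classes.iloc[j] = "C"

    for j in idx_d:
        col = calls[:, j]
        major_hom = HOM_A if p_b[j] <= 0.5 else HOM_B
        col[col != NO_CALL] = major_hom
        classes.iloc[j] = "D"

    for j in idx_e:
        mode = rng.integers(3)
        if mode == 0:
            hit = rng.random(n) < rng.uniform(0.55, 0.9)
            calls[hit, j] = NO_CALL
        elif mode == 1:
            tab.iloc[j, tab.columns.get_loc("gentrain")] = rng.uniform(0.05, 0.39)
        else:
            tab.iloc[j, tab.columns.get_loc("gencall10")] = rng.uniform(0.01, 0.19)
        classes.iloc[j] = "E"

    # clone groups ---------------------------------------------------------
    sample_ids = list(panel.sample_ids)
    new_rows = [calls]
    new_low = [low]
    clone_groups: list[list[str]] = []
    # groups that will carry a sport need a parent with heterozygous calls
    # inside the sport region, or there is no het->hom signal to plant
    pos_arr = tab["pos"].to_numpy()
    chrom_arr = tab["chrom"].to_numpy()
    originals = []
    available = np.ones(n, dtype=bool)
    for gi in range(len(config.clone_group_sizes)):
        if gi < len(config.sports):
            spec = config.sports[gi]
            region = (
                (chrom_arr == spec.chrom)
                & (pos_arr >= spec.start)
                & (pos_arr < spec.start + spec.length)
            )
            het_counts = (calls[:, region] == HET).sum(axis=1)
            cand = np.nonzero(available & (het_counts >= max(8, int(0.25 * region.sum()))))[0]
            if len(cand) == 0:
                cand = np.nonzero(available)[0][np.argsort(-het_counts[available])][:5]
        else:
            cand = np.nonzero(available)[0]
        pick = int(cand[rng.integers(len(cand))])
        originals.append(pick)
        available[pick] = False
    for gi, (orig_idx, size) in enumerate(zip(originals, config.clone_group_sizes)):
        members = [sample_ids[orig_idx]]
        for ci in range(size - 1):
            row = calls[orig_idx].copy()
            noisy = rng.random(m) < config.clone_noise
            for j in np.nonzero(noisy)[0]:
                choices = [c for c in (HOM_A, HET, HOM_B, NO_CALL) if c != row[j]]
                row[j] = choices[rng.integers(3)]
            cid = f"{sample_ids[orig_idx]}_clone{ci+1}"
            members.append(cid)
            sample_ids.append(cid)
            new_rows.append(row[None, :])
            new_low.append(low[orig_idx][None, :])
        clone_groups.append(members)
    calls = np.vstack(new_rows)
    low = np.vstack(new_low)

    # sports ---------------------------------------------------------------
    sport_regions: list[dict] = []
    pos = tab["pos"].to_numpy()
    chrom = tab["chrom"].to_numpy()
    for si, spec in enumerate(config.sports):
        if si >= len(clone_groups):
            break
        parent, derived = clone_groups[si][0], clone_groups[si][1]
        di = sample_ids.index(derived)
        in_region = (
            (chrom == spec.chrom)
            & (pos >= spec.start)
            & (pos < spec.start + spec.length)
        )
        region_idx = np.nonzero(in_region)[0]
        het_idx = region_idx[calls[di, region_idx] == HET]
        conv = het_idx[rng.random(len(het_idx)) < spec.het_to_hom_rate]
        for j in conv:
            calls[di, j] = HOM_A if rng.random() < 0.5 else HOM_B
        missable = np.setdiff1d(region_idx, conv)
        miss = missable[rng.random(len(missable)) < spec.missing_rate]
        calls[di, miss] = NO_CALL
        sport_regions.append(
            {
                "parent": parent,
                "derived": derived,
                "chrom": spec.chrom,
                "start": int(spec.start),
                "end": int(spec.start + spec.length - 1),
                "n_converted": int(len(conv)),
                "n_missing": int(len(miss)),
            }
        )

    out_panel = GenotypeMatrix(sample_ids, panel.marker_ids, calls)
    out_info = MarkerInfo(tab, low_intensity=low)
    # extend truth to the clone copies
    q = truth.q.reindex(sample_ids)
    labels = truth.pop_labels.reindex(sample_ids)
    for group in clone_groups:
        for member in group[1:]:
            q.loc[member] = q.loc[group[0]]
            labels.loc[member] = labels.loc[group[0]]
    new_truth = SyntheticTruth(
        q=q,
        pop_labels=labels,
        marker_class=classes,
        clone_groups=clone_groups,
        sport_regions=sport_regions,
        causal_markers=dict(truth.causal_markers),
        trait_modes=dict(truth.trait_modes),
    )
    return out_panel, out_info, new_truth


def simulate_study(
    config: SimConfig | None = None,
) -> tuple[GenotypeMatrix, MarkerInfo, PhenotypeTable, SyntheticTruth]:
    """Full pipeline input: panel + artifacts/clones/sports + traits."""
    config = config or SimConfig()
    panel, info, truth = simulate_panel(config)
    panel, info, truth = inject_artifacts(panel, info, truth, config)
    phenotypes = simulate_traits(panel, truth, config.traits, seed=config.seed + 2)
    return panel, info, phenotypes, truth
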