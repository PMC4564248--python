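"""Reading and writing of panel formats: TSV genotype matrices, VCF
(GT field only), PLINK-style ped/map text, phenotype TSVs, marker
metadata, Newick trees and the JSON run manifest.

Coordinates are 1-based inclusive bp internally (VCF-native); BED-style
exports are half-open 0-based.  Array alleles A/B map to VCF REF/ALT per
marker; downstream statistics are invariant to that labeling.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import (
    CALL_TO_STR,
    HET,
    HOM_A,
    HOM_B,
    NO_CALL,
    STR_TO_CALL,
    GenotypeMatrix,
    MarkerInfo,
    PanelError,
    PhenotypeTable,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TSV genotype matrix
# ---------------------------------------------------------------------------


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a samples x markers TSV of AA/AB/BB/NC cells.

    First column holds sample ids, header row holds marker ids.  Accepted
    no-call spellings: NC, --, ./., ., empty cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    calls = np.empty(df.shape, dtype=np.int8)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, cell in enumerate(row):
            cell = cell.strip().upper() if cell else ""
            if cell not in STR_TO_CALL:
                raise PanelError(
                    f"{path}: unrecognized genotype {cell!r} at line {i + 2}, column {j + 2}"
                )
            calls[i, j] = STR_TO_CALL[cell]
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def write_genotype_tsv(panel: GenotypeMatrix, path: str | Path) -> None:
    strs = np.vectorize(CALL_TO_STR.get)(panel.calls)
    pd.DataFrame(strs, index=panel.sample_ids, columns=panel.marker_ids).to_csv(
        path, sep="\t", index_label="sample"
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame, list[str]]:
    """Read biallelic GT calls from a VCF.

    REF maps to array allele A and ALT to B.  Multi-allelic records are
    skipped and reported.  Returns (panel, map table, skipped ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows = []
    cols = []
    skipped: list[str] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        if len(var.ALT) != 1:
            skipped.append(vid)
            continue
        if vid in set(marker_ids):
            raise PanelError(f"{path}: duplicated marker id {vid!r}")
        gt = var.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = NO_CALL
        cols.append(gt)
        marker_ids.append(vid)
        try:
            chrom = int(str(var.CHROM).removeprefix("chr").removeprefix("scaffold_"))
        except ValueError:
            chrom = -1
        rows.append({"marker": vid, "chrom": chrom, "pos": var.POS})
    if skipped:
        log.warning("%s: skipped %d multi-allelic records", path, len(skipped))
    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    mapdf = pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame()
    return GenotypeMatrix(samples, marker_ids, calls), mapdf, skipped


_GT = {HOM_A: "0/0", HET: "0/1", HOM_B: "1/1", NO_CALL: "./."}


def write_vcf(panel: GenotypeMatrix, info: MarkerInfo, path: str | Path) -> None:
    """Write the panel as a minimal VCF (GT only, A->REF=A, B->ALT=T)."""
    tab = info.table.reindex(panel.marker_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(tab["chrom"].unique()):
            fh.write(f"##contig=<ID={int(c)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        order = tab.sort_values(["chrom", "pos"]).index
        for mid in order:
            j = panel.marker_index(mid)
            row = tab.loc[mid]
            gts = "\t".join(_GT[int(c)] for c in panel.calls[:, j])
            fh.write(f"{int(row['chrom'])}\t{int(row['pos'])}\t{mid}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK-style text ped/map
# ---------------------------------------------------------------------------

_PED_ALLELES = {HOM_A: ("A", "A"), HET: ("A", "B"), HOM_B: ("B", "B"), NO_CALL: ("0", "0")}


def write_pedmap(panel: GenotypeMatrix, info: MarkerInfo, prefix: str | Path) -> None:
    prefix = Path(prefix)
    tab = info.table.reindex(panel.marker_ids)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for mid in panel.marker_ids:
            row = tab.loc[mid]
            fh.write(f"{int(row['chrom'])}\t{mid}\t0\t{int(row['pos'])}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            alleles = []
            for c in panel.calls[i]:
                alleles.extend(_PED_ALLELES[int(c)])
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\t" + "\t".join(alleles) + "\n")


def read_pedmap(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    prefix = Path(prefix)
    mapdf = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        names=["chrom", "marker", "cm", "pos"],
        dtype={"marker": str},
    ).set_index("marker")
    marker_ids = list(mapdf.index)
    sample_ids: list[str] = []
    rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(marker_ids):
                raise PanelError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * len(marker_ids)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            alleles = parts[6:]
            row = np.empty(len(marker_ids), dtype=np.int8)
            for j in range(len(marker_ids)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    row[j] = NO_CALL
                else:
                    row[j] = (a == "B") + (b == "B")
            rows.append(row)
    return GenotypeMatrix(sample_ids, marker_ids, np.vstack(rows)), mapdf


# ---------------------------------------------------------------------------
# marker metadata and phenotypes
# ---------------------------------------------------------------------------


def read_marker_info(path: str | Path) -> MarkerInfo:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return MarkerInfo(tab)


def write_marker_info(info: MarkerInfo, path: str | Path) -> None:
    info.table.to_csv(path, sep="\t", index_label="marker")


def read_phenotypes(path: str | Path, panel: GenotypeMatrix | None = None) -> PhenotypeTable:
    """Read a sample x trait TSV of binary codes (blank = missing).

    Non-binary values raise with the offending rows listed; samples
    unknown to the panel (when given) are reported and kept.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad_rows = []
    for trait in df.columns:
        vals = pd.to_numeric(df[trait], errors="coerce")
        bad = df[trait].notna() & vals.isna()
        bad |= vals.notna() & ~vals.isin([0, 1])
        bad_rows += [(s, trait, df.loc[s, trait]) for s in df.index[bad]]
        df[trait] = vals
    if bad_rows:
        raise PanelError(f"{path}: non-binary phenotype values: {bad_rows[:10]}")
    if panel is not None:
        unknown = [s for s in df.index if s not in set(panel.sample_ids)]
        if unknown:
            log.warning("%s: %d phenotyped samples not in the panel", path, len(unknown))
    return PhenotypeTable(df)


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.table.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# results and manifest
# ---------------------------------------------------------------------------


def write_manifest(path: str | Path, config: dict, seed: int | None) -> None:
    """JSON run manifest recording the configuration and RNG seed so any
    stochastic stage can be rerun bit-identically."""
    payload = {"seed": seed, "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def write_blocks_bed(blocks, path: str | Path) -> None:
    """High-LD blocks as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\tn={b.n_markers};median_r2={b.median_r2:.4f}\n")


def write_regions_bed(regions, path: str | Path) -> None:
    """Sport regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.sample_low_missing}|{r.sample_high_missing};diffs={r.n_differences}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")
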