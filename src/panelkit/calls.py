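"""Core containers for biallelic SNP-array genotype panels.

Genotype calls are stored as a dense ``int8`` matrix (samples x markers)
with the four call states produced by array genotyping software:

* ``HOM_A``  (0) — homozygous for array allele A
* ``HET``    (1) — heterozygous AB
* ``HOM_B``  (2) — homozygous for array allele B
* ``NO_CALL`` (-1) — failed / missing call

The A/B labels are arbitrary per marker (they map to array probe alleles,
not to major/minor); all downstream statistics are invariant to swapping
them, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NO_CALL: int = -1
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2

CALL_TO_STR = {HOM_A: "AA", HET: "AB", HOM_B: "BB", NO_CALL: "NC"}

#: accepted spellings on input (TSV cells, ped alleles, etc.)
STR_TO_CALL = {
    "AA": HOM_A,
    "AB": HET,
    "BA": HET,
    "BB": HOM_B,
    "NC": NO_CALL,
    "--": NO_CALL,
    "./.": NO_CALL,
    ".": NO_CALL,
    "": NO_CALL,
}


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel inputs."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise PanelError(f"duplicated {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Samples x markers grid of biallelic genotype calls.

    Parameters
    ----------
    sample_ids, marker_ids
        Unique string identifiers for rows and columns.
    calls
        ``int8`` array of shape ``(n_samples, n_markers)`` with values in
        ``{HOM_A, HET, HOM_B, NO_CALL}``.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise PanelError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        bad = ~np.isin(self.calls, (NO_CALL, HOM_A, HET, HOM_B))
        if bad.any():
            raise PanelError(f"invalid call values: {np.unique(self.calls[bad])}")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise PanelError(f"unknown sample id {sample_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise PanelError(f"unknown marker id {marker_id!r}") from None

    # -- derived quantities ----------------------------------------------
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != NO_CALL

    def sample_call_rates(self) -> pd.Series:
        return pd.Series(self.called().mean(axis=1), index=self.sample_ids)

    def marker_call_rates(self) -> pd.Series:
        return pd.Series(self.called().mean(axis=0), index=self.marker_ids)

    # -- subsetting -------------------------------------------------------
    def subset(
        self,
        samples: Iterable[str] | None = None,
        markers: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new panel restricted to the given ids (order preserved)."""
        si = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self.sample_index(s) for s in samples])
        )
        mi = (
            np.arange(self.n_markers)
            if markers is None
            else np.array([self.marker_index(m) for m in markers])
        )
        return GenotypeMatrix(
            [self.sample_ids[i] for i in si],
            [self.marker_ids[j] for j in mi],
            self.calls[np.ix_(si, mi)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), list(self.marker_ids), self.calls.copy())

    def swap_alleles(self, markers: Iterable[str]) -> "GenotypeMatrix":
        """Return a panel with the A/B labels exchanged at the given markers."""
        out = self.copy()
        for m in markers:
            j = self.marker_index(m)
            col = out.calls[:, j]
            called = col != NO_CALL
            col[called] = 2 - col[called]
        return out


@dataclass
class MarkerInfo:
    """Per-marker map position and array-quality metadata.

    ``table`` is indexed by marker id with columns ``chrom`` (int),
    ``pos`` (1-based bp) and optional ``gentrain`` / ``gencall10`` scores in
    [0, 1].  ``low_intensity`` is an optional samples x markers boolean
    matrix flagging calls whose normalized intensity R fell below 0.2 —
    the hallmark of a null allele / preferential annealing marker.
    """

    table: pd.DataFrame
    low_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "pos"}
        missing = required - set(self.table.columns)
        if missing:
            raise PanelError(f"MarkerInfo missing columns: {sorted(missing)}")
        if (self.table["pos"] < 0).any():
            raise PanelError("marker positions must be nonnegative")
        for col in ("gentrain", "gencall10"):
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise PanelError(f"{col} scores must lie in [0, 1]")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    def positions(self) -> pd.Series:
        return self.table["pos"]

    def chromosomes(self) -> pd.Series:
        return self.table["chrom"]

    def subset(self, markers: Sequence[str], panel: GenotypeMatrix | None = None) -> "MarkerInfo":
        cols = None
        low = None
        if self.low_intensity is not None and panel is not None:
            cols = [panel.marker_index(m) for m in markers]
        tab = self.table.loc[list(markers)].copy()
        if self.low_intensity is not None and cols is not None:
            low = self.low_intensity[:, cols].copy()
        return MarkerInfo(tab, low)


@dataclass
class PhenotypeTable:
    """Binary trait codes per sample.

    ``table`` is indexed by sample id; each column is one trait with values
    in {0, 1} or NaN for unphenotyped samples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            rows, cols = np.nonzero(~ok)
            examples = [
                (self.table.index[r], self.table.columns[c], vals[r, c])
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise PanelError(f"non-binary phenotype values: {examples}")

    @property
    def traits(self) -> list[str]:
        return list(self.table.columns)

    def trait(self, name: str) -> pd.Series:
        """Codes for one trait, restricted to phenotyped samples."""
        return self.table[name].dropna().astype(int)

    def n_phenotyped(self, name: str) -> int:
        return int(self.table[name].notna().sum())
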