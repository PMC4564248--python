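"""Panel bookkeeping: the small derived quantities a germplasm study
reports alongside the heavy analyses — class proportions, marker
densities, clone-removal arithmetic, admixed counts, the fixation index
from panel heterozygosities, multiple-testing cutoffs and physical-to-
genetic distance conversion."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import PanelError


def class_percentages(class_counts: pd.Series | dict) -> pd.Series:
    """Percentage of assayed markers in each QC class."""
    counts = pd.Series(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise PanelError("no markers counted")
    return 100.0 * counts / total


def percent_of_assayed(n: int, n_assayed: int) -> float:
    if n_assayed <= 0:
        raise PanelError("assayed count must be positive")
    return 100.0 * n / n_assayed


def marker_density_per_mb(n_markers: int, genome_mbp: float) -> float:
    """Average marker density in markers per Mbp."""
    return n_markers / genome_mbp


def marker_density_per_cm(n_markers: int, map_cm: float) -> float:
    """Average marker density in markers per cM of the reference map."""
    return n_markers / map_cm


def bp_to_cm(bp: float, genome_bp: float, map_cm: float) -> float:
    """Convert a physical distance to genetic distance assuming a uniform
    genome-wide ratio (map length over genome length)."""
    return bp * map_cm / genome_bp


def clones_removed(n_grouped_samples: int, n_groups: int) -> int:
    """Samples removed when each clone group keeps one representative."""
    if n_groups > n_grouped_samples:
        raise PanelError("more groups than grouped samples")
    return n_grouped_samples - n_groups


def unique_panel_size(n_genotyped: int, n_low_quality: int, n_clones_removed: int) -> int:
    return n_genotyped - n_low_quality - n_clones_removed


def admixed_count(n_unique: int, assigned_per_population: list[int] | tuple[int, ...]) -> int:
    """Samples not assigned to any single population at the q threshold."""
    return n_unique - int(sum(assigned_per_population))


def fixation_index_from_means(mean_ho: float, mean_he: float) -> float:
    """Panel fixation index F = (He − Ho)/He from mean heterozygosities."""
    if mean_he == 0:
        raise PanelError("mean expected heterozygosity is zero")
    return (mean_he - mean_ho) / mean_he


def bonferroni_neglog10(n_tests: int, alpha: float = 0.01) -> float:
    if n_tests < 1:
        raise PanelError("need at least one test")
    return float(-np.log10(alpha / n_tests))
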