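"""Tumor-vs-normal k-mer subtraction.

Raw per-sample counts are normalized to counts per 10^9 bp of sequencing
effort ("abundance").  For a conservative ratio, a k-mer missing from a
sample's thresholded catalog is imputed at the raw-count level before
normalization: 0 for tumor samples and the 10-count floor for normal
samples.  The per-tissue statistic is then

    ratio(kmer, tissue) = min over tumor samples of abundance
                          / max over that tissue's normal samples,

and a k-mer is "over-abundant" in a tissue when the ratio strictly
exceeds the threshold (default 500).  Imputation guarantees every
denominator is positive, so ratios are always finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import SampleCatalog, SampleMeta

__all__ = [
    "AbundanceTable",
    "TissueRatioProfile",
    "normalize_abundance",
    "build_abundance_table",
    "ratio_matrix",
    "tissue_ratio",
    "overabundance_profile",
    "filter_candidates",
    "truncate_ratio",
]


def normalize_abundance(count: float, total_bp: int) -> float:
    """Counts per billion bp: ``count * 1e9 / total_bp``."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e9 / total_bp


@dataclass
class AbundanceTable:
    """Normalized abundances for the union of cataloged k-mers.

    ``matrix`` is indexed by k-mer code with one column per sample id.
    Only k-mers present in at least one sample's catalog appear; values
    for samples missing a k-mer are the imputed-then-normalized floor.
    """

    samples: list[SampleMeta]
    matrix: pd.DataFrame
    k: int
    imputation_floor: int = 10

    @property
    def tumor_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.cohort == "tumor"]

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.cohort == "normal" and s.tissue not in seen:
                seen.append(s.tissue)
        return seen

    def tissue_sample_ids(self, tissue: str) -> list[str]:
        ids = [
            s.sample_id
            for s in self.samples
            if s.cohort == "normal" and s.tissue == tissue
        ]
        if not ids:
            raise KeyError(f"unknown tissue {tissue!r}")
        return ids


@dataclass
class TissueRatioProfile:
    """Per-tissue T:N ratios and over-abundance flags for one k-mer."""

    kmer: int
    ratios: dict[str, float]
    overabundant: dict[str, bool]
    threshold: float = 500.0
    tissue_count: int = 0

    def __post_init__(self) -> None:
        self.tissue_count = sum(self.overabundant.values())

    @property
    def min_ratio(self) -> float:
        return min(self.ratios.values()) if self.ratios else 0.0


def build_abundance_table(catalogs: Sequence[SampleCatalog]) -> AbundanceTable:
    """Union per-sample catalogs into a normalized abundance matrix.

    Missing entries are imputed as raw counts (0 for tumor, ``min_count``
    for normal) and every column is normalized by its sample's total bp.
    """
    if not catalogs:
        raise ValueError("no catalogs")
    ks = {c.k for c in catalogs}
    if len(ks) != 1:
        raise ValueError(f"catalogs mix word lengths: {sorted(ks)}")
    k = ks.pop()
    floors = {c.min_count for c in catalogs}
    if len(floors) != 1:
        raise ValueError(f"catalogs mix min_count thresholds: {sorted(floors)}")
    floor = floors.pop()
    ids = [c.meta.sample_id for c in catalogs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among catalogs")
    cohorts = {c.meta.cohort for c in catalogs}
    if cohorts != {"tumor", "normal"}:
        raise ValueError("need at least one tumor and one normal catalog")

    all_codes = np.unique(
        np.concatenate(
            [np.fromiter(c.counts.keys(), dtype=np.int64, count=len(c.counts))
             for c in catalogs if c.counts]
            or [np.empty(0, dtype=np.int64)]
        )
    )
    cols = {}
    for cat in catalogs:
        if cat.meta.total_bp <= 0:
            raise ValueError(f"sample {cat.meta.sample_id!r} has no total_bp")
        fill = 0.0 if cat.meta.cohort == "tumor" else float(floor)
        raw = np.full(all_codes.size, fill)
        if cat.counts:
            codes = np.fromiter(cat.counts.keys(), dtype=np.int64, count=len(cat.counts))
            vals = np.fromiter(cat.counts.values(), dtype=np.float64, count=len(cat.counts))
            pos = np.searchsorted(all_codes, codes)
            raw[pos] = vals
        cols[cat.meta.sample_id] = raw * 1e9 / cat.meta.total_bp
    matrix = pd.DataFrame(cols, index=all_codes)
    return AbundanceTable(
        samples=[c.meta for c in catalogs], matrix=matrix, k=k, imputation_floor=floor
    )


def ratio_matrix(table: AbundanceTable) -> pd.DataFrame:
    """T:N ratio of every k-mer in every tissue (rows x tissue columns)."""
    tumor_min = table.matrix[table.tumor_ids].min(axis=1)
    out = {}
    for tissue in table.tissues:
        normal_max = table.matrix[table.tissue_sample_ids(tissue)].max(axis=1)
        out[tissue] = tumor_min / normal_max
    return pd.DataFrame(out, index=table.matrix.index)


def tissue_ratio(kmer: int, table: AbundanceTable, tissue: str) -> float:
    """min-tumor over max-normal abundance ratio for one k-mer and tissue."""
    if kmer not in table.matrix.index:
        raise KeyError(f"k-mer code {kmer} not in table")
    row = table.matrix.loc[kmer]
    tmin = row[table.tumor_ids].min()
    nmax = row[table.tissue_sample_ids(tissue)].max()
    return float(tmin / nmax)


def overabundance_profile(
    kmer: int, table: AbundanceTable, threshold: float = 500.0
) -> TissueRatioProfile:
    """Per-tissue ratios and strict ``ratio > threshold`` flags for a k-mer."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ratios = {t: tissue_ratio(kmer, table, t) for t in table.tissues}
    flags = {t: r > threshold for t, r in ratios.items()}
    return TissueRatioProfile(kmer=kmer, ratios=ratios, overabundant=flags, threshold=threshold)


def filter_candidates(
    table: AbundanceTable, threshold: float = 500.0
) -> list[TissueRatioProfile]:
    """Keep k-mers over-abundant in at least one tissue.

    Output is sorted by flagged-tissue count descending, then k-mer code
    ascending, so it is invariant to sample ordering in the table.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rm = ratio_matrix(table)
    flags = rm > threshold
    counts = flags.sum(axis=1)
    keep = counts[counts > 0]
    profiles = []
    for code in keep.index:
        ratios = rm.loc[code].to_dict()
        profiles.append(
            TissueRatioProfile(
                kmer=int(code),
                ratios={t: float(v) for t, v in ratios.items()},
                overabundant={t: bool(v) for t, v in flags.loc[code].to_dict().items()},
                threshold=threshold,
            )
        )
    profiles.sort(key=lambda p: (-p.tissue_count, p.kmer))
    return profiles


def truncate_ratio(x: float, decimals: int = 2) -> float:
    """Truncate toward zero at ``decimals`` places (display convention).

    Full precision is kept in all files; this formatting helper exists
    because reports print ratios truncated, e.g. 0.16896... -> 0.16.
    """
    scale = 10**decimals
    return math.trunc(x * scale) / scale
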