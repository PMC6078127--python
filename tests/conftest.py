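import numpy as np
import pandas as pd
import pytest

import kmersub as ks
from kmersub.subtract import build_abundance_table, filter_candidates


def random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bases[rng.integers(0, 4, size=length)].tobytes().decode() for _ in range(n)]


def naive_kmer_tally(reads, k: int, min_count: int = 1) -> dict[str, int]:
    """Brute-force window tally oracle (independent of the package path)."""
    tally: dict[str, int] = {}
    for r in reads:
        for i in range(len(r) - k + 1):
            w = r[i : i + k].upper().replace("U", "T")
            if any(c not in "ACGT" for c in w):
                continue
            tally[w] = tally.get(w, 0) + 1
    return {w: n for w, n in tally.items() if n >= min_count}


def make_table(tumor_counts, normal_by_tissue, total_bp=10**9, kmers=(0,), floor=10):
    """Abundance table from explicit raw counts, one row per k-mer code.

    ``tumor_counts``: {sample: {kmer: count}}; ``normal_by_tissue``:
    {tissue: {sample: {kmer: count}}}.  Equal total_bp everywhere makes
    abundances numerically equal to raw counts.
    """
    catalogs = []
    for sid, counts in tumor_counts.items():
        meta = ks.SampleMeta(sid, "tumor", "", total_bp)
        catalogs.append(ks.SampleCatalog(meta, dict(counts), k=25, min_count=floor))
    for tissue, samples in normal_by_tissue.items():
        for sid, counts in samples.items():
            meta = ks.SampleMeta(sid, "normal", tissue, total_bp)
            catalogs.append(ks.SampleCatalog(meta, dict(counts), k=25, min_count=floor))
    return build_abundance_table(catalogs)


def run_subtraction(cohort: ks.SyntheticCohort, threshold: float = 500.0):
    """Count every sample, build the table, and filter candidates."""
    cfg = cohort.config
    catalogs = [
        ks.count_sample(cohort.reads[m.sample_id], m, k=25, min_count=10)
        for m in cohort.samples
    ]
    table = build_abundance_table(catalogs)
    return table, filter_candidates(table, threshold=threshold)


def mini_config(seed: int = 0, **overrides) -> ks.CohortConfig:
    """Very small cohort for structural/CLI tests (no ratio recovery)."""
    params = dict(
        n_tissues=3,
        n_shared_transcripts=6,
        normal_reads_per_sample=800,
        tumor_reads_per_sample=800,
    )
    params.update(overrides)
    return ks.toy_config(seed=seed, **params)
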