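"""Synthetic cohorts and viability plates with known ground truth.

The cohort generator emulates the structure of a tumor-vs-normal
subtraction study: a panel of normal tissues with several samples each, a
handful of tumor cell-line samples, ~100 bp single-end reads, and a set
of "planted" transcripts expressed only in tumor samples.  Shared
transcripts get independent lognormal expression weights per sample (a
standard heavy-tailed stand-in for bulk expression); reads are drawn from
transcripts proportionally to weight with uniform start positions and
i.i.d. substitution errors.  Everything is a deterministic function of
the seed.

Desk-scale depth note: with the 10-count imputation floor, the planted
k-mer T:N ratio is (tumor count / 10) x (normal bp / tumor bp), which is
proportional to normal-sample depth and independent of tumor depth.  The
default normal depth (60,000 x 100 bp reads) puts planted ratios at
roughly 10^2-10^3, comfortably past the 500:1 filter; tumor runs default
shallower, mirroring a deep multi-tissue reference against a few
cell-line runs.

The viability simulator draws plates from the median-effect model
fa/(1-fa) = (D/Dm)^m with multiplicative Gaussian fluorescence noise,
plus untreated-control and scramble wells.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .doseresponse import PlateRecord
from .kmers import SampleMeta

__all__ = [
    "CohortConfig",
    "SyntheticGroundTruth",
    "SyntheticCohort",
    "toy_config",
    "simulate_cohort",
    "write_cohort",
    "simulate_viability",
]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and depth parameters for one simulated cohort.

    ``tumor_fold_excess`` scales a planted transcript's expression weight
    in tumor samples relative to the median shared-transcript weight
    (shared weights are lognormal(0, 1), median 1).
    """

    n_tissues: int = 26
    samples_per_tissue: tuple[int, int] = (6, 26)
    n_tumor_samples: int = 3
    n_shared_transcripts: int = 20
    n_tumor_specific: int = 3
    transcript_length: tuple[int, int] = (150, 300)
    tumor_fold_excess: float = 1000.0
    read_length: int = 100
    normal_reads_per_sample: int = 60_000
    tumor_reads_per_sample: int = 10_000
    substitution_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_tissues,
            self.n_tumor_samples,
            self.n_shared_transcripts,
            self.n_tumor_specific,
            self.read_length,
            self.normal_reads_per_sample,
            self.tumor_reads_per_sample,
        ) < 1:
            raise ValueError("all counts must be positive")
        if self.tumor_fold_excess <= 1:
            raise ValueError("tumor fold-excess must exceed 1")
        if self.read_length > self.transcript_length[0]:
            raise ValueError(
                "read length exceeds the minimum transcript length; "
                "no read can be drawn"
            )
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")


@dataclass
class SyntheticGroundTruth:
    """What was planted, so recovery can be checked exactly."""

    planted: dict[str, str]  # transcript id -> sequence
    weights: pd.DataFrame  # transcripts x samples expression weights
    seed: int

    def __post_init__(self) -> None:
        # planted transcripts must be silent in every normal sample
        normal_cols = [c for c in self.weights.columns if c.startswith("normal")]
        if normal_cols and (self.weights.loc[list(self.planted), normal_cols] != 0).any().any():
            raise ValueError("planted transcript expressed in a normal sample")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    transcripts: dict[str, str]
    samples: list[SampleMeta]
    reads: dict[str, np.ndarray]  # sample id -> (n_reads, read_len) uint8
    truth: SyntheticGroundTruth


def toy_config(seed: int = 0, **overrides) -> CohortConfig:
    """Desk preset: 24 transcripts, 10 tissues, 2 samples per tissue."""
    params = dict(
        n_tissues=10,
        samples_per_tissue=(2, 2),
        n_shared_transcripts=21,
        n_tumor_specific=3,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def _random_transcripts(
    rng: np.random.Generator, n: int, length_range: tuple[int, int], prefix: str
) -> dict[str, str]:
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    return {
        f"{prefix}{i:03d}": "".join(_ASCII[rng.integers(0, 4, size=L)].tobytes().decode())
        for i, L in enumerate(lengths)
    }


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort (transcripts, reads, sample sheet, ground truth)."""
    rng = np.random.default_rng(config.seed)
    shared = _random_transcripts(
        rng, config.n_shared_transcripts, config.transcript_length, "shared"
    )
    planted = _random_transcripts(
        rng, config.n_tumor_specific, config.transcript_length, "planted"
    )
    transcripts = {**shared, **planted}
    tx_ids = list(transcripts)
    n_tx = len(tx_ids)
    planted_mask = np.array([t in planted for t in tx_ids])

    # padded 2-bit code matrix for vectorized read gathering
    lengths = np.array([len(transcripts[t]) for t in tx_ids])
    max_len = int(lengths.max())
    code_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    tx_codes = np.zeros((n_tx, max_len), dtype=np.uint8)
    for i, t in enumerate(tx_ids):
        raw = np.frombuffer(transcripts[t].encode(), dtype=np.uint8)
        tx_codes[i, : raw.size] = code_of[raw]

    samples: list[SampleMeta] = []
    lo, hi = config.samples_per_tissue
    for ti in range(config.n_tissues):
        tissue = f"tissue{ti:02d}"
        n_samp = int(rng.integers(lo, hi + 1))
        for si in range(n_samp):
            samples.append(SampleMeta(f"normal_{tissue}_s{si}", "normal", tissue))
    for si in range(config.n_tumor_samples):
        samples.append(SampleMeta(f"tumor_s{si}", "tumor", ""))

    weights = pd.DataFrame(0.0, index=tx_ids, columns=[s.sample_id for s in samples])
    reads: dict[str, np.ndarray] = {}
    L = config.read_length
    new_samples = []
    for meta in samples:
        w = rng.lognormal(0.0, 1.0, size=n_tx)
        if meta.cohort == "normal":
            w[planted_mask] = 0.0
            n_reads = config.normal_reads_per_sample
        else:
            w[planted_mask] = config.tumor_fold_excess
            n_reads = config.tumor_reads_per_sample
        weights[meta.sample_id] = w
        p = w / w.sum()
        tx_idx = rng.choice(n_tx, size=n_reads, p=p)
        max_start = lengths[tx_idx] - L + 1
        starts = (rng.random(n_reads) * max_start).astype(np.int64)
        mat = tx_codes[tx_idx[:, None], starts[:, None] + np.arange(L)]
        if config.substitution_rate > 0:
            mask = rng.random(mat.shape) < config.substitution_rate
            n_err = int(mask.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                mat[mask] = (mat[mask] + shift) % 4
        reads[meta.sample_id] = _ASCII[mat]
        new_samples.append(
            SampleMeta(meta.sample_id, meta.cohort, meta.tissue, n_reads * L)
        )

    truth = SyntheticGroundTruth(planted=planted, weights=weights, seed=config.seed)
    return SyntheticCohort(
        config=config, transcripts=transcripts, samples=new_samples, reads=reads, truth=truth
    )


def write_cohort(
    cohort: SyntheticCohort, outdir: Union[str, Path], gzip_reads: bool = False
) -> None:
    """Write transcripts FASTA, per-sample FASTQ, sample sheet, ground truth."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    with open(outdir / "transcripts.fasta", "w") as fh:
        for tid, seq in cohort.transcripts.items():
            fh.write(f">{tid}\n{seq}\n")
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tcohort\ttissue\ttotal_bp\tfastq\n")
        for meta in cohort.samples:
            suffix = ".fastq.gz" if gzip_reads else ".fastq"
            fh.write(
                f"{meta.sample_id}\t{meta.cohort}\t{meta.tissue}\t{meta.total_bp}\t"
                f"reads/{meta.sample_id}{suffix}\n"
            )
    for sid, mat in cohort.reads.items():
        suffix = ".fastq.gz" if gzip_reads else ".fastq"
        path = outdir / "reads" / f"{sid}{suffix}"
        opener = (lambda p: gzip.open(p, "wt", compresslevel=1)) if gzip_reads else (
            lambda p: open(p, "w")
        )
        qual = "I" * mat.shape[1]
        with opener(path) as fh:
            for i in range(mat.shape[0]):
                fh.write(f"@{sid}_r{i}\n{mat[i].tobytes().decode()}\n+\n{qual}\n")
    truth = {
        "seed": cohort.truth.seed,
        "planted": cohort.truth.planted,
        "config": asdict(cohort.config),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    cohort.truth.weights.to_csv(outdir / "expression_weights.tsv", sep="\t")


def simulate_viability(
    m: float,
    Dm_uM: float,
    doses_uM: Sequence[float],
    replicates: int = 6,
    noise_sd: float = 0.05,
    seed: int = 0,
    treatment: str = "agent",
    control_signal: float = 1000.0,
    scramble_fa: float = 0.02,
) -> list[PlateRecord]:
    """Draw one plate from the median-effect model.

    True FA(D) = (D/Dm)^m / (1 + (D/Dm)^m); each well's fluorescence is
    control_signal * (1 - FA) * (1 + N(0, noise_sd)).  The plate includes
    ``replicates`` untreated-control wells and scramble wells whose true
    FA sits near zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    doses = np.asarray(doses_uM, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)

    def wells(label: str, dose: float, fa_true: float, start: int) -> list[PlateRecord]:
        noise = rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.zeros(replicates)
        out = []
        for j in range(replicates):
            fluor = control_signal * (1.0 - fa_true) * (1.0 + noise[j])
            out.append(
                PlateRecord(
                    well=f"{label}_d{dose:g}_r{j}",
                    treatment=label,
                    dose_uM=dose,
                    fluorescence=max(fluor, 0.0),
                )
            )
        return out

    records = wells("vehicle", 0.0, 0.0, 0)
    records += wells("scramble", float(doses.max()), scramble_fa, 0)
    for d in doses:
        ratio = (d / Dm_uM) ** m
        fa = ratio / (1.0 + ratio)
        records += wells(treatment, float(d), fa, 0)
    return records
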