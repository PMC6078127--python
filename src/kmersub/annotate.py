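"""Transcript annotation, ranking, and antisense target selection.

Candidate k-mers are located in a reference transcriptome index.  Each
transcript is scored by the contained candidate k-mer that is
over-abundant in the greatest number of tissues (its "selected" k-mer);
the count of those tissues is the transcript's over-abundance breadth.
Transcripts are ranked by breadth, a heat-map matrix of per-tissue ratios
is exported for the top of the ranking, and therapeutic targets are
called where the selected k-mer's ratio clears a stricter threshold
(default 10,000:1) in many tissues.  A k-mer shared by several
transcripts credits every one of them; splice variants are not collapsed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .kmers import decode_kmer, extract_kmers
from .subtract import TissueRatioProfile

__all__ = [
    "TranscriptomeIndex",
    "TranscriptScore",
    "TargetCall",
    "index_transcriptome",
    "score_transcripts",
    "rank_transcripts",
    "heatmap_matrix",
    "render_heatmap",
    "select_targets",
    "design_antisense",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


@dataclass
class TranscriptomeIndex:
    """All k-mer occurrences in a set of stranded transcript sequences."""

    transcripts: dict[str, str]
    kmer_hits: dict[int, list[tuple[str, int]]]
    k: int


@dataclass
class TranscriptScore:
    """A transcript's selected k-mer and its over-abundance breadth."""

    transcript_id: str
    selected_kmer: int | None
    tissue_count: int
    ratio_vector: dict[str, float]
    hit_offset: int = -1

    @property
    def min_ratio(self) -> float:
        return min(self.ratio_vector.values()) if self.ratio_vector else float("-inf")


@dataclass
class TargetCall:
    """A ranked transcript judged against the target-priority threshold."""

    transcript_id: str
    selected_kmer: int | None
    qualifying_tissues: int
    target_threshold: float = 10000.0


FastaLike = Union[str, Path, Iterable[tuple[str, str]]]


def _iter_transcripts(records: FastaLike) -> Iterable[tuple[str, str]]:
    if isinstance(records, (str, Path)):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(records), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        yield from records


def index_transcriptome(records: FastaLike, k: int) -> TranscriptomeIndex:
    """Catalog every valid k-window of every transcript with its offset.

    Transcript ids are FASTA headers up to the first whitespace.  Empty
    sequences are skipped with a warning; duplicate ids are an error.
    """
    transcripts: dict[str, str] = {}
    hits: dict[int, list[tuple[str, int]]] = {}
    for tid, seq in _iter_transcripts(records):
        if tid in transcripts:
            raise ValueError(f"duplicate transcript id {tid!r}")
        if not seq:
            warnings.warn(f"transcript {tid!r} has empty sequence; skipped", stacklevel=2)
            continue
        transcripts[tid] = seq
        codes = extract_kmers(seq, k)
        # offsets of valid windows: rebuild by scanning validity like extract_kmers
        offset = 0
        valid = np.array([c in "ACGTUacgtu" for c in seq])
        if valid.all():
            offsets = range(len(seq) - k + 1)
        else:
            cs = np.concatenate(([0], np.cumsum(~valid)))
            offsets = [i for i in range(len(seq) - k + 1) if cs[i + k] - cs[i] == 0]
        for off, code in zip(offsets, codes):
            hits.setdefault(int(code), []).append((tid, int(off)))
    if not transcripts:
        raise ValueError("no non-empty transcripts")
    return TranscriptomeIndex(transcripts=transcripts, kmer_hits=hits, k=k)


def score_transcripts(
    index: TranscriptomeIndex, profiles: Sequence[TissueRatioProfile]
) -> list[TranscriptScore]:
    """Pick each transcript's maximum-breadth candidate k-mer.

    Ties on tissue count are broken by the larger minimum per-tissue
    ratio, then by the smaller k-mer code; transcripts containing no
    candidate k-mer score 0 with no selected k-mer.
    """
    by_kmer = {p.kmer: p for p in profiles}
    best: dict[str, tuple[tuple[int, float, int], TranscriptScore]] = {}
    for code, prof in by_kmer.items():
        for tid, off in index.kmer_hits.get(code, ()):
            # sort key: maximize tissue_count, then min ratio, then prefer
            # the numerically smaller code (hence -code in a max compare)
            key = (prof.tissue_count, prof.min_ratio, -code)
            cur = best.get(tid)
            if cur is None or key > cur[0]:
                best[tid] = (
                    key,
                    TranscriptScore(
                        transcript_id=tid,
                        selected_kmer=code,
                        tissue_count=prof.tissue_count,
                        ratio_vector=dict(prof.ratios),
                        hit_offset=off,
                    ),
                )
    scores = []
    for tid in index.transcripts:
        if tid in best:
            scores.append(best[tid][1])
        else:
            scores.append(
                TranscriptScore(
                    transcript_id=tid, selected_kmer=None, tissue_count=0, ratio_vector={}
                )
            )
    return scores


def rank_transcripts(
    scores: Sequence[TranscriptScore], top_n: int = 400
) -> list[TranscriptScore]:
    """Total order: tissue count desc, min selected-k-mer ratio desc, id asc."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ordered = sorted(
        scores, key=lambda s: (-s.tissue_count, -s.min_ratio, s.transcript_id)
    )
    return ordered[:top_n]


def heatmap_matrix(
    ranking: Sequence[TranscriptScore],
    tissues: Sequence[str],
) -> pd.DataFrame:
    """Ratio of each ranked transcript's selected k-mer per tissue.

    Rows follow rank order, columns follow the given tissue order;
    transcripts without a selected k-mer get zero rows.
    """
    rows = []
    for s in ranking:
        rows.append([s.ratio_vector.get(t, 0.0) for t in tissues])
    return pd.DataFrame(
        rows, index=[s.transcript_id for s in ranking], columns=list(tissues)
    )


def render_heatmap(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    """Render the ratio matrix as a log10-scaled image (monotone in ratio)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with np.errstate(divide="ignore"):
        logm = np.log10(matrix.to_numpy(dtype=float) + 1.0)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(3, 0.05 * matrix.shape[0]))
    )
    im = ax.imshow(logm, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} transcripts (rank order)")
    fig.colorbar(im, ax=ax, label="log10(1 + T:N ratio)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def select_targets(
    ranking: Sequence[TranscriptScore],
    target_threshold: float = 10000.0,
) -> list[TargetCall]:
    """Count tissues where each selected k-mer's ratio strictly clears the bar.

    Sorted by qualifying-tissue count descending (stable within ties, so
    rank order is preserved); the caller applies a shortlist floor such as
    "qualifies in every tissue".
    """
    if target_threshold <= 0:
        raise ValueError("target_threshold must be positive")
    calls = [
        TargetCall(
            transcript_id=s.transcript_id,
            selected_kmer=s.selected_kmer,
            qualifying_tissues=sum(r > target_threshold for r in s.ratio_vector.values()),
            target_threshold=target_threshold,
        )
        for s in ranking
    ]
    calls.sort(key=lambda c: -c.qualifying_tissues)
    return calls


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def design_antisense(transcript: str, start: int, length: int) -> str:
    """Antisense oligo for a transcript window: its reverse complement, 5'->3'.

    Typical antisense oligomers run 15-30 bases; lengths outside that
    range are permitted with a warning.
    """
    if start < 0 or start + length > len(transcript):
        raise ValueError(
            f"window [{start}, {start + length}) out of bounds for transcript of "
            f"length {len(transcript)}"
        )
    if not 15 <= length <= 30:
        warnings.warn(f"oligo length {length} outside the usual 15-30 range", stacklevel=2)
    return reverse_complement(transcript[start : start + length])
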