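"""Per-sample k-mer cataloging.

A k-mer is a length-``k`` nucleotide word over {A, C, G, T} stored as a
2-bit-per-base integer code (A=0, C=1, G=2, T=3, most significant base
first).  Because the base order matches ASCII order, sorting codes
numerically equals sorting the decoded words lexicographically.

Counting is stranded by default: transcript k-mers are matched as read,
without collapsing a word with its reverse complement, because downstream
stages assign k-mers to stranded transcript sequences.  ``canonical=True``
switches to the min(word, revcomp) convention used by many k-mer counters.

Counts below ``min_count`` (default 10) are discarded per sample: rare
words are indistinguishable from sequencing error at typical error rates,
and the default mirrors the 10-count floor used when normal-tissue
abundances are imputed downstream.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "SampleMeta",
    "SampleCatalog",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "extract_kmers",
    "count_sample",
    "read_sequences",
    "parse_kmer_dump",
    "write_catalog",
    "read_catalog",
]

_BASES = "ACGT"

# 256-entry lookup: ASCII byte -> 2-bit base code, 255 for anything that is
# not A/C/G/T/U (U maps to T so RNA- and DNA-alphabet inputs unify).
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("U")] = 3
_LUT[ord("u")] = 3


@dataclass(frozen=True)
class SampleMeta:
    """Identity and sequencing effort of one RNA-seq sample."""

    sample_id: str
    cohort: str  # "tumor" | "normal"
    tissue: str = ""
    total_bp: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in ("tumor", "normal"):
            raise ValueError(f"cohort must be 'tumor' or 'normal', got {self.cohort!r}")
        if self.cohort == "normal" and not self.tissue:
            raise ValueError(f"normal sample {self.sample_id!r} needs a tissue label")
        if self.total_bp < 0:
            raise ValueError("total_bp must be non-negative")


@dataclass
class SampleCatalog:
    """Thresholded k-mer counts for one sample.

    Every stored count is >= ``min_count``; all codes refer to a single
    word length ``k``.
    """

    meta: SampleMeta
    counts: dict[int, int]
    k: int
    min_count: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def encode_kmer(word: str) -> int:
    """Encode a nucleotide word into its 2-bit integer code."""
    code = 0
    for ch in word:
        b = _LUT[ord(ch)]
        if b == 255:
            raise ValueError(f"non-ACGTU symbol {ch!r} in k-mer {word!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a word of length ``k``."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement a k-mer in code space."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((code & 3) ^ 3)
        code >>= 2
    return rc


def _window_codes(seq: Union[str, bytes, np.ndarray], k: int) -> np.ndarray:
    """All valid k-window codes of ``seq``, left to right (vectorized).

    Windows containing any symbol outside {A,C,G,T,U} are skipped entirely.
    """
    if isinstance(seq, str):
        raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    elif isinstance(seq, (bytes, bytearray)):
        raw = np.frombuffer(bytes(seq), dtype=np.uint8)
    else:
        raw = np.asarray(seq, dtype=np.uint8)
    if raw.size < k:
        return np.empty(0, dtype=np.int64)
    codes = _LUT[raw]
    bad = codes == 255
    n_win = codes.size - k + 1
    # shift-or scan: k passes over the windows beats materializing an
    # (n_win, k) matrix for the usual k=25
    vals = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        np.left_shift(vals, 2, out=vals)
        np.bitwise_or(vals, codes[j : j + n_win] & 3, out=vals)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        ok = (cs[k:] - cs[:-k]) == 0
        vals = vals[ok]
    return vals


def extract_kmers(sequence: str, k: int, canonical: bool = False) -> np.ndarray:
    """k-mer codes of every valid window of ``sequence``, in order.

    A window is valid when all its symbols are in {A,C,G,T,U} (case
    insensitive, U read as T).  A sequence shorter than ``k`` yields an
    empty array.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = _window_codes(sequence, k)
    if canonical and vals.size:
        rc = np.fromiter(
            (revcomp_code(int(v), k) for v in vals), dtype=np.int64, count=vals.size
        )
        vals = np.minimum(vals, rc)
    return vals


ReadSource = Union[Iterable[str], np.ndarray, str, Path]


def _iter_reads(reads: ReadSource) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        yield from read_sequences(reads)
    else:
        yield from reads  # type: ignore[misc]


def count_sample(
    reads: ReadSource,
    meta: SampleMeta,
    k: int = 25,
    min_count: int = 10,
    canonical: bool = False,
) -> SampleCatalog:
    """Tally k-mers across a read set and drop counts below ``min_count``.

    ``reads`` may be an iterable of sequence strings, a FASTA/FASTQ path,
    or a 2-D uint8 byte matrix of fixed-length reads (one row per read, as
    produced by the cohort simulator).  ``meta.total_bp`` is set to the sum
    of read lengths unless a positive override is already present.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if isinstance(reads, np.ndarray):
        if reads.ndim != 2:
            raise ValueError("read matrix must be 2-D (reads x bases)")
        n_reads, read_len = reads.shape
        total_bp = n_reads * read_len
        # one 'N' separator column keeps windows from spanning reads
        sep = np.full((n_reads, 1), ord("N"), dtype=np.uint8)
        flat = np.hstack([reads, sep]).ravel()
        vals = _window_codes(flat, k)
        if canonical and vals.size:
            rc = np.fromiter(
                (revcomp_code(int(v), k) for v in vals), dtype=np.int64, count=vals.size
            )
            vals = np.minimum(vals, rc)
        uniq, cnt = np.unique(vals, return_counts=True)
        keep = cnt >= min_count
        counts = dict(zip(uniq[keep].tolist(), cnt[keep].tolist()))
        max_len = read_len
    else:
        # batch reads into ~4 Mb chunks joined by 'N' so window extraction
        # stays vectorized without windows spanning read boundaries
        total_bp = 0
        max_len = 0
        n_reads = 0
        chunks: list[np.ndarray] = []
        buf: list[str] = []
        buf_len = 0
        for idx, seq in enumerate(_iter_reads(reads)):
            if not isinstance(seq, str):
                raise TypeError(f"unreadable record at index {idx}: {type(seq).__name__}")
            n_reads += 1
            total_bp += len(seq)
            max_len = max(max_len, len(seq))
            buf.append(seq)
            buf_len += len(seq) + 1
            if buf_len >= 4_000_000:
                chunks.append(_window_codes("N".join(buf), k))
                buf, buf_len = [], 0
        if buf:
            chunks.append(_window_codes("N".join(buf), k))
        vals = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        if canonical and vals.size:
            rc = np.fromiter(
                (revcomp_code(int(v), k) for v in vals), dtype=np.int64, count=vals.size
            )
            vals = np.minimum(vals, rc)
        uniq, cnt = np.unique(vals, return_counts=True)
        keep = cnt >= min_count
        counts = dict(zip(uniq[keep].tolist(), cnt[keep].tolist()))
    if n_reads == 0:
        raise ValueError(f"sample {meta.sample_id!r}: read source is empty")
    if max_len < k:
        warnings.warn(
            f"sample {meta.sample_id!r}: all reads shorter than k={k}; catalog empty",
            stacklevel=2,
        )
    if meta.total_bp <= 0:
        meta = replace(meta, total_bp=total_bp)
    return SampleCatalog(meta=meta, counts=counts, k=k, min_count=min_count)


def _maybe_gzip(path: Union[str, Path]) -> IO[str]:
    path = Path(path)
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def read_sequences(path: Union[str, Path]) -> Iterator[str]:
    """Yield sequences from a FASTA or FASTQ file, plain or gzipped."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    handle = _maybe_gzip(path)
    try:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            for _title, seq in SimpleFastaParser(handle):
                yield seq
        elif first == "@":
            for _title, seq, _qual in FastqGeneralIterator(handle):
                yield seq
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    finally:
        handle.close()


def parse_kmer_dump(stream: Union[IO[str], Iterable[str]], k: int) -> dict[int, int]:
    """Parse a Jellyfish-style k-mer dump into raw ``{code: count}``.

    Two dialects are accepted, never mixed within one stream: column lines
    ``KMER COUNT`` or FASTA pairs ``>COUNT`` / ``KMER``.  Thresholding is
    the caller's business; raw counts are returned as-is.
    """
    counts: dict[int, int] = {}
    dialect: str | None = None
    pending: int | None = None
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if dialect == "column":
                raise ValueError(f"line {lineno}: FASTA header in column-dialect dump")
            dialect = "fasta"
            try:
                pending = int(line[1:])
            except ValueError:
                raise ValueError(f"line {lineno}: bad count header {line!r}") from None
            continue
        if dialect == "fasta":
            if pending is None:
                raise ValueError(f"line {lineno}: k-mer line without preceding count header")
            word, cnt = line, pending
            pending = None
        else:
            dialect = "column"
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'KMER COUNT', got {line!r}")
            word = parts[0]
            try:
                cnt = int(parts[1])
            except ValueError:
                raise ValueError(f"line {lineno}: bad count {parts[1]!r}") from None
        if len(word) != k:
            raise ValueError(f"line {lineno}: k-mer length {len(word)} != k={k}")
        try:
            code = encode_kmer(word)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        counts[code] = counts.get(code, 0) + cnt
    if dialect == "fasta" and pending is not None:
        raise ValueError("dump ends with a count header and no k-mer line")
    return counts


_HEADER_FIELDS = ("sample_id", "cohort", "tissue", "total_bp", "k", "min_count")


def write_catalog(catalog: SampleCatalog, path: Union[str, Path]) -> None:
    """Serialize a catalog to TSV with a commented metadata header.

    Rows are emitted in lexicographic (= numeric code) k-mer order so the
    file is deterministic and diffable.
    """
    with open(path, "w") as fh:
        fh.write(f"# sample_id={catalog.meta.sample_id}\n")
        fh.write(f"# cohort={catalog.meta.cohort}\n")
        fh.write(f"# tissue={catalog.meta.tissue}\n")
        fh.write(f"# total_bp={catalog.meta.total_bp}\n")
        fh.write(f"# k={catalog.k}\n")
        fh.write(f"# min_count={catalog.min_count}\n")
        fh.write("kmer\tcount\n")
        for code in sorted(catalog.counts):
            fh.write(f"{decode_kmer(code, catalog.k)}\t{catalog.counts[code]}\n")


def read_catalog(path: Union[str, Path]) -> SampleCatalog:
    """Inverse of :func:`write_catalog`."""
    header: dict[str, str] = {}
    counts: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("=")
                header[key] = val
            elif line and line != "kmer\tcount":
                word, _, cnt = line.partition("\t")
                counts[encode_kmer(word)] = int(cnt)
    for f in _HEADER_FIELDS:
        if f not in header:
            raise ValueError(f"{path}: catalog header missing field {f!r}")
    meta = SampleMeta(
        sample_id=header["sample_id"],
        cohort=header["cohort"],
        tissue=header["tissue"],
        total_bp=int(header["total_bp"]),
    )
    return SampleCatalog(
        meta=meta, counts=counts, k=int(header["k"]), min_count=int(header["min_count"])
    )
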