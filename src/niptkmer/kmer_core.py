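"""Canonical k-mer primitives.

Everything downstream (list building, sample counting) is built on exact,
in-memory counting of *canonical* k-mers: a k-mer is stored as the
lexicographic minimum of itself and its reverse complement, so matching is
strand-agnostic (sequencing reads originate from either strand).

K-mers are packed 2 bits per base into ``uint64`` codes; because A<C<G<T maps
to 0<1<2<3, lexicographic order on k-mer strings equals numeric order on
codes, and sorted code arrays double as the on-disk sort order. This caps k
at 32, which comfortably covers the default k=25.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MAX_K = 32
DEFAULT_K = 25

LIST_MAGIC = "#niptmer-kmerlist"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # case-folded
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TRANS = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def _check_k(k: int) -> int:
    k = int(k)
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    return k


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved; non-ACGT bases pass through)."""
    return seq.translate(_RC_TRANS)[::-1]


def canonicalize(kmer: str) -> str:
    """Return min(kmer, reverse_complement(kmer)), uppercased.

    Raises ValueError on any non-ACGT character (callers skip such windows).
    """
    km = kmer.upper()
    if not km:
        raise ValueError("empty k-mer")
    enc = _ENCODE[np.frombuffer(km.encode("ascii"), dtype=np.uint8)]
    if (enc > 3).any():
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = reverse_complement(km)
    return km if km <= rc else rc


def encode_bases(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3; anything else 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def window_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical uint64 codes of every ACGT-only window of ``base_codes``.

    Windows covering a non-ACGT base are dropped; order of the surviving
    windows follows sequence position.
    """
    k = _check_k(k)
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = base_codes > 3
    clean = np.where(invalid, 0, base_codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        col = clean[j : j + n]
        fwd |= col << np.uint64(2 * (k - 1 - j))
        rev |= (three - col) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    if invalid.any():
        bad = np.cumsum(invalid)
        spanning = (bad[k - 1 :] - np.concatenate(([0], bad[: n - 1]))) > 0
        canon = canon[~spanning]
    return canon


def kmer_code(kmer: str) -> np.uint64:
    """Canonical uint64 code of a single k-mer string."""
    enc = encode_bases(kmer)
    if (enc > 3).any():
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    codes = window_codes(enc, len(kmer))
    return codes[0]


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """uint64 codes -> list of k-mer strings."""
    k = _check_k(k)
    arr = np.ascontiguousarray(codes, dtype=np.uint64).reshape(-1, 1)
    shifts = (2 * (k - 1 - np.arange(k))).astype(np.uint64)
    mat = ((arr >> shifts) & np.uint64(3)).astype(np.uint8)
    blob = _DECODE[mat].tobytes()
    return [blob[i * k : (i + 1) * k].decode("ascii") for i in range(arr.shape[0])]


def _codes_isin(codes: np.ndarray, sorted_codes: np.ndarray) -> np.ndarray:
    """Boolean membership mask of ``codes`` in a sorted-unique code array."""
    if sorted_codes.size == 0:
        return np.zeros(codes.size, dtype=bool)
    idx = np.searchsorted(sorted_codes, codes)
    idx[idx == sorted_codes.size] = sorted_codes.size - 1
    return sorted_codes[idx] == codes


def merge_code_counts(
    code_arrays: Iterable[np.ndarray], count_arrays: Iterable[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge (codes, counts) pairs into one sorted-unique (codes, counts)."""
    codes = np.concatenate([np.asarray(c, dtype=np.uint64) for c in code_arrays])
    counts = np.concatenate([np.asarray(c, dtype=np.int64) for c in count_arrays])
    if codes.size == 0:
        return codes, counts
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    counts = counts[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(codes)) + 1))
    return codes[starts], np.add.reduceat(counts, starts)


class KmerSet:
    """A set of canonical k-mers of one fixed k, stored as sorted codes."""

    __slots__ = ("k", "codes")

    def __init__(self, k: int, codes: np.ndarray | None = None):
        self.k = _check_k(k)
        if codes is None:
            codes = np.empty(0, dtype=np.uint64)
        self.codes = np.ascontiguousarray(codes, dtype=np.uint64)

    @classmethod
    def from_codes(cls, k: int, codes: np.ndarray) -> "KmerSet":
        return cls(k, np.unique(np.asarray(codes, dtype=np.uint64)))

    @classmethod
    def from_strings(cls, k: int, kmers: Iterable[str]) -> "KmerSet":
        codes = []
        for km in kmers:
            if len(km) != k:
                raise ValueError(f"k-mer {km!r} does not have length {k}")
            codes.append(kmer_code(km))
        return cls.from_codes(k, np.array(codes, dtype=np.uint64))

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        return bool(_codes_isin(np.array([kmer_code(kmer)], dtype=np.uint64), self.codes)[0])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KmerSet)
            and self.k == other.k
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"KmerSet(k={self.k}, n={len(self)})"

    def to_strings(self) -> list[str]:
        return decode_codes(self.codes, self.k)

    def _check_other(self, other: "KmerSet | KmerCountList") -> np.ndarray:
        if self.k != other.k:
            raise ValueError(f"mismatched k: {self.k} vs {other.k}")
        return other.codes

    def union(self, other: "KmerSet") -> "KmerSet":
        codes = self._check_other(other)
        return KmerSet(self.k, np.union1d(self.codes, codes))

    def intersection(self, other: "KmerSet") -> "KmerSet":
        codes = self._check_other(other)
        return KmerSet(self.k, self.codes[_codes_isin(self.codes, codes)])

    def difference(self, other: "KmerSet") -> "KmerSet":
        codes = self._check_other(other)
        return KmerSet(self.k, self.codes[~_codes_isin(self.codes, codes)])

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    def isdisjoint(self, other: "KmerSet") -> bool:
        return len(self.intersection(other)) == 0


class KmerCountList:
    """Mapping canonical k-mer -> occurrence count (all counts >= 1)."""

    __slots__ = ("k", "codes", "counts", "source_label")

    def __init__(
        self,
        k: int,
        codes: np.ndarray,
        counts: np.ndarray,
        source_label: str = "",
    ):
        self.k = _check_k(k)
        self.codes = np.ascontiguousarray(codes, dtype=np.uint64)
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must have equal length")
        self.source_label = source_label

    @classmethod
    def empty(cls, k: int, source_label: str = "") -> "KmerCountList":
        return cls(k, np.empty(0, np.uint64), np.empty(0, np.int64), source_label)

    @classmethod
    def from_raw_codes(cls, k: int, raw: np.ndarray, source_label: str = "") -> "KmerCountList":
        codes, counts = np.unique(np.asarray(raw, dtype=np.uint64), return_counts=True)
        return cls(k, codes, counts.astype(np.int64), source_label)

    @classmethod
    def from_dict(cls, k: int, mapping: Mapping[str, int], source_label: str = "") -> "KmerCountList":
        items = sorted((canonicalize(km), int(c)) for km, c in mapping.items())
        codes = np.array([kmer_code(km) for km, _ in items], dtype=np.uint64)
        counts = np.array([c for _, c in items], dtype=np.int64)
        order = np.argsort(codes)
        return cls(k, codes[order], counts[order], source_label)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def total(self) -> int:
        """Total count mass (number of contributing windows)."""
        return int(self.counts.sum())

    def get(self, kmer: str, default: int = 0) -> int:
        code = kmer_code(kmer)
        idx = np.searchsorted(self.codes, code)
        if idx < self.codes.size and self.codes[idx] == code:
            return int(self.counts[idx])
        return default

    def __getitem__(self, kmer: str) -> int:
        code = kmer_code(kmer)
        idx = np.searchsorted(self.codes, code)
        if idx < self.codes.size and self.codes[idx] == code:
            return int(self.counts[idx])
        raise KeyError(kmer)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer, 0) > 0

    def items(self) -> Iterator[tuple[str, int]]:
        return zip(decode_codes(self.codes, self.k), (int(c) for c in self.counts))

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    def keys_set(self) -> KmerSet:
        return KmerSet(self.k, self.codes.copy())

    def __repr__(self) -> str:
        return f"KmerCountList(k={self.k}, n={len(self)}, total={self.total})"


def enumerate_kmers(sequence: str, k: int, source_label: str = "") -> KmerCountList:
    """Count canonical k-mers over every ACGT-only window of ``sequence``.

    Case-insensitive; windows overlapping N or any other symbol are skipped;
    a sequence shorter than k yields an empty list.
    """
    raw = window_codes(encode_bases(sequence), k)
    return KmerCountList.from_raw_codes(k, raw, source_label)


def intersect(a: KmerCountList | KmerSet, b: KmerSet | KmerCountList):
    """Entries of ``a`` whose key is in ``b`` (counts, if any, taken from a)."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    b_codes = b.codes
    mask = _codes_isin(a.codes, b_codes)
    if isinstance(a, KmerCountList):
        return KmerCountList(a.k, a.codes[mask], a.counts[mask], a.source_label)
    return KmerSet(a.k, a.codes[mask])


def subtract(a: KmerSet | KmerCountList, b: KmerSet | KmerCountList):
    """Set difference a \\ b (counts, if any, taken from a)."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    mask = ~_codes_isin(a.codes, b.codes)
    if isinstance(a, KmerCountList):
        return KmerCountList(a.k, a.codes[mask], a.counts[mask], a.source_label)
    return KmerSet(a.k, a.codes[mask])


# ---------------------------------------------------------------------------
# FASTQ counting
# ---------------------------------------------------------------------------

PathOrHandle = Union[str, Path, IO]


def open_text(path: PathOrHandle, mode: str = "rt"):
    """Open a path transparently handling gzip (sniffed by magic bytes)."""
    if hasattr(path, "read") or hasattr(path, "write"):
        return path
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if str(path).endswith(".gz"):
        # mtime=0 keeps outputs byte-identical across reruns
        return io.TextIOWrapper(gzip.GzipFile(filename="", fileobj=open(path, "wb"), mode="wb", mtime=0))
    return open(path, mode)


@dataclass
class FastqKmerCounts:
    """Canonical k-mer counts of a FASTQ stream plus base-composition tallies."""

    kmers: KmerCountList
    total_reads: int
    total_bases: int
    called_bases: int  # A/C/G/T only; N excluded
    gc_bases: int

    @property
    def gc_fraction(self) -> float:
        """GC_S: (G+C bases) / (called bases); 0.0 for an empty stream."""
        return self.gc_bases / self.called_bases if self.called_bases else 0.0


def count_from_fastq(
    fastq: PathOrHandle,
    k: int,
    source_label: str | None = None,
    batch_bases: int = 1 << 22,
) -> FastqKmerCounts:
    """Convert a FASTQ stream (plain or gzip) to a canonical k-mer count list.

    Reads are scanned window-by-window exactly as :func:`enumerate_kmers`;
    windows never span read boundaries. Base-composition tallies for GC_S are
    accumulated over all reads (N bases excluded from both numerator and
    denominator).
    """
    k = _check_k(k)
    if source_label is None:
        source_label = str(fastq) if not hasattr(fastq, "read") else "<stream>"
    total_reads = total_bases = called = gc = 0
    batch: list[str] = []
    batch_size = 0
    code_chunks: list[np.ndarray] = []
    count_chunks: list[np.ndarray] = []

    def flush():
        nonlocal batch, batch_size, called, gc
        if not batch:
            return
        enc = encode_bases("N".join(batch))
        valid = enc <= 3
        called += int(valid.sum())
        gc += int(((enc == 1) | (enc == 2)).sum())
        raw = window_codes(enc, k)
        if raw.size:
            codes, counts = np.unique(raw, return_counts=True)
            code_chunks.append(codes)
            count_chunks.append(counts.astype(np.int64))
        batch = []
        batch_size = 0

    handle = open_text(fastq, "rt")
    close = handle is not fastq
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                _title, seq, _qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {total_reads}: {exc}"
                ) from exc
            total_reads += 1
            total_bases += len(seq)
            batch.append(seq)
            batch_size += len(seq)
            if batch_size >= batch_bases:
                flush()
        flush()
    finally:
        if close:
            handle.close()

    if code_chunks:
        codes, counts = merge_code_counts(code_chunks, count_chunks)
    else:
        codes = np.empty(0, np.uint64)
        counts = np.empty(0, np.int64)
    return FastqKmerCounts(
        kmers=KmerCountList(k, codes, counts, source_label),
        total_reads=total_reads,
        total_bases=total_bases,
        called_bases=called,
        gc_bases=gc,
    )


# ---------------------------------------------------------------------------
# K-mer list file format
# ---------------------------------------------------------------------------


def write_kmer_list(
    path: str | Path,
    data: KmerCountList | KmerSet,
    source_label: str | None = None,
) -> None:
    """Write the gzip text list format: header line then ``kmer\\tcount``.

    Entries are sorted ascending lexicographically (equals code order). A pure
    set is written with count 1 everywhere. The gzip mtime is zeroed so
    identical inputs produce byte-identical files.
    """
    if isinstance(data, KmerCountList):
        codes, counts = data.codes, data.counts
        label = source_label if source_label is not None else data.source_label
    else:
        codes = data.codes
        counts = np.ones(codes.size, dtype=np.int64)
        label = source_label or ""
    k = data.k
    with io.TextIOWrapper(gzip.GzipFile(filename="", fileobj=open(path, "wb"), mode="wb", mtime=0)) as out:
        out.write(f"{LIST_MAGIC}\tk={k}\tsource={label}\n")
        chunk = 1 << 16
        for start in range(0, codes.size, chunk):
            kms = decode_codes(codes[start : start + chunk], k)
            cts = counts[start : start + chunk]
            out.write("".join(f"{km}\t{ct}\n" for km, ct in zip(kms, cts)))


def read_kmer_list(path: str | Path) -> KmerCountList:
    """Read the list format back (inverse of :func:`write_kmer_list`)."""
    with gzip.open(path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if not header.startswith(LIST_MAGIC) or len(fields) < 3:
            raise ValueError(f"{path}: not a k-mer list file (bad header {header!r})")
        k = int(fields[1].removeprefix("k="))
        label = fields[2].removeprefix("source=")
        kmers: list[str] = []
        counts: list[int] = []
        for line in fh:
            km, _, ct = line.rstrip("\n").partition("\t")
            kmers.append(km)
            counts.append(int(ct))
    if not kmers:
        return KmerCountList.empty(k, label)
    joined = "".join(kmers)
    enc = encode_bases(joined)
    if (enc > 3).any():
        raise ValueError(f"{path}: non-ACGT k-mer in list")
    mat = enc.reshape(len(kmers), k).astype(np.uint64)
    shifts = (2 * (k - 1 - np.arange(k))).astype(np.uint64)
    codes = (mat << shifts).sum(axis=1, dtype=np.uint64)
    counts_arr = np.array(counts, dtype=np.int64)
    if codes.size > 1 and bool((codes[1:] <= codes[:-1]).any()):
        raise ValueError(f"{path}: k-mer list not sorted/unique")
    return KmerCountList(k, codes, counts_arr, label)
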