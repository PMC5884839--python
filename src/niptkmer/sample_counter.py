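"""Per-sample chromosome-specific k-mer counting and the cohort data matrix.

A sample's FASTQ is converted to a canonical k-mer count list and intersected
with every chromosome's filtered list, giving K_sc (per-chromosome k-mer
count) and GC_S (overall GC fraction of the reads). Stacking samples gives
the cohort data matrix: one row per sample, one column per chromosome plus a
final ``gc`` column.

K_sc is, by default, the *summed occurrence* count (multiplicity-aware): it
scales linearly with sequencing depth at any coverage. The alternative
``distinct`` mode tallies how many list k-mers were seen at least once; it
saturates as depth grows but is retained as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kmer_core import FastqKmerCounts, PathOrHandle, count_from_fastq
from .list_builder import ChromosomeKmerList, lists_content_hash, sort_chromosomes

GC_COLUMN = "gc"
COUNT_MODES = ("occurrences", "distinct")


class ChromosomeKmerIndex:
    """Merged lookup over per-chromosome lists: code -> owning chromosome.

    Final lists are pairwise disjoint, so each code has a unique owner; a
    shared code is a hard error.
    """

    def __init__(self, lists: Mapping[str, ChromosomeKmerList], manifest_hash: str | None = None):
        ks = {l.k for l in lists.values()}
        if len(ks) != 1:
            raise ValueError(f"chromosome lists disagree on k: {sorted(ks)}")
        self.k = ks.pop()
        self.chromosomes = sort_chromosomes(lists)
        codes = np.concatenate([lists[c].kmers.codes for c in self.chromosomes])
        owners = np.concatenate(
            [np.full(lists[c].L_c, i, dtype=np.int32) for i, c in enumerate(self.chromosomes)]
        )
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.owners = owners[order]
        if self.codes.size > 1 and bool((self.codes[1:] == self.codes[:-1]).any()):
            raise ValueError("chromosome lists are not disjoint")
        self.L_c = {c: lists[c].L_c for c in self.chromosomes}
        self.manifest_hash = manifest_hash if manifest_hash is not None else lists_content_hash(lists)

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Owner chromosome index per code; -1 for codes in no list."""
        if self.codes.size == 0:
            return np.full(codes.size, -1, dtype=np.int32)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, self.codes.size - 1)
        hit = self.codes[idx_c] == codes
        out = np.where(hit, self.owners[idx_c], -1).astype(np.int32)
        return out


@dataclass
class SampleCounts:
    """Raw chromosome-specific counts K_sc plus GC_S for one sample."""

    sample_id: str
    k_sc: dict[str, int]
    gc_s: float
    total_bases: int
    total_reads: int
    k: int
    mode: str = "occurrences"
    manifest_hash: str | None = None


def count_sample(
    fastq: PathOrHandle,
    lists: Mapping[str, ChromosomeKmerList] | ChromosomeKmerIndex,
    mode: str = "occurrences",
    sample_id: str | None = None,
) -> SampleCounts:
    """Count a sample's FASTQ against the chromosome-specific k-mer lists."""
    if mode not in COUNT_MODES:
        raise ValueError(f"mode must be one of {COUNT_MODES}, got {mode!r}")
    index = lists if isinstance(lists, ChromosomeKmerIndex) else ChromosomeKmerIndex(lists)
    if sample_id is None:
        sample_id = Path(str(fastq)).name if not hasattr(fastq, "read") else "<stream>"
    fq: FastqKmerCounts = count_from_fastq(fastq, index.k, source_label=sample_id)
    owners = index.lookup(fq.kmers.codes)
    hit = owners >= 0
    n_chrom = len(index.chromosomes)
    if mode == "occurrences":
        per = np.bincount(owners[hit], weights=fq.kmers.counts[hit], minlength=n_chrom)
    else:
        per = np.bincount(owners[hit], minlength=n_chrom)
    k_sc = {c: int(per[i]) for i, c in enumerate(index.chromosomes)}
    return SampleCounts(
        sample_id=sample_id,
        k_sc=k_sc,
        gc_s=fq.gc_fraction,
        total_bases=fq.total_bases,
        total_reads=fq.total_reads,
        k=index.k,
        mode=mode,
        manifest_hash=index.manifest_hash,
    )


@dataclass
class DataMatrix:
    """Cohort matrix: rows = samples, columns = chromosomes + ``gc``.

    ``l_c`` carries the per-chromosome list sizes and ``manifest_hash`` ties
    the matrix to the exact k-mer lists it was counted against.
    """

    frame: pd.DataFrame
    l_c: dict[str, int]
    k: int
    manifest_hash: str
    mode: str = "occurrences"

    @property
    def chromosomes(self) -> list[str]:
        return [c for c in self.frame.columns if c != GC_COLUMN]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tsv = prefix.with_suffix(".tsv")
        sidecar = prefix.with_suffix(".manifest.json")
        out = self.frame.copy()
        out.insert(0, "sample_id", out.index)
        # %.17g keeps the write/read round trip lossless for float64
        out.to_csv(tsv, sep="\t", index=False, float_format="%.17g")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "L_c": self.l_c,
                    "hash": self.manifest_hash,
                    "mode": self.mode,
                    "columns": list(self.frame.columns),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return tsv, sidecar

    @classmethod
    def read(cls, prefix: str | Path) -> "DataMatrix":
        prefix = Path(prefix)
        frame = pd.read_csv(
            prefix.with_suffix(".tsv"), sep="\t", dtype={"sample_id": str},
            float_precision="round_trip",
        )
        frame = frame.set_index("sample_id")
        frame.index.name = None
        with open(prefix.with_suffix(".manifest.json")) as fh:
            meta = json.load(fh)
        frame = frame[meta["columns"]].astype(float)
        return cls(
            frame=frame,
            l_c=dict(meta["L_c"]),
            k=int(meta["k"]),
            manifest_hash=meta["hash"],
            mode=meta.get("mode", "occurrences"),
        )


def build_matrix(samples: Sequence[SampleCounts], manifest: Mapping) -> DataMatrix:
    """Stack per-sample counts into the cohort matrix.

    Column order is fixed by the manifest (autosomes in natural order, X, Y,
    then ``gc``) regardless of input sample order. Every sample must have been
    counted against the same lists (manifest hash check).
    """
    if not samples:
        raise ValueError("no samples to stack")
    chroms = list(manifest["chromosomes"])
    modes = {s.mode for s in samples}
    if len(modes) != 1:
        raise ValueError(f"samples counted in different modes: {sorted(modes)}")
    rows = {}
    for s in samples:
        if s.manifest_hash is not None and s.manifest_hash != manifest["hash"]:
            raise ValueError(
                f"sample {s.sample_id} was counted against different k-mer lists "
                f"(hash {s.manifest_hash[:12]} != manifest {manifest['hash'][:12]})"
            )
        missing = [c for c in chroms if c not in s.k_sc]
        if missing:
            raise ValueError(f"sample {s.sample_id} lacks counts for {missing}")
        rows[s.sample_id] = [float(s.k_sc[c]) for c in chroms] + [s.gc_s]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=chroms + [GC_COLUMN])
    return DataMatrix(
        frame=frame,
        l_c={c: int(manifest["L_c"][c]) for c in chroms},
        k=int(manifest["k"]),
        manifest_hash=manifest["hash"],
        mode=modes.pop(),
    )


def concat_matrices(matrices: Sequence[DataMatrix]) -> DataMatrix:
    """Stack row files produced by separate ``count`` invocations."""
    if not matrices:
        raise ValueError("nothing to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if m.manifest_hash != first.manifest_hash:
            raise ValueError("matrices were counted against different k-mer lists")
        if m.mode != first.mode:
            raise ValueError("matrices mix count modes")
        if list(m.frame.columns) != list(first.frame.columns):
            raise ValueError("matrices have different column sets")
    frame = pd.concat([m.frame for m in matrices], axis=0)
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids across row files: {dups}")
    return DataMatrix(frame, first.l_c, first.k, first.manifest_hash, first.mode)
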