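"""Construction of the final filtered per-chromosome k-mer lists.

The list-building pipeline turns a reference genome into one set of k-mers
per chromosome such that every member (i) occurs exactly once genome-wide,
(ii) does not overlap a common polymorphism on any allele, (iii) does not
overlap an excluded region (low-complexity repeats, pseudoautosomal regions,
...), and (iv) shows a Poisson-stable count in every deep-coverage control
individual. The final list size per chromosome is L_c; sample coverage is
later measured as (k-mers hit) / L_c.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .kmer_core import (
    DEFAULT_K,
    KmerCountList,
    KmerSet,
    count_from_fastq,
    enumerate_kmers,
    intersect,
    merge_code_counts,
    read_kmer_list,
    window_codes,
    encode_bases,
    write_kmer_list,
)

log = logging.getLogger(__name__)

LIST_SUFFIX = ".kmers.gz"
MANIFEST_NAME = "manifest.json"


# ---------------------------------------------------------------------------
# Input containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """One polymorphism record; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    maf: float | None  # None = frequency unknown, treated as above threshold

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        return self.pos0 + len(self.ref)


class VariantSet:
    """Polymorphisms sorted by (chromosome, position)."""

    def __init__(self, variants: Iterable[Variant]):
        self.variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
        for v in self.variants:
            if v.maf is not None and not 0.0 <= v.maf <= 1.0:
                raise ValueError(f"MAF out of [0,1] for {v.chrom}:{v.pos}")
        self._by_chrom: dict[str, list[Variant]] = {}
        for v in self.variants:
            self._by_chrom.setdefault(v.chrom, []).append(v)

    @classmethod
    def from_vcf(cls, path: str | Path, af_key: str = "AF") -> "VariantSet":
        from cyvcf2 import VCF

        variants = []
        for rec in VCF(str(path)):
            af = rec.INFO.get(af_key)
            if isinstance(af, (tuple, list)):
                af = af[0]
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alts=tuple(rec.ALT),
                    maf=float(af) if af is not None else None,
                )
            )
        return cls(variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def on_chrom(self, chrom: str) -> list[Variant]:
        return self._by_chrom.get(chrom, [])


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"degenerate region {self.chrom}:{self.start}-{self.end}")


class GenomicRegionSet:
    """Excluded regions (BED semantics: 0-based half-open)."""

    def __init__(self, regions: Iterable[Region]):
        self.regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicRegionSet":
        regions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                regions.append(Region(chrom, int(start), int(end)))
        return cls(regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


@dataclass
class PoissonFilterParams:
    """Population-stability filter: keep k-mers whose control count lies in the
    central Poisson interval [ppf(p_low), ppf(p_high)] at the control's
    per-chromosome mean coverage lambda (estimated from data when None)."""

    p_low: float = 0.01
    p_high: float = 0.99
    lam: float | None = None

    def __post_init__(self):
        if not 0.0 < self.p_low < self.p_high < 1.0:
            raise ValueError(f"need 0 < p_low < p_high < 1, got {self.p_low}, {self.p_high}")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class ChromosomeKmerList:
    """Final filtered k-mer set representing one chromosome; |kmers| = L_c."""

    chromosome: str
    kmers: KmerSet

    @property
    def L_c(self) -> int:
        return len(self.kmers)

    @property
    def k(self) -> int:
        return self.kmers.k


# ---------------------------------------------------------------------------
# Genome loading and chromosome ordering
# ---------------------------------------------------------------------------


def load_genome(genome) -> dict[str, str]:
    """Accept a FASTA path or a chrom->sequence mapping; return the mapping."""
    if isinstance(genome, Mapping):
        return dict(genome)
    from pyfaidx import Fasta

    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def _chrom_sort_key(name: str):
    base = name.removeprefix("chr")
    if base.isdigit():
        return (0, int(base), name)
    if base in ("X", "Y"):
        return (1, "XY".index(base), name)
    return (2, 0, name)


def sort_chromosomes(names: Iterable[str]) -> list[str]:
    """Stable natural order: autosomes numerically, then X, Y, then others."""
    return sorted(names, key=_chrom_sort_key)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def build_initial_lists(genome, k: int = DEFAULT_K) -> dict[str, KmerCountList]:
    """Per-chromosome canonical k-mer counts of the reference genome."""
    seqs = load_genome(genome)
    if not seqs:
        raise ValueError("empty genome: no chromosome records")
    return {
        chrom: enumerate_kmers(seq, k, source_label=chrom)
        for chrom, seq in seqs.items()
    }


def filter_nonunique(per_chrom_lists: Mapping[str, KmerCountList]) -> dict[str, KmerSet]:
    """Keep a k-mer on chromosome c iff its genome-wide canonical count is 1."""
    ks = {lst.k for lst in per_chrom_lists.values()}
    if len(ks) != 1:
        raise ValueError(f"lists disagree on k: {sorted(ks)}")
    codes, totals = merge_code_counts(
        [lst.codes for lst in per_chrom_lists.values()],
        [lst.counts for lst in per_chrom_lists.values()],
    )
    singles = codes[totals == 1]
    out = {}
    for chrom, lst in per_chrom_lists.items():
        keep = np.isin(lst.codes, singles, assume_unique=True)
        out[chrom] = KmerSet(lst.k, lst.codes[keep])
    return out


def polymorphic_kmers(
    genome,
    variants: VariantSet,
    k: int = DEFAULT_K,
    maf_min: float = 0.01,
    max_haplotypes: int = 4096,
) -> KmerSet:
    """All canonical k-mers touched by any allele combination of common variants.

    For each variant with MAF >= ``maf_min`` (unknown MAF counts as common),
    the k-1 flanked window around it is expanded into every haplotype over the
    variants inside that window (ref plus each alt per variant). If the
    combination count exceeds ``max_haplotypes`` — or overlapping ref spans
    make substitution ambiguous — the fallback is all *reference* k-mers of
    the window (conservative: biases toward exclusion).
    """
    seqs = load_genome(genome)
    chunks: list[np.ndarray] = []
    for chrom, chrom_variants in ((c, variants.on_chrom(c)) for c in sorted({v.chrom for v in variants})):
        if chrom not in seqs:
            raise ValueError(f"variant chromosome {chrom!r} not in genome")
        seq = seqs[chrom].upper()
        starts = [v.pos0 for v in chrom_variants]
        for v in chrom_variants:
            if v.maf is not None and v.maf < maf_min:
                continue
            if seq[v.pos0 : v.end0] != v.ref.upper():
                raise ValueError(
                    f"variant {chrom}:{v.pos} ref {v.ref!r} does not match genome "
                    f"{seq[v.pos0:v.end0]!r}"
                )
            wstart = max(0, v.pos0 - (k - 1))
            wend = min(len(seq), v.end0 + (k - 1))
            lo = bisect_left(starts, wstart)
            hi = bisect_right(starts, wend - 1)
            inside = [w for w in chrom_variants[lo:hi] if w.pos0 < wend and w.end0 > wstart]
            n_combos = 1
            for w in inside:
                n_combos *= 1 + len(w.alts)
            spans = sorted((w.pos0, w.end0) for w in inside)
            overlapping_refs = any(a_end > b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))
            if n_combos > max_haplotypes or overlapping_refs:
                chunks.append(window_codes(encode_bases(seq[wstart:wend]), k))
                continue
            for alleles in itertools.product(*([w.ref] + list(w.alts) for w in inside)):
                hap = seq[wstart:wend]
                for w, allele in sorted(zip(inside, alleles), key=lambda p: -p[0].pos0):
                    off = w.pos0 - wstart
                    hap = hap[:off] + allele.upper() + hap[off + len(w.ref) :]
                chunks.append(window_codes(encode_bases(hap), k))
    if not chunks:
        return KmerSet(k)
    return KmerSet.from_codes(k, np.concatenate(chunks))


def region_kmers(genome, regions: GenomicRegionSet, k: int = DEFAULT_K) -> KmerSet:
    """All canonical k-mers whose window overlaps any region by >= 1 base."""
    seqs = load_genome(genome)
    chunks = []
    for region in regions:
        if region.chrom not in seqs:
            raise ValueError(f"region chromosome {region.chrom!r} not in genome")
        seq = seqs[region.chrom]
        if region.end > len(seq):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        lo = max(0, region.start - (k - 1))
        hi = min(len(seq), region.end + (k - 1))
        chunks.append(window_codes(encode_bases(seq[lo:hi]), k))
    if not chunks:
        return KmerSet(k)
    return KmerSet.from_codes(k, np.concatenate(chunks))


def poisson_bounds(lam: float, p_low: float = 0.01, p_high: float = 0.99) -> tuple[int, int]:
    """Central-interval count cut-offs from the cumulative Poisson distribution.

    Returns (low, high) where each bound is the smallest integer x with
    CDF(x; lam) >= p. The stability interval is inclusive at both ends.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0.0 < p_low < p_high < 1.0:
        raise ValueError(f"need 0 < p_low < p_high < 1, got {p_low}, {p_high}")
    return int(poisson.ppf(p_low, lam)), int(poisson.ppf(p_high, lam))


def estimate_lambda(control_counts: KmerCountList, candidate_set: KmerSet) -> float:
    """Mean control count over candidate k-mers present in the control.

    Controls are deep (20-30x), so the zero-truncation bias of conditioning on
    presence is negligible.
    """
    present = intersect(control_counts, candidate_set)
    if len(present) == 0:
        return 0.0
    return float(present.counts.mean())


def stable_kmers_for_control(
    control_counts: KmerCountList,
    candidate_set: KmerSet,
    params: PoissonFilterParams | None = None,
) -> KmerSet:
    """Members of ``candidate_set`` with a Poisson-stable count in one control.

    A candidate absent from the control has count 0 and is rejected whenever
    low >= 1. K-mers not present in exactly two copies in the control genome
    (e.g. under a CNV duplication, counts ~ 2*lambda) fall outside the
    interval and are rejected.
    """
    params = params or PoissonFilterParams()
    if control_counts.k != candidate_set.k:
        raise ValueError(f"mismatched k: {control_counts.k} vs {candidate_set.k}")
    if len(candidate_set) == 0:
        raise ValueError("candidate set is empty")
    lam = params.lam if params.lam is not None else estimate_lambda(control_counts, candidate_set)
    if lam <= 0:
        raise ValueError("cannot estimate lambda: no candidate k-mers present in control")
    low, high = poisson_bounds(lam, params.p_low, params.p_high)
    idx = np.searchsorted(control_counts.codes, candidate_set.codes)
    idx_clipped = np.minimum(idx, max(len(control_counts) - 1, 0))
    if len(control_counts):
        hit = control_counts.codes[idx_clipped] == candidate_set.codes
        counts = np.where(hit, control_counts.counts[idx_clipped], 0)
    else:
        counts = np.zeros(len(candidate_set), dtype=np.int64)
    keep = (counts >= low) & (counts <= high)
    return KmerSet(candidate_set.k, candidate_set.codes[keep])


def finalize_lists(
    per_chrom_unique: Mapping[str, KmerSet],
    polymorphic: KmerSet | None = None,
    region_set: KmerSet | None = None,
    per_control_stable: Sequence[KmerSet | Mapping[str, KmerSet]] = (),
    strict: bool = True,
) -> dict[str, ChromosomeKmerList]:
    """final(c) = (unique(c) \\ polymorphic \\ regions) ∩ stable_1 ∩ ... ∩ stable_n.

    Polymorphic and region k-mers are subtracted genome-wide (an alt-allele
    k-mer may coincide with reference sequence on another chromosome). Each
    element of ``per_control_stable`` is either one genome-wide stable set or
    a per-chromosome mapping (a chromosome missing from the mapping is
    unconstrained by that control). With no controls and ``strict`` false the
    stability stage is skipped.
    """
    if not per_control_stable and strict:
        raise ValueError("no control individuals configured (pass strict=False to skip stability)")
    out = {}
    for chrom in sort_chromosomes(per_chrom_unique):
        current = per_chrom_unique[chrom]
        if polymorphic is not None and len(polymorphic):
            current = current - polymorphic
        if region_set is not None and len(region_set):
            current = current - region_set
        for stable in per_control_stable:
            if isinstance(stable, Mapping):
                if chrom in stable:
                    current = current & stable[chrom]
            else:
                current = current & stable
        if len(current) == 0:
            raise ValueError(
                f"final k-mer list for {chrom} is empty "
                "(toy genome too small or filters too strict)"
            )
        out[chrom] = ChromosomeKmerList(chrom, current)
    return out


# ---------------------------------------------------------------------------
# Orchestration, manifest, disk format
# ---------------------------------------------------------------------------


def lists_content_hash(lists: Mapping[str, ChromosomeKmerList]) -> str:
    h = hashlib.sha256()
    for chrom in sort_chromosomes(lists):
        ckl = lists[chrom]
        h.update(chrom.encode())
        h.update(str(ckl.k).encode())
        h.update(np.ascontiguousarray(ckl.kmers.codes).tobytes())
    return h.hexdigest()


def build_chromosome_lists(
    genome,
    k: int = DEFAULT_K,
    variants: VariantSet | None = None,
    regions: GenomicRegionSet | None = None,
    control_fastqs: Sequence = (),
    params: PoissonFilterParams | None = None,
    maf_min: float = 0.01,
    max_haplotypes: int = 4096,
    min_present_fraction: float = 0.05,
    strict: bool = True,
) -> tuple[dict[str, ChromosomeKmerList], dict]:
    """Run the full list-building pipeline and return (lists, manifest).

    The stability filter estimates lambda per chromosome; a chromosome that is
    essentially absent from a control (fewer than ``min_present_fraction`` of
    candidates present, e.g. chrY in a female control) contributes no
    constraint from that control and is recorded in the manifest.
    """
    params = params or PoissonFilterParams()
    seqs = load_genome(genome)
    initial = build_initial_lists(seqs, k)
    log.info("initial lists: %s", {c: len(l) for c, l in initial.items()})
    unique = filter_nonunique(initial)
    log.info("unique lists: %s", {c: len(s) for c, s in unique.items()})
    poly = polymorphic_kmers(seqs, variants, k, maf_min, max_haplotypes) if variants else None
    if poly is not None:
        log.info("polymorphic k-mers: %d", len(poly))
    reg = region_kmers(seqs, regions, k) if regions else None
    if reg is not None:
        log.info("region k-mers: %d", len(reg))

    base = {}
    for chrom, uset in unique.items():
        cur = uset
        if poly is not None and len(poly):
            cur = cur - poly
        if reg is not None and len(reg):
            cur = cur - reg
        base[chrom] = cur

    per_control_stable: list[dict[str, KmerSet]] = []
    control_ids: list[str] = []
    skipped: dict[str, list[str]] = {}
    for fq in control_fastqs:
        label = Path(str(fq)).name if not hasattr(fq, "read") else f"control_{len(control_ids)}"
        counts = count_from_fastq(fq, k, source_label=label).kmers
        stable: dict[str, KmerSet] = {}
        for chrom, candidates in base.items():
            if len(candidates) == 0:
                continue
            present = intersect(counts, candidates)
            frac = len(present) / len(candidates)
            lam = float(present.counts.mean()) if len(present) else 0.0
            if frac < min_present_fraction or lam < 1.0:
                log.warning(
                    "control %s: %s skipped in stability filter "
                    "(present fraction %.3f, lambda %.2f)",
                    label, chrom, frac, lam,
                )
                skipped.setdefault(label, []).append(chrom)
                continue
            stable[chrom] = stable_kmers_for_control(
                counts, candidates, PoissonFilterParams(params.p_low, params.p_high, params.lam)
            )
        per_control_stable.append(stable)
        control_ids.append(label)
        log.info("control %s: stable sizes %s", label, {c: len(s) for c, s in stable.items()})

    final = finalize_lists(unique, poly, reg, per_control_stable, strict=strict)
    log.info("final lists: %s", {c: l.L_c for c, l in final.items()})
    manifest = {
        "format": "niptmer-lists",
        "k": k,
        "chromosomes": sort_chromosomes(final),
        "L_c": {c: final[c].L_c for c in sort_chromosomes(final)},
        "params": {
            "p_low": params.p_low,
            "p_high": params.p_high,
            "lambda": params.lam,
            "maf_min": maf_min,
            "max_haplotypes": max_haplotypes,
            "min_present_fraction": min_present_fraction,
        },
        "controls": control_ids,
        "stability_skipped": skipped,
        "hash": lists_content_hash(final),
    }
    return final, manifest


def write_lists(
    lists: Mapping[str, ChromosomeKmerList], manifest: dict, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for chrom, ckl in lists.items():
        write_kmer_list(outdir / f"{chrom}{LIST_SUFFIX}", ckl.kmers, source_label=chrom)
    with open(outdir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_lists(indir: str | Path) -> tuple[dict[str, ChromosomeKmerList], dict]:
    indir = Path(indir)
    with open(indir / MANIFEST_NAME) as fh:
        manifest = json.load(fh)
    lists = {}
    for chrom in manifest["chromosomes"]:
        lst = read_kmer_list(indir / f"{chrom}{LIST_SUFFIX}")
        lists[chrom] = ChromosomeKmerList(chrom, lst.keys_set())
    if lists_content_hash(lists) != manifest["hash"]:
        raise ValueError(f"{indir}: list files do not match manifest hash")
    return lists, manifest
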