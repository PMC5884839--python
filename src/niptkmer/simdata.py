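"""Seeded synthetic data: toy genomes, diploid individuals, cfDNA mixtures.

The generator emulates, at toy scale, every input the pipeline needs:

* a multi-chromosome reference genome with planted duplicated blocks (to
  exercise uniqueness filtering), low-complexity stretches and a
  pseudoautosomal block shared between X and Y (both emitted as exclusion-BED
  truth), and mild per-chromosome GC differences (so the GC regressor has
  signal);
* a SNV set with minor-allele frequencies spanning the 1% threshold;
* deep-coverage control individuals (default 25x, emulating 20-30x
  population controls);
* NIPT samples as maternal/fetal read mixtures at a configurable fetal
  fraction, with optional fetal trisomy and either fetal sex. The fetal
  fraction is *weight-based*: fetal-origin reads make up n% of the total.

Depths are scaled up relative to real cfDNA sequencing (0.08-0.42x) because
toy chromosomes are ~3 orders of magnitude shorter than human ones; the
relative counting noise at the defaults matches the regime where a 10% fetal
fraction trisomy is separable at 3.5 SD. All generators are deterministic
under a fixed seed (byte-identical files).
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kmer_core import _DECODE  # 2-bit code -> ASCII base lookup
from .list_builder import Variant, VariantSet

_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SimConfig:
    """Study conditions for the toy scenario.

    Lengths are per chromosome (autosomes in natural order, then X, Y).
    ``control_depth`` emulates the 20-30x population controls;
    ``sample_depth`` the cfDNA samples (scaled up for toy genomes);
    ``read_length`` 85 matches single-end cfDNA sequencing (a 50 bp cohort is
    also representable); ``fetal_fraction`` is in percent.
    """

    seed: int = 1
    k: int = 25
    autosome_lengths: tuple[int, ...] = (150_000, 130_000, 110_000, 90_000)
    x_length: int = 120_000
    y_length: int = 60_000
    gc_content_sd: float = 0.04
    repeat_fraction: float = 0.01
    repeat_block: int = 400
    lowcomplexity_per_chromosome: int = 2
    lowcomplexity_length: int = 600
    par_length: int = 1_500
    snp_density: float = 1.0 / 800.0
    maf_range: tuple[float, float] = (0.002, 0.5)
    read_length: int = 85
    error_rate: float = 0.002
    gc_bias_strength: float = 0.0
    control_depth: float = 25.0
    n_controls: int = 3
    sample_depth: float = 16.0
    # per-sample depth = sample_depth * U(jitter): cfDNA cohorts span a wide
    # coverage range around their mean, and the no-intercept regression model
    # relies on that common depth variation to be identifiable
    sample_depth_jitter: tuple[float, float] = (0.75, 1.25)
    fetal_fraction: float = 10.0
    trisomy_chromosome: str | None = None
    fetal_sex: str = "female"

    def __post_init__(self):
        if self.control_depth <= 0 or self.sample_depth <= 0:
            raise ValueError("depths must be positive")
        if not 0.0 <= self.fetal_fraction <= 100.0:
            raise ValueError("fetal fraction percent must be in [0, 100]")
        names = self.chromosome_names()
        if self.trisomy_chromosome is not None and self.trisomy_chromosome not in names:
            raise ValueError(f"unknown trisomy chromosome {self.trisomy_chromosome!r}")
        if min(self.lengths().values()) < self.k:
            raise ValueError("chromosome lengths must be >= k")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.autosome_lengths))] + ["chrX", "chrY"]

    def lengths(self) -> dict[str, int]:
        out = {f"chr{i + 1}": L for i, L in enumerate(self.autosome_lengths)}
        out["chrX"] = self.x_length
        out["chrY"] = self.y_length
        return out

    def haploid_length(self) -> int:
        return sum(self.lengths().values())


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    """Reference genome (2-bit codes per chromosome) plus truth annotations."""

    codes: dict[str, np.ndarray]
    truth: dict  # duplications, lowcomplexity, par, gc targets

    @property
    def sequences(self) -> dict[str, str]:
        return {c: codes_to_str(a) for c, a in self.codes.items()}

    def lengths(self) -> dict[str, int]:
        return {c: int(a.size) for c, a in self.codes.items()}

    def exclusion_regions(self) -> list[tuple[str, int, int]]:
        """Low-complexity + pseudoautosomal intervals (BED rows)."""
        rows = [tuple(r) for r in self.truth["lowcomplexity"]]
        rows += [tuple(r) for r in self.truth["par"]]
        return sorted(rows)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.codes:
                fh.write(f">{chrom}\n")
                seq = codes_to_str(self.codes[chrom])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_exclusion_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.exclusion_regions():
                fh.write(f"{chrom}\t{start}\t{end}\n")


def codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Random toy genome with planted duplications, low-complexity runs, PAR."""
    rng = np.random.default_rng(cfg.seed)
    lengths = cfg.lengths()
    codes: dict[str, np.ndarray] = {}
    gc_targets: dict[str, float] = {}
    lowc: list[list] = []
    for chrom, L in lengths.items():
        gc = float(np.clip(rng.normal(0.5, cfg.gc_content_sd), 0.3, 0.7))
        gc_targets[chrom] = gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes[chrom] = rng.choice(4, size=L, p=p).astype(np.uint8)
        # low-complexity stretches: short tandem motifs
        for _ in range(cfg.lowcomplexity_per_chromosome):
            mlen = int(rng.integers(2, 4))
            motif = rng.integers(0, 4, size=mlen).astype(np.uint8)
            start = int(rng.integers(0, L - cfg.lowcomplexity_length))
            run = np.tile(motif, cfg.lowcomplexity_length // mlen + 1)[: cfg.lowcomplexity_length]
            codes[chrom][start : start + cfg.lowcomplexity_length] = run
            lowc.append([chrom, start, start + cfg.lowcomplexity_length])

    duplications: list[list] = []
    if cfg.repeat_fraction > 0:
        for chrom, L in lengths.items():
            n_blocks = int(round(cfg.repeat_fraction * L / cfg.repeat_block))
            for _ in range(n_blocks):
                src = int(rng.integers(0, L - cfg.repeat_block))
                dst = int(rng.integers(0, L - cfg.repeat_block))
                if abs(dst - src) < cfg.repeat_block:  # keep the two copies apart
                    continue
                codes[chrom][dst : dst + cfg.repeat_block] = codes[chrom][src : src + cfg.repeat_block]
                duplications.append([chrom, src, dst, cfg.repeat_block])

    par: list[list] = []
    if cfg.par_length > 0 and "chrX" in codes and "chrY" in codes:
        n = min(cfg.par_length, lengths["chrX"], lengths["chrY"])
        codes["chrY"][:n] = codes["chrX"][:n]
        par = [["chrX", 0, n], ["chrY", 0, n]]

    truth = {
        "lowcomplexity": lowc,
        "duplications": duplications,
        "par": par,
        "gc_targets": gc_targets,
    }
    return SimulatedGenome(codes=codes, truth=truth)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def simulate_variants(genome: SimulatedGenome, cfg: SimConfig, seed: int | None = None) -> VariantSet:
    """SNVs at ``snp_density`` with MAFs uniform over ``maf_range``.

    The range straddles the 1% threshold so the polymorphism filter has both
    included and excluded records to act on.
    """
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    variants = []
    for chrom, arr in genome.codes.items():
        n = rng.binomial(arr.size, cfg.snp_density)
        if n == 0:
            continue
        positions = np.sort(rng.choice(arr.size, size=n, replace=False))
        mafs = rng.uniform(*cfg.maf_range, size=n)
        for pos0, maf in zip(positions, mafs):
            ref_code = int(arr[pos0])
            alt_code = int((ref_code + rng.integers(1, 4)) % 4)
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=int(pos0) + 1,
                    ref="ACGT"[ref_code],
                    alts=("ACGT"[alt_code],),
                    maf=float(maf),
                )
            )
    return VariantSet(variants)


def write_vcf(variants: VariantSet, lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Minor allele frequency">\n')
        for chrom, L in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            alt = ",".join(v.alts)
            af = f"AF={v.maf:.6g}" if v.maf is not None else "."
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{alt}\t.\t.\t{af}\n")


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """A (possibly aneuploid) genome as chromosome -> list of haplotype copies."""

    name: str
    sex: str  # "female" | "male"
    haplotypes: dict[str, list[np.ndarray]]
    genotypes: dict[tuple[str, int], tuple[int, ...]] = field(default_factory=dict)

    def segments(self) -> list[np.ndarray]:
        return [h for copies in self.haplotypes.values() for h in copies]

    def total_length(self) -> int:
        return sum(h.size for h in self.segments())

    def copy_number(self, chrom: str) -> int:
        return len(self.haplotypes.get(chrom, []))


def _copies_for(sex: str, chrom: str) -> int:
    if chrom == "chrX":
        return 2 if sex == "female" else 1
    if chrom == "chrY":
        return 0 if sex == "female" else 1
    return 2


def simulate_individual(
    genome: SimulatedGenome,
    variants: VariantSet,
    seed: int,
    sex: str = "female",
    name: str = "individual",
    cnv: tuple[str, int, int] | None = None,
) -> Individual:
    """Diploid individual: per haplotype copy, each SNV carried with prob MAF.

    ``cnv`` plants a duplicated interval (chrom, start, end) as an extra
    segment — a copy-number gain the stability filter should reject.
    """
    rng = np.random.default_rng(seed)
    haplotypes: dict[str, list[np.ndarray]] = {}
    genotypes: dict[tuple[str, int], tuple[int, ...]] = {}
    for chrom, base in genome.codes.items():
        n_copies = _copies_for(sex, chrom)
        copies = []
        chrom_variants = variants.on_chrom(chrom)
        carried = [[] for _ in range(n_copies)]
        for ci in range(n_copies):
            hap = base.copy()
            for v in chrom_variants:
                maf = v.maf if v.maf is not None else 0.0
                carry = int(rng.random() < maf)
                carried[ci].append(carry)
                if carry:
                    hap[v.pos0] = _CODE_OF[v.alts[0]]
            copies.append(hap)
        haplotypes[chrom] = copies
        for vi, v in enumerate(chrom_variants):
            genotypes[(chrom, v.pos)] = tuple(carried[ci][vi] for ci in range(n_copies))
    if cnv is not None:
        chrom, start, end = cnv
        haplotypes[chrom].append(haplotypes[chrom][0][start:end].copy())
    return Individual(name=name, sex=sex, haplotypes=haplotypes, genotypes=genotypes)


def make_child(
    mother: Individual,
    father: Individual,
    seed: int,
    sex: str,
    trisomy: str | None = None,
    name: str = "fetus",
) -> Individual:
    """Fetal genome: one haplotype per chromosome from each parent.

    A male fetus receives the maternal X and the paternal Y; a trisomy adds a
    third copy of the affected chromosome from a random parent (meiotic
    nondisjunction).
    """
    rng = np.random.default_rng(seed)
    haplotypes: dict[str, list[np.ndarray]] = {}
    for chrom in mother.haplotypes:
        if chrom == "chrX":
            mat = mother.haplotypes[chrom][int(rng.integers(0, 2))]
            if sex == "female":
                haplotypes[chrom] = [mat, father.haplotypes["chrX"][0]]
            else:
                haplotypes[chrom] = [mat]
        elif chrom == "chrY":
            haplotypes[chrom] = [father.haplotypes["chrY"][0]] if sex == "male" else []
        else:
            mat = mother.haplotypes[chrom][int(rng.integers(0, 2))]
            pat = father.haplotypes[chrom][int(rng.integers(0, 2))]
            haplotypes[chrom] = [mat, pat]
    if trisomy is not None:
        if not haplotypes.get(trisomy):
            raise ValueError(f"cannot make trisomy of {trisomy!r}")
        parent = mother if rng.random() < 0.5 else father
        pool = parent.haplotypes[trisomy]
        haplotypes[trisomy] = haplotypes[trisomy] + [pool[int(rng.integers(0, len(pool)))]]
    return Individual(name=name, sex=sex, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_reads(
    sources: Sequence[tuple[Individual, float]],
    depth: float,
    read_length: int,
    error_rate: float,
    seed: int,
    out,
    genome_length: int,
    gc_bias_strength: float = 0.0,
    id_prefix: str = "r",
) -> int:
    """Sample single-end reads uniformly from weighted source genomes.

    ``depth`` is relative to the haploid reference (``genome_length``):
    n_reads = round(depth * genome_length / read_length). Within each source
    reads fall uniformly over all haplotype copies, so a trisomic chromosome
    carries 3/2 the read density of a disomic one. Per-base substitution
    errors at ``error_rate``; optional logistic GC acceptance bias. Returns
    the number of reads written (FASTQ, gzip if the path ends in .gz).
    """
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, w in sources], dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("source weights must be >= 0 and sum to 1")
    segs: list[np.ndarray] = []
    probs: list[float] = []
    for ind, w in sources:
        ind_segs = ind.segments()
        starts = []
        for s in ind_segs:
            if s.size < read_length:
                raise ValueError(
                    f"read_length {read_length} exceeds a chromosome segment "
                    f"({s.size} bp) of {ind.name}"
                )
            starts.append(s.size - read_length + 1)
        total = float(sum(starts))
        for s, ns in zip(ind_segs, starts):
            segs.append(s)
            probs.append(w * ns / total)
    probs_arr = np.array(probs)
    probs_arr /= probs_arr.sum()
    n_reads = int(round(depth * genome_length / read_length))

    def draw(n: int) -> np.ndarray:
        counts = rng.multinomial(n, probs_arr)
        blocks = []
        for seg, c in zip(segs, counts):
            if c == 0:
                continue
            starts = rng.integers(0, seg.size - read_length + 1, size=c)
            blocks.append(seg[starts[:, None] + np.arange(read_length)])
        reads = np.concatenate(blocks, axis=0) if blocks else np.empty((0, read_length), np.uint8)
        flip = rng.random(reads.shape[0]) < 0.5
        reads[flip] = (3 - reads[flip])[:, ::-1]
        if error_rate > 0:
            mask = rng.random(reads.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                reads[mask] = (reads[mask] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
        return reads

    reads = draw(n_reads)
    if gc_bias_strength > 0 and reads.shape[0]:
        # logistic acceptance on fragment GC, topped up to the target count
        kept = []
        need = n_reads
        batch = reads
        while need > 0:
            gcf = ((batch == 1) | (batch == 2)).mean(axis=1)
            accept = rng.random(batch.shape[0]) < 1.0 / (1.0 + np.exp(-gc_bias_strength * (gcf - 0.5)))
            batch = batch[accept]
            take = batch[:need]
            kept.append(take)
            need -= take.shape[0]
            if need > 0:
                batch = draw(max(need * 2, 64))
        reads = np.concatenate(kept, axis=0)

    close = False
    if not hasattr(out, "write"):
        path = str(out)
        if path.endswith(".gz"):
            handle = io.TextIOWrapper(gzip.GzipFile(filename="", fileobj=open(path, "wb"), mode="wb", mtime=0))
        else:
            handle = open(path, "w")
        close = True
    else:
        handle = out
    try:
        qual = "I" * read_length
        blob = reads if reads.size else reads.reshape(0, read_length)
        ascii_rows = _DECODE[blob].tobytes()
        lines = []
        for i in range(reads.shape[0]):
            seq = ascii_rows[i * read_length : (i + 1) * read_length].decode("ascii")
            lines.append(f"@{id_prefix}{i}\n{seq}\n+\n{qual}\n")
        handle.write("".join(lines))
    finally:
        if close:
            handle.close()
    return int(reads.shape[0])


def simulate_control_fastq(
    individual: Individual, cfg: SimConfig, seed: int, out
) -> int:
    """Deep-coverage whole-genome reads of one control individual."""
    return simulate_reads(
        [(individual, 1.0)],
        depth=cfg.control_depth,
        read_length=cfg.read_length,
        error_rate=cfg.error_rate,
        seed=seed,
        out=out,
        genome_length=cfg.haploid_length(),
        gc_bias_strength=cfg.gc_bias_strength,
        id_prefix=f"{individual.name}_",
    )


def simulate_nipt_sample(
    mother: Individual,
    fetus: Individual,
    fetal_fraction: float,
    cfg: SimConfig,
    seed: int,
    out,
) -> dict:
    """cfDNA mixture: maternal weight (100-n)/100, fetal weight n/100."""
    if not 0.0 <= fetal_fraction <= 100.0:
        raise ValueError(f"fetal fraction percent must be in [0, 100], got {fetal_fraction}")
    w = fetal_fraction / 100.0
    sources = [(mother, 1.0 - w), (fetus, w)] if w > 0 else [(mother, 1.0)]
    rng = np.random.default_rng(seed)
    depth = cfg.sample_depth * rng.uniform(*cfg.sample_depth_jitter)
    n = simulate_reads(
        sources,
        depth=depth,
        read_length=cfg.read_length,
        error_rate=cfg.error_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
        out=out,
        genome_length=cfg.haploid_length(),
        gc_bias_strength=cfg.gc_bias_strength,
        id_prefix="cf",
    )
    trisomy = next(
        (c for c in fetus.haplotypes if len(fetus.haplotypes[c]) == 3), None
    )
    return {
        "n_reads": n,
        "depth": depth,
        "fetal_fraction": fetal_fraction,
        "fetal_sex": fetus.sex,
        "trisomy": trisomy,
    }


def expected_weight_based_shift(
    fetal_fraction: float, cfg: SimConfig, trisomy: str, fetal_sex: str = "female"
) -> float:
    """Exact expected relative coverage elevation of the trisomic chromosome.

    Under the weight-based mixture (fetal reads = n% of the total) with
    maternal genome length G_m and trisomic fetal genome length G_f, the
    elevation of the affected chromosome relative to the disomic autosomes is

        D = 0.5 w r / (1 - w + w r),  w = n/100,  r = G_m / G_f,

    which is ~0.5 n/100 for a trisomic chromosome small against the genome
    (~0.046 at n=10 for the default toy genome). The maternal-fixed
    parametrization gives 0.5 n/(100+n) instead; see docs/methods.md.
    """
    w = fetal_fraction / 100.0
    lengths = cfg.lengths()
    # mother is female: two copies of each autosome and of X, no Y
    g_m = 2 * sum(L for c, L in lengths.items() if c != "chrY")
    if fetal_sex == "female":
        g_f = g_m + lengths[trisomy]
    else:
        g_f = g_m - lengths["chrX"] + lengths["chrY"] + lengths[trisomy]
    r = g_m / g_f
    return 0.5 * w * r / (1.0 - w + w * r)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: SimConfig,
    outdir: str | Path,
    n_reference: int = 12,
    n_euploid_tests: int = 4,
    n_trisomic_tests: int = 2,
    trisomy_chromosome: str = "chr1",
    gzip_fastq: bool = False,
) -> dict:
    """Full synthetic scenario on disk: genome, VCF, BED, controls, samples.

    Reference and test pregnancies alternate fetal sex; trisomic tests carry
    ``trisomy_chromosome`` at ``cfg.fetal_fraction``. Returns the truth
    record (also written to ``truth.json``).
    """
    outdir = Path(outdir)
    (outdir / "controls").mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    variants = simulate_variants(genome, cfg)
    fasta = outdir / "genome.fa"
    vcf = outdir / "snps.vcf"
    bed = outdir / "exclude.bed"
    genome.write_fasta(fasta)
    write_vcf(variants, genome.lengths(), vcf)
    genome.write_exclusion_bed(bed)

    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    next_seed = iter(np.random.default_rng(cfg.seed + 104729).integers(0, 2**31 - 1, size=10 + 4 * (n_reference + n_euploid_tests + n_trisomic_tests) + 2 * cfg.n_controls))

    controls = []
    for i in range(cfg.n_controls):
        sex = "male" if i % 2 == 0 else "female"
        ind = simulate_individual(genome, variants, int(next(next_seed)), sex=sex, name=f"control_{i:02d}")
        path = outdir / "controls" / f"{ind.name}{suffix}"
        simulate_control_fastq(ind, cfg, int(next(next_seed)), path)
        controls.append({"id": ind.name, "sex": sex, "fastq": str(path)})

    samples = []

    def one_pregnancy(sample_id: str, role: str, fetal_sex: str, trisomy: str | None):
        mother = simulate_individual(genome, variants, int(next(next_seed)), sex="female", name=f"{sample_id}_mother")
        father = simulate_individual(genome, variants, int(next(next_seed)), sex="male", name=f"{sample_id}_father")
        fetus = make_child(mother, father, int(next(next_seed)), sex=fetal_sex, trisomy=trisomy)
        path = outdir / "samples" / f"{sample_id}{suffix}"
        info = simulate_nipt_sample(mother, fetus, cfg.fetal_fraction, cfg, int(next(next_seed)), path)
        samples.append(
            {
                "id": sample_id,
                "role": role,
                "fetal_sex": fetal_sex,
                "trisomy": trisomy,
                "fetal_fraction": cfg.fetal_fraction,
                "fastq": str(path),
                "n_reads": info["n_reads"],
            }
        )

    for i in range(n_reference):
        one_pregnancy(f"ref_{i:03d}", "reference", "male" if i % 2 else "female", None)
    for i in range(n_euploid_tests):
        one_pregnancy(f"test_eu_{i:03d}", "test", "male" if i % 2 else "female", None)
    for i in range(n_trisomic_tests):
        one_pregnancy(f"test_tri_{i:03d}", "test", "male" if i % 2 else "female", trisomy_chromosome)

    truth = {
        "seed": cfg.seed,
        "config": {
            **{k: v for k, v in asdict(cfg).items() if not isinstance(v, np.ndarray)},
        },
        "genome": genome.lengths(),
        "files": {"fasta": str(fasta), "vcf": str(vcf), "bed": str(bed)},
        "controls": controls,
        "samples": samples,
        "trisomy_chromosome": trisomy_chromosome,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
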