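# niptkmer

Alignment-free detection of fetal autosomal trisomies from low-coverage
cell-free DNA (cfDNA) sequencing, by counting chromosome-specific unique
k-mers directly in raw reads.

Non-invasive prenatal testing (NIPT) screens for fetal aneuploidies (T13,
T18, T21) from the cfDNA in maternal plasma, a mixture of maternal and
placental (fetal) fragments. Most pipelines map reads to a reference genome
to measure per-chromosome coverage; `niptkmer` replaces mapping with a
pre-computed list of 25-mers per chromosome — each unique genome-wide, free
of common polymorphisms and problematic regions, and count-stable across
deep-sequenced control individuals — and simply counts those k-mers in the
FASTQ stream. It is written for bioinformaticians building or studying
NIPT-style coverage analyses, and validates itself end-to-end on seeded
synthetic cohorts.

## Model

Per-chromosome coverage of sample *s* is `C_sc = K_sc / L_c`, where `K_sc`
is the number of chromosome-c list k-mers observed in the reads and `L_c`
the list size. Each chromosome's expected coverage is predicted from the
other autosomes and the sample GC fraction by ordinary least squares without
intercept, fitted on euploid reference samples:

```
C'_sc = β₁C₁ + … + β_pC_p + β_GC·GC_S,      β̂ = (XᵀX)⁻¹Xᵀy
D_sc  = (C_sc − C'_sc) / C'_sc
Z_sc  = (D_sc − mean(D_ref)) / SD(D_ref)
```

A chromosome is called *elevated* (trisomy risk) when `Z_sc > 3.5`
(one-sided; configurable). If n% of the cfDNA is fetal, a full trisomy
shifts the affected chromosome's relative coverage by
`(100 + 3/2·n)/(100 + n) − 1 ≈ 0.5·n/100` — about 4.5% at a 10% fetal
fraction, which is why the regression normalization matters. Fetal sex is
decided by four sex-chromosome models (X and Y, fitted on female- and
male-fetus reference pregnancies) via the minimum joint squared z; the
Mahalanobis distance of a sample's normalized coverage profile from the
reference centroid serves as a quality-control metric. See
`docs/methods.md` for the full account.

## Worked example

Simulate a toy scenario (multi-chromosome genome, SNP set, exclusion BED,
deep-coverage controls, and cfDNA samples including trisomic ones), build
the k-mer lists, count every sample, and call:

```bash
niptkmer simulate --scenario scenario.yaml --out-dir demo
niptkmer make-lists \
    --reference demo/genome.fa --snps demo/snps.vcf --exclude demo/exclude.bed \
    --controls demo/controls/control_00.fastq --controls demo/controls/control_01.fastq \
    --out-dir demo/lists
for fq in demo/samples/*.fastq; do
    niptkmer count --lists demo/lists --fastq "$fq" \
        --out "demo/rows/$(basename "$fq" .fastq)" --sample-id "$(basename "$fq" .fastq)"
done
niptkmer merge-counts demo/rows/*.tsv --out demo/matrix
niptkmer call --matrix demo/matrix --reference-ids demo/refs.tsv \
    --cutoff 3.5 --out-prefix demo/calls
```

with `scenario.yaml` such as (depths are scaled far above real cfDNA
coverage because the toy chromosomes are ~3 orders of magnitude shorter
than human ones — see `docs/methods.md`):

```yaml
seed: 77
autosome_lengths: [20000, 18000, 16000, 14000]
x_length: 16000
y_length: 8000
sample_depth: 120.0
control_depth: 25.0
n_controls: 2
n_reference: 24
n_euploid_tests: 1
n_trisomic_tests: 1
trisomy_chromosome: chr1
```

and `refs.tsv` listing the euploid reference pregnancies as
`sample_id<TAB>fetal_sex` (fetal sexes are in `demo/truth.json`).
`make-lists` prints the final filtered list size per chromosome:

```
chr1	L_c=17714
chr2	L_c=15569
chr3	L_c=13820
chr4	L_c=11938
chrX	L_c=12247
chrY	L_c=4871
manifest_hash	ba7ac2c893802bb2eb6f76d0f6de36954a7d11f8ac44ecda2aa6ee93326a215d
```

and `call` writes `demo/calls_chromosomes.tsv` / `demo/calls_samples.tsv`
and flags the trisomic test sample:

```
ELEVATED	test_tri_000	chr1	Z=3.99
```

meaning chromosome 1 of that sample sits ~4 standard deviations above its
regression-predicted coverage — a trisomy call at the 3.5 SD cut-off. The
per-sample table carries the fetal sex call, the z-scores of X and Y under
both sex hypotheses, and the Mahalanobis QC distance.

The same workflow runs on real data by pointing `make-lists` at a reference
FASTA, a dbSNP-style VCF (allele-frequency INFO field, key configurable), a
BED of excluded regions, and deep-coverage control FASTQs — noting that
this implementation counts in memory and is sized for toy-scale validation,
not full human-genome lists.

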