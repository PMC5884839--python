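import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `naive` oracles importable

from niptkmer.aneuploidy_model import AneuploidyCaller
from niptkmer.list_builder import (
    GenomicRegionSet,
    VariantSet,
    build_chromosome_lists,
)
from niptkmer.sample_counter import ChromosomeKmerIndex, build_matrix, count_sample
from niptkmer.simdata import SimConfig, simulate_cohort


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def cohort_config() -> SimConfig:
    """Study conditions of the shared end-to-end cohort."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def toy_cohort(tmp_path_factory, cohort_config):
    """Seeded end-to-end scenario: 60 euploid references, 10 euploid tests,
    5 trisomic tests at 10% fetal fraction, pushed through list building,
    counting and model fitting once per session."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = cohort_config
    truth = simulate_cohort(
        cfg,
        outdir,
        n_reference=60,
        n_euploid_tests=10,
        n_trisomic_tests=5,
        trisomy_chromosome="chr1",
    )
    variants = VariantSet.from_vcf(truth["files"]["vcf"])
    regions = GenomicRegionSet.from_bed(truth["files"]["bed"])
    lists, manifest = build_chromosome_lists(
        truth["files"]["fasta"],
        k=cfg.k,
        variants=variants,
        regions=regions,
        control_fastqs=[c["fastq"] for c in truth["controls"]],
    )
    index = ChromosomeKmerIndex(lists, manifest_hash=manifest["hash"])
    samples = [
        count_sample(s["fastq"], index, sample_id=s["id"]) for s in truth["samples"]
    ]
    matrix = build_matrix(samples, manifest)
    reference_ids = [s["id"] for s in truth["samples"] if s["role"] == "reference"]
    sexes = {s["id"]: s["fetal_sex"] for s in truth["samples"]}
    caller = AneuploidyCaller.fit(
        matrix,
        reference_ids,
        reference_sexes={r: sexes[r] for r in reference_ids},
    )
    return {
        "config": cfg,
        "truth": truth,
        "lists": lists,
        "manifest": manifest,
        "index": index,
        "matrix": matrix,
        "reference_ids": reference_ids,
        "sexes": sexes,
        "caller": caller,
    }
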