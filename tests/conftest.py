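"""Shared fixtures: a small synthetic specimen, the 100-read QC fixture,
and the default error model. Everything is generated programmatically from
frozen seeds, so tests are deterministic and need no data files."""

from __future__ import annotations

import numpy as np
import pytest

from taxoskim.read_model import ErrorModel, Read
from taxoskim.sample import SampleConfig, make_sample, random_bases

QC_FIXTURE_SEED = 20240917
SAMPLE_SEED = 5


@pytest.fixture(scope="session")
def default_model() -> ErrorModel:
    return ErrorModel()


@pytest.fixture(scope="session")
def zero_error_model() -> ErrorModel:
    return ErrorModel(p_sub=0.0, p_ins=0.0, p_del=0.0)


@pytest.fixture(scope="session")
def small_sample(default_model):
    """A ~120 kb mixed specimen over a 20 kb target genome (frozen seed)."""
    cfg = SampleConfig(seed=SAMPLE_SEED, total_bases=120_000,
                       genome_length=20_000, gene_count=10)
    reads, labels, refs = make_sample(cfg, default_model)
    return reads, labels, refs


@pytest.fixture(scope="session")
def taxon_of_read(small_sample):
    reads, _labels, refs = small_sample
    src2tax = {r.id: r.taxon_label for r in refs.all_references()}
    return {r.id: src2tax[r.truth.source_id] for r in reads}


def make_qc_fixture_reads() -> list[Read]:
    """100 reads with broad length (80-900 bp) and quality (Q5-Q14) spread;
    frozen seed so every retained-count assertion is reproducible."""
    rng = np.random.default_rng(QC_FIXTURE_SEED)
    reads = []
    for i in range(100):
        ln = int(rng.integers(80, 901))
        base_q = int(rng.integers(5, 15))
        quals = np.clip(base_q + rng.integers(-3, 4, size=ln), 2, 30)
        reads.append(Read(f"qcfix{i:03d}", random_bases(ln, rng), quals))
    return reads


@pytest.fixture(scope="session")
def qc_fixture_reads() -> list[Read]:
    return make_qc_fixture_reads()
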