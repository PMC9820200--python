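from __future__ import annotations

import random

import pytest

from mestudio.fixtures import FixtureSpec, generate
from mestudio.formats_io import GeneRecord

IUPAC = "ACGTRYSWKMBDHVN"


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The standard planted dataset: (40, 25, 10, 5) methylated motif
    hits in (CDS, nCDS, tIG, US) with motif-free background."""
    outdir = tmp_path_factory.mktemp("fixture_default")
    return generate(FixtureSpec(seed=7), outdir)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact dataset for oracle comparisons (single replicon)."""
    spec = FixtureSpec(
        seed=11, replicon_lengths=(9_000,), n_genes=8,
        gene_length=(200, 600), gap_length=(50, 250),
        plant_counts={"CDS": 6, "nCDS": 4, "tIG": 2, "US": 2},
        unmethylated_per_category=1, n_noise_methylations=4)
    outdir = tmp_path_factory.mktemp("fixture_small")
    return generate(spec, outdir)


def random_sequence(rng: random.Random, length: int, with_n: bool = False
                    ) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    weights = [10, 10, 10, 10, 1] if with_n else None
    return "".join(rng.choices(alphabet, weights=weights, k=length))


def random_motif(rng: random.Random, max_len: int = 10,
                 max_degeneracy: int = 4096) -> str:
    """Random IUPAC motif, biased toward concrete bases so the expansion
    oracle stays cheap."""
    from mestudio.motif_core import degeneracy
    while True:
        length = rng.randint(2, max_len)
        motif = "".join(
            rng.choice(IUPAC) if rng.random() < 0.3 else rng.choice("ACGT")
            for _ in range(length))
        if degeneracy(motif) <= max_degeneracy and motif.count("N") <= 3:
            return motif


def random_annotation(rng: random.Random, seqid: str, length: int
                      ) -> list[GeneRecord]:
    """Random non-overlapping genes along one replicon."""
    genes = []
    cursor = 1
    i = 0
    while True:
        gap = rng.randint(0, 300)
        glen = rng.randint(100, 900)
        start = cursor + gap
        end = start + glen - 1
        if end > length:
            break
        i += 1
        genes.append(GeneRecord(seqid, start, end,
                                rng.choice("+-"), f"g{i:04d}",
                                f"protein {i}"))
        cursor = end + 1
    return genes
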