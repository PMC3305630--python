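"""Shared fixtures: a deterministic simulated dataset and independent
translation oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from proteoseed.refinement import refine_all
from proteoseed.synthetic import SimulationConfig, simulate_dataset

# Standard genetic code (sense translations of NCBI table 11 equal table 1;
# the tables differ only in permitted initiators).  Kept literal so tests do
# not depend on the translation machinery they are checking.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def oracle_translate(nt: str) -> str:
    """Codon-by-codon translation; unknown/ambiguous codons become X."""
    return "".join(
        CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def dataset():
    """One deterministic simulated dataset shared across read-only tests."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def refined(dataset):
    return refine_all([dataset.genome], dataset.db, dataset.annotation_published,
                      dataset.psms, transcription_evidence=dataset.transcription)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
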