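"""Shared fixtures: the reference construct layout, sample sheet, and
helpers that assemble clean (error-free) reads and random count tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import pandas as pd

from phagedeconv.amplicon import SampleMeta
from phagedeconv.deconvolve import FORWARD, REVERSE, reverse_complement
from phagedeconv.enrich import AA_ORDER, CountTable
from phagedeconv.io_seq import SeqRead
from phagedeconv.simulate import (
    assemble_library_amplicon,
    assemble_wt_amplicon,
    build_regions,
    encode_peptide_nnk,
    fixture_layout,
    fixture_sheet,
)


@pytest.fixture(scope="session")
def layout():
    return fixture_layout()


@pytest.fixture(scope="session")
def sheet():
    return fixture_sheet()


@pytest.fixture(scope="session")
def regions(layout, sheet):
    return build_regions(layout, sheet.barcodes)


def make_clean_read(
    layout,
    regions,
    barcode: str,
    peptide: str,
    rng: np.random.Generator,
    orientation: str = FORWARD,
    read_id: str = "r0",
    qual: int = 30,
) -> tuple[SeqRead, str]:
    """Assemble an error-free library read; returns (read, insert_nt)."""
    insert = encode_peptide_nnk(peptide, rng)
    seq = assemble_library_amplicon(layout, regions, barcode, insert)
    if orientation == REVERSE:
        seq = reverse_complement(seq)
    return SeqRead(read_id, seq, [qual] * len(seq)), insert


def make_wt_read(
    layout, regions, barcode: str, read_id: str = "wt0", qual: int = 30
) -> SeqRead:
    seq = assemble_wt_amplicon(layout, regions, barcode)
    return SeqRead(read_id, seq, [qual] * len(seq))


def random_peptide(rng: np.random.Generator, k: int = 12) -> str:
    letters = list(AA_ORDER)
    return "".join(letters[i] for i in rng.integers(0, len(letters), k))


def random_count_table(
    rng: np.random.Generator, n_peptides: int = 12, max_count: int = 50
) -> CountTable:
    """Random table over 3 samples (one parental), with some poly-His
    peptides mixed in so both filters have work to do."""
    samples = {
        "AAA": SampleMeta("AAA", "parental", 0, "none", False),
        "ACT": SampleMeta("ACT", "ubiquitin", 3, "slow", False),
        "ATC": SampleMeta("ATC", "nedd8", 1, "fast", False),
    }
    peptides = set()
    while len(peptides) < n_peptides:
        pep = random_peptide(rng)
        if rng.random() < 0.25:
            i = int(rng.integers(0, 10))
            pep = pep[:i] + "HHH" + pep[i + 3:]
        peptides.add(pep)
    counts = pd.DataFrame(
        rng.integers(0, max_count, (n_peptides, 3)),
        index=sorted(peptides),
        columns=list(samples),
        dtype="int64",
    )
    return CountTable(counts, samples)
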