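"""Peptide count tables, enrichment fractions and consensus summaries.

The central container is :class:`CountTable`: a peptide x sample matrix of
nonnegative read counts with per-sample metadata.  "Enrichment" of a
peptide in a sample is defined as its share of that sample's accepted
reads, which makes trajectories across panning rounds comparable despite
unequal sequencing depth per barcode.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .amplicon import SampleMeta, SampleSheet
from .deconvolve import ACCEPTED, InsertRecord

__all__ = [
    "UNASSIGNED",
    "AA_ORDER",
    "CountTable",
    "tabulate",
    "sample_fraction",
    "round_trajectory",
    "target_overlap",
    "overlap_report",
    "PositionFrequencyMatrix",
    "position_frequency_matrix",
]

#: Pseudo-sample column aggregating accepted reads whose (valid) barcode is
#: absent from the sample sheet.
UNASSIGNED = "unassigned"

#: Standard one-letter amino-acid alphabet, alphabetical.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


class CountTable:
    """Peptide x sample matrix of nonnegative integer read counts.

    Rows are kept sorted by descending total count, ties broken
    lexicographically by peptide.  Columns follow the sample-sheet order,
    with an optional trailing ``unassigned`` pseudo-sample.
    """

    def __init__(self, counts: pd.DataFrame, samples: Mapping[str, SampleMeta]):
        self.samples: dict[str, SampleMeta] = dict(samples)
        columns = [bc for bc in self.samples]
        extra = [c for c in counts.columns if c not in self.samples]
        unknown = [c for c in extra if c != UNASSIGNED]
        if unknown:
            raise ValueError(f"count columns without sample metadata: {unknown}")
        if UNASSIGNED in counts.columns:
            columns.append(UNASSIGNED)
        frame = counts.reindex(columns=columns, fill_value=0).astype("int64")
        if (frame.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        totals = frame.sum(axis=1)
        order = sorted(frame.index, key=lambda p: (-int(totals[p]), p))
        self.counts: pd.DataFrame = frame.loc[order]

    # -- views ------------------------------------------------------------

    @property
    def peptides(self) -> list[str]:
        return list(self.counts.index)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def column_sum(self, barcode: str) -> int:
        return int(self.counts[barcode].sum())

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.counts.equals(other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"CountTable({len(self.counts)} peptides x "
            f"{len(self.counts.columns)} samples, "
            f"{int(self.totals.sum())} reads)"
        )

    def drop_peptides(self, peptides: Iterable[str]) -> "CountTable":
        """New table with the given peptides removed from every sample."""
        drop = set(peptides)
        keep = [p for p in self.counts.index if p not in drop]
        return CountTable(self.counts.loc[keep], self.samples)

    def peptides_for_target(self, target: str) -> set[str]:
        """Peptides observed at least once in any sample of the given target."""
        barcodes = [bc for bc, m in self.samples.items() if m.target == target]
        if not barcodes:
            return set()
        sub = self.counts[barcodes]
        return set(sub.index[sub.sum(axis=1) > 0])


def tabulate(records: Iterable[InsertRecord], sheet: SampleSheet) -> CountTable:
    """Build a CountTable from accepted deconvolution records.

    ``counts[p][s]`` is the number of accepted records with peptide ``p``
    and the barcode of sample ``s``; accepted records whose barcode is not
    in the sheet are aggregated into the flagged ``unassigned`` column.
    """
    counter: Counter[tuple[str, str]] = Counter()
    saw_unassigned = False
    for rec in records:
        if rec.fate != ACCEPTED:
            continue
        if rec.barcode in sheet:
            col = rec.barcode
        else:
            col = UNASSIGNED
            saw_unassigned = True
        counter[(rec.peptide, col)] += 1
    columns = sheet.barcodes + ([UNASSIGNED] if saw_unassigned else [])
    peptides = sorted({p for p, _ in counter})
    frame = pd.DataFrame(0, index=peptides, columns=columns, dtype="int64")
    for (pep, col), n in counter.items():
        frame.at[pep, col] = n
    return CountTable(frame, {m.barcode: m for m in sheet})


def sample_fraction(table: CountTable, peptide: str, barcode: str) -> float:
    """Fraction of the sample's accepted reads carrying the peptide.

    Returns 0 for an empty sample column; an unknown peptide yields 0 with
    a warning.
    """
    if barcode not in table.counts.columns:
        raise KeyError(f"sample {barcode!r} not present in table")
    denom = table.column_sum(barcode)
    if denom == 0:
        return 0.0
    if peptide not in table.counts.index:
        warnings.warn(f"peptide {peptide!r} not present in table; fraction is 0")
        return 0.0
    return int(table.counts.at[peptide, barcode]) / denom


def round_trajectory(
    table: CountTable,
    peptide: str,
    target: str,
    wash: str | None = None,
    amplified: bool | None = None,
) -> list[tuple[int, int, float]]:
    """Per-round (round, count, fraction) trajectory under a fixed selector.

    Samples are selected by target and optionally wash stringency and
    amplification status; counts of multiple matching samples within one
    round are pooled, and the fraction uses the pooled round depth.  Rounds
    are returned in ascending order.  A selector matching nothing yields an
    empty list with a warning.
    """
    selected: dict[int, list[str]] = {}
    for bc, meta in table.samples.items():
        if meta.target != target:
            continue
        if wash is not None and meta.wash != wash:
            continue
        if amplified is not None and meta.amplified != amplified:
            continue
        selected.setdefault(meta.round, []).append(bc)
    if not selected:
        warnings.warn(
            f"selector (target={target!r}, wash={wash!r}, amplified={amplified!r}) "
            "matches no samples"
        )
        return []
    out: list[tuple[int, int, float]] = []
    known = peptide in table.counts.index
    for rnd in sorted(selected):
        barcodes = selected[rnd]
        denom = sum(table.column_sum(bc) for bc in barcodes)
        count = (
            int(table.counts.loc[peptide, barcodes].sum()) if known else 0
        )
        out.append((rnd, count, count / denom if denom else 0.0))
    return out


def target_overlap(
    peptides_a: set[str], peptides_b: set[str], metric: str = "jaccard"
) -> float:
    """Overlap between two targets' peptide sets.

    ``jaccard``: |A n B| / |A u B|; ``min``: |A n B| / min(|A|, |B|).
    Empty denominators are signalled as errors.
    """
    a, b = set(peptides_a), set(peptides_b)
    inter = len(a & b)
    if metric == "jaccard":
        union = len(a | b)
        if union == 0:
            raise ValueError("overlap undefined: both peptide sets are empty")
        return inter / union
    if metric == "min":
        denom = min(len(a), len(b))
        if denom == 0:
            raise ValueError("overlap undefined: a peptide set is empty")
        return inter / denom
    raise ValueError(f"unknown overlap metric {metric!r}")


def overlap_report(peptides_a: set[str], peptides_b: set[str]) -> dict[str, float]:
    """Both overlap metrics, labelled; the denominator choice is reported,
    not guessed."""
    return {
        "jaccard": target_overlap(peptides_a, peptides_b, "jaccard"),
        "min": target_overlap(peptides_a, peptides_b, "min"),
    }


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies over aligned equal-length peptides.

    ``matrix`` is a 20 x k DataFrame (rows: residues in alphabetical
    order; columns: 0-based positions) whose columns each sum to 1.
    ``consensus`` reports the modal residue per position where its
    frequency exceeds 0.5, and ``x`` otherwise (so an even two-way split
    is indeterminate, not a call).
    """

    matrix: pd.DataFrame
    consensus: str
    n_peptides: int


def position_frequency_matrix(peptides: list[str]) -> PositionFrequencyMatrix:
    """Build a position frequency matrix and consensus string.

    All peptides must have the same length and use the 20 standard
    residues; ragged input is a hard error.
    """
    peps = list(peptides)
    if not peps:
        raise ValueError("cannot build a PFM from zero peptides")
    k = len(peps[0])
    aa = set(AA_ORDER)
    for p in peps:
        if len(p) != k:
            raise ValueError(
                f"ragged peptide lengths: expected {k}, got {len(p)} for {p!r}"
            )
        bad = set(p) - aa
        if bad:
            raise ValueError(f"peptide {p!r} contains non-standard residues {sorted(bad)}")
    counts = np.zeros((len(AA_ORDER), k), dtype=float)
    index = {r: i for i, r in enumerate(AA_ORDER)}
    for p in peps:
        for j, r in enumerate(p):
            counts[index[r], j] += 1
    freqs = counts / len(peps)
    matrix = pd.DataFrame(freqs, index=list(AA_ORDER), columns=range(k))
    consensus = []
    for j in range(k):
        col = matrix[j]
        modal = col.idxmax()  # ties resolve to the alphabetically first residue
        consensus.append(modal if col[modal] > 0.5 else "x")
    return PositionFrequencyMatrix(matrix, "".join(consensus), len(peps))
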