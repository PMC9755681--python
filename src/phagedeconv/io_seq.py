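"""Sequence and tabular I/O for the deconvolution pipeline.

Supports the classic Roche 454 convention of paired ``.fasta`` + ``.qual``
files (one FASTA record per read plus a parallel record of whitespace-
separated Phred quality integers), modern single-file FASTQ (Phred+33),
and the peptide-count CSV that the downstream enrichment stage produces.

All readers stream: memory use is proportional to a single record.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from itertools import zip_longest
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SeqRead",
    "read_fasta_qual",
    "read_fastq",
    "write_fasta_qual",
    "write_fastq",
    "write_count_csv",
    "read_count_csv",
    "write_insert_tsv",
    "read_insert_tsv",
    "write_discard_summary",
]

_NON_NUCLEOTIDE = re.compile(r"[^ACGTN]")

MAX_PHRED = 93


def _normalize_bases(raw: str) -> str:
    """Upper-case, map U->T (RNA dialect), and any other symbol to N."""
    s = raw.upper().replace("U", "T")
    return _NON_NUCLEOTIDE.sub("N", s)


@dataclass
class SeqRead:
    """One sequencing read: identifier, bases and optional per-base Phred scores.

    Bases are case-normalized to upper and restricted to ``{A,C,G,T,N}``;
    any unexpected symbol becomes ``N`` on construction (tolerant ingestion;
    strictness is applied downstream by the codon validator).
    """

    read_id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        self.bases = _normalize_bases(self.bases)
        if self.quals is not None:
            self.quals = [int(q) for q in self.quals]
            if len(self.quals) != len(self.bases):
                raise ValueError(
                    f"record {self.read_id!r}: {len(self.quals)} quality values "
                    f"for {len(self.bases)} bases"
                )
            for q in self.quals:
                if not 0 <= q <= MAX_PHRED:
                    raise ValueError(
                        f"record {self.read_id!r}: Phred score {q} outside [0, {MAX_PHRED}]"
                    )

    def __len__(self) -> int:
        return len(self.bases)


def read_fasta_qual(fasta_source, qual_source) -> Iterator[SeqRead]:
    """Stream reads from paired FASTA and 454-style QUAL files.

    Records are paired by ordinal position and must agree on their IDs;
    a mismatch (or a file ending early) is a hard error naming both IDs.
    """
    fasta_it = SeqIO.parse(fasta_source, "fasta")
    qual_it = SeqIO.parse(qual_source, "qual")
    for i, (fa, qa) in enumerate(zip_longest(fasta_it, qual_it)):
        if fa is None:
            raise ValueError(
                f"record {i}: QUAL record {qa.id!r} has no FASTA counterpart"
            )
        if qa is None:
            raise ValueError(
                f"record {i}: FASTA record {fa.id!r} has no QUAL counterpart"
            )
        if fa.id != qa.id:
            raise ValueError(
                f"record {i}: FASTA id {fa.id!r} does not match QUAL id {qa.id!r}"
            )
        quals = list(qa.letter_annotations["phred_quality"])
        if len(quals) != len(fa.seq):
            raise ValueError(
                f"record {fa.id!r}: {len(quals)} quality values for "
                f"{len(fa.seq)} bases"
            )
        yield SeqRead(fa.id, str(fa.seq), quals)


def read_fastq(source) -> Iterator[SeqRead]:
    """Stream reads from a Phred+33 FASTQ file.

    Same contract as :func:`read_fasta_qual`; malformed records raise a
    hard error carrying the record ordinal.
    """
    it = SeqIO.parse(source, "fastq")
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"FASTQ record {i}: {exc}") from exc
        yield SeqRead(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        i += 1


def _to_seqrecords(reads: Iterable[SeqRead]) -> Iterator[SeqRecord]:
    for r in reads:
        if r.quals is None:
            raise ValueError(f"record {r.read_id!r} has no qualities to write")
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        yield rec


def write_fasta_qual(reads: Iterable[SeqRead], fasta_dest, qual_dest) -> int:
    """Write reads as paired FASTA + QUAL files. Returns record count."""
    records = list(_to_seqrecords(reads))
    SeqIO.write(records, fasta_dest, "fasta")
    SeqIO.write(records, qual_dest, "qual")
    return len(records)


def write_fastq(reads: Iterable[SeqRead], dest) -> int:
    """Write reads as Phred+33 FASTQ. Returns record count."""
    return SeqIO.write(_to_seqrecords(reads), dest, "fastq")


# ---------------------------------------------------------------------------
# Count-table CSV


def _sample_label(meta) -> str:
    amp = "amplified" if meta.amplified else "unamplified"
    return f"{meta.barcode}|{meta.target}|{meta.round}|{meta.wash}|{amp}"


def write_count_csv(table, destination) -> None:
    """Export a peptide x sample count table as CSV.

    One row per peptide (descending total, ties lexicographic), a ``total``
    column, then one column per sample whose header carries the sample
    metadata as ``barcode|target|round|wash|amplified``.  The dialect is
    fixed (comma separated, minimal quoting, ``\\n`` line ends) so that the
    file round-trips bit-exactly through :func:`read_count_csv`.
    """
    from .enrich import UNASSIGNED  # local import to avoid a cycle

    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        handle: IO[str] = open(destination, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, lineterminator="\n")
        header = ["peptide", "total"]
        for bc in table.barcodes:
            if bc == UNASSIGNED:
                header.append(UNASSIGNED)
            else:
                header.append(_sample_label(table.samples[bc]))
        writer.writerow(header)
        totals = table.totals
        for pep in table.peptides:
            row = [pep, int(totals[pep])]
            row.extend(int(table.counts.at[pep, bc]) for bc in table.barcodes)
            writer.writerow(row)
    finally:
        if close:
            handle.close()


def read_count_csv(source):
    """Re-read a count CSV written by :func:`write_count_csv` into a CountTable."""
    import pandas as pd

    from .amplicon import SampleMeta
    from .enrich import UNASSIGNED, CountTable

    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle: IO[str] = open(source, encoding="utf-8", newline="")
        close = True
    else:
        handle = source
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise ValueError("empty count CSV: no header row") from exc
        if header[:2] != ["peptide", "total"]:
            raise ValueError("count CSV must start with 'peptide,total' columns")
        samples: dict[str, SampleMeta] = {}
        barcodes: list[str] = []
        for label in header[2:]:
            if label == UNASSIGNED:
                barcodes.append(UNASSIGNED)
                continue
            parts = label.split("|")
            if len(parts) != 5:
                raise ValueError(f"malformed sample header {label!r}")
            bc, target, rnd, wash, amp = parts
            samples[bc] = SampleMeta(
                barcode=bc,
                target=target,
                round=int(rnd),
                wash=wash,
                amplified=(amp == "amplified"),
            )
            barcodes.append(bc)
        peptides: list[str] = []
        rows: list[list[int]] = []
        for row in reader:
            if not row:
                continue
            pep, total, *counts = row
            counts_i = [int(c) for c in counts]
            if int(total) != sum(counts_i):
                raise ValueError(f"peptide {pep!r}: total column does not match row sum")
            peptides.append(pep)
            rows.append(counts_i)
        frame = pd.DataFrame(rows, index=peptides, columns=barcodes, dtype="int64")
        return CountTable(frame, samples)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Per-read record TSV and discard summary

_RECORD_FIELDS = [
    "read_id",
    "fate",
    "discard_reason",
    "orientation",
    "barcode",
    "assigned",
    "raw_insert",
    "insert_nt",
    "peptide",
]


def write_insert_tsv(records, destination) -> None:
    """Write per-read deconvolution records as TSV (one line per input read)."""
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        handle: IO[str] = open(destination, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_RECORD_FIELDS)
        for rec in records:
            writer.writerow(
                [
                    rec.read_id,
                    rec.fate,
                    rec.discard_reason or "",
                    rec.orientation or "",
                    rec.barcode or "",
                    "" if rec.assigned is None else str(rec.assigned).lower(),
                    rec.raw_insert or "",
                    rec.insert_nt or "",
                    rec.peptide or "",
                ]
            )
    finally:
        if close:
            handle.close()


def read_insert_tsv(source) -> Iterator:
    """Stream InsertRecords back from a TSV written by :func:`write_insert_tsv`."""
    from .deconvolve import InsertRecord

    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle: IO[str] = open(source, encoding="utf-8", newline="")
        close = True
    else:
        handle = source
    try:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if header != _RECORD_FIELDS:
            raise ValueError("unrecognized insert-record TSV header")
        for row in reader:
            if not row:
                continue
            d = dict(zip(_RECORD_FIELDS, row))
            yield InsertRecord(
                read_id=d["read_id"],
                fate=d["fate"],
                discard_reason=d["discard_reason"] or None,
                orientation=d["orientation"] or None,
                barcode=d["barcode"] or None,
                assigned=None if d["assigned"] == "" else d["assigned"] == "true",
                raw_insert=d["raw_insert"] or None,
                insert_nt=d["insert_nt"] or None,
                peptide=d["peptide"] or None,
            )
    finally:
        if close:
            handle.close()


def write_discard_summary(summary: dict[str, int], destination) -> None:
    """Write an ``outcome\\tcount`` TSV summarising read fates."""
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        handle: IO[str] = open(destination, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["outcome", "count"])
        for key in sorted(summary):
            writer.writerow([key, summary[key]])
    finally:
        if close:
            handle.close()
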