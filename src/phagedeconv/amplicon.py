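"""Amplicon architecture of a barcoded phage-display construct.

A Ph.D.-12 style amplicon reads, 5'->3' on the forward strand::

    [fwd primer ... anchor][barcode][vector][left border][insert 3k nt]
    [right border = spacer][gIII / adapter ...][rc(barcode)][rc(rev anchor)]

The inline trinucleotide barcode sits immediately 3' of the matched primer
anchor on whichever strand the read starts from, so demultiplexing is
positional: anchor match fixes the frame, the next ``barcode_length`` bases
are the sample tag.  A wild-type (insert-less) phage lacks both the random
insert and the spacer, shortening the amplicon by ``3*(insert_codons +
spacer_codons)`` nucleotides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Mapping

import yaml

__all__ = [
    "ConstructLayout",
    "SampleMeta",
    "SampleSheet",
    "WASH_LABELS",
    "amplicon_length",
    "insert_nt_length",
    "min_read_length",
    "load_layout",
    "write_layout",
    "load_sample_sheet",
    "write_sample_sheet",
]

WASH_LABELS = frozenset({"fast", "slow", "none"})

_DNA = frozenset("ACGT")


def _check_dna(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be a nonempty A/C/G/T string")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{name} contains non-nucleotide characters: {sorted(bad)}")


@dataclass(frozen=True)
class ConstructLayout:
    """The amplicon architecture: anchors, barcode slot, borders, insert size.

    Parameters
    ----------
    fwd_anchor, rev_anchor
        Exact-match primer fragments immediately 5' of the barcode slot on
        forward and reverse reads respectively.  When longer than
        ``anchor_min_length``, only the 3'-most ``anchor_min_length`` bases
        (those adjacent to the barcode) are used for matching.
    left_border, right_border
        Constant sequences directly flanking the variable region; the right
        border is the start of the spacer-coding sequence.
    insert_codons
        Number of randomized codons (12 for a Ph.D.-12 library).
    spacer_codons
        Length of the peptide-gIII spacer in codons (4: Gly-Gly-Gly-Ser).
    wt_amplicon_length
        Length in nt of the amplicon from a wild-type (insert-less) phage.
    """

    fwd_anchor: str
    rev_anchor: str
    left_border: str
    right_border: str
    barcode_length: int = 3
    insert_codons: int = 12
    spacer_codons: int = 4
    wt_amplicon_length: int = 381
    anchor_min_length: int = 12

    def __post_init__(self) -> None:
        for name in ("fwd_anchor", "rev_anchor", "left_border", "right_border"):
            _check_dna(name, getattr(self, name))
        if self.insert_codons < 1:
            raise ValueError("insert_codons must be >= 1")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if self.spacer_codons < 0:
            raise ValueError("spacer_codons must be >= 0")
        if self.anchor_min_length < 1:
            raise ValueError("anchor_min_length must be >= 1")
        if (
            self.left_border in self.right_border
            or self.right_border in self.left_border
        ):
            raise ValueError("left_border and right_border must not contain each other")

    @property
    def fwd_anchor_match(self) -> str:
        """Fragment of the forward anchor used for exact matching (3' end)."""
        return self.fwd_anchor[-self.anchor_min_length:]

    @property
    def rev_anchor_match(self) -> str:
        """Fragment of the reverse anchor used for exact matching (3' end)."""
        return self.rev_anchor[-self.anchor_min_length:]


def amplicon_length(layout: ConstructLayout, with_insert: bool) -> int:
    """Length in nt of the PCR amplicon, with or without the peptide insert.

    An insert-bearing clone carries ``3*insert_codons`` nt of variable
    region plus ``3*spacer_codons`` nt of spacer that the wild-type phage
    lacks.
    """
    if not with_insert:
        return layout.wt_amplicon_length
    return layout.wt_amplicon_length + 3 * (layout.insert_codons + layout.spacer_codons)


def insert_nt_length(layout: ConstructLayout) -> int:
    """Length in nt of the variable region (3 nt per randomized codon)."""
    return 3 * layout.insert_codons


def min_read_length(layout: ConstructLayout) -> int:
    """Shortest read that could still contain the whole variable region."""
    shorter_anchor = min(len(layout.fwd_anchor_match), len(layout.rev_anchor_match))
    return (
        shorter_anchor
        + layout.barcode_length
        + len(layout.left_border)
        + insert_nt_length(layout)
        + len(layout.right_border)
    )


_LAYOUT_FIELDS = (
    "fwd_anchor",
    "rev_anchor",
    "left_border",
    "right_border",
    "barcode_length",
    "insert_codons",
    "spacer_codons",
    "wt_amplicon_length",
    "anchor_min_length",
)


def load_layout(source) -> ConstructLayout:
    """Load a ConstructLayout from a flat key-value (YAML) config file."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
    else:
        data = yaml.safe_load(source)
    if not isinstance(data, dict):
        raise ValueError("layout config must be a flat key-value mapping")
    unknown = set(data) - set(_LAYOUT_FIELDS)
    if unknown:
        raise ValueError(f"unknown layout keys: {sorted(unknown)}")
    return ConstructLayout(**data)


def write_layout(layout: ConstructLayout, destination) -> None:
    data = {f: getattr(layout, f) for f in _LAYOUT_FIELDS}
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        with open(destination, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)
    else:
        yaml.safe_dump(data, destination, sort_keys=False)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one barcoded sample of the pooled sequencing run."""

    barcode: str
    target: str
    round: int
    wash: str
    amplified: bool

    def __post_init__(self) -> None:
        _check_dna("barcode", self.barcode)
        if self.wash not in WASH_LABELS:
            raise ValueError(
                f"unknown wash label {self.wash!r} (expected one of {sorted(WASH_LABELS)})"
            )
        if self.round < 0:
            raise ValueError("round must be >= 0 (0 denotes the unpanned parental library)")


class SampleSheet:
    """Barcode -> sample metadata mapping for one sequencing pool.

    Barcodes are unique and at most one entry may carry the ``parental``
    target (the unpanned input library, conventionally round 0).
    """

    def __init__(self, entries: list[SampleMeta] | Mapping[str, SampleMeta]):
        if isinstance(entries, Mapping):
            entries = list(entries.values())
        self.entries: dict[str, SampleMeta] = {}
        for meta in entries:
            if meta.barcode in self.entries:
                raise ValueError(f"duplicate barcode {meta.barcode!r} in sample sheet")
            self.entries[meta.barcode] = meta
        parental = [m for m in self.entries.values() if m.target == "parental"]
        if len(parental) > 1:
            raise ValueError("sample sheet may contain at most one parental entry")

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries

    def __getitem__(self, barcode: str) -> SampleMeta:
        return self.entries[barcode]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcodes(self) -> list[str]:
        return list(self.entries)

    @property
    def parental(self) -> SampleMeta | None:
        """The parental-library entry, if one is declared."""
        for meta in self.entries.values():
            if meta.target == "parental":
                return meta
        for meta in self.entries.values():
            if meta.round == 0:
                return meta
        return None


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def load_sample_sheet(source, layout: ConstructLayout) -> SampleSheet:
    """Load and validate a sample sheet from CSV/TSV.

    Required columns: ``barcode,target,round,wash,amplified``.  The
    delimiter (comma or tab) is auto-detected from the header line.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle: IO[str] = open(source, encoding="utf-8", newline="")
        close = True
    else:
        handle = source
    try:
        first = handle.readline()
        if not first:
            raise ValueError("empty sample sheet")
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
        header = [h.strip() for h in first.rstrip("\n").split(delimiter)]
        required = ["barcode", "target", "round", "wash", "amplified"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        reader = csv.DictReader(handle, fieldnames=header, delimiter=delimiter)
        entries: list[SampleMeta] = []
        for row in reader:
            if all(not (v or "").strip() for v in row.values()):
                continue
            barcode = row["barcode"].strip().upper()
            if len(barcode) != layout.barcode_length:
                raise ValueError(
                    f"barcode {barcode!r} has length {len(barcode)}; layout "
                    f"expects {layout.barcode_length}"
                )
            entries.append(
                SampleMeta(
                    barcode=barcode,
                    target=row["target"].strip(),
                    round=int(row["round"]),
                    wash=row["wash"].strip(),
                    amplified=_parse_bool(row["amplified"]),
                )
            )
        return SampleSheet(entries)
    finally:
        if close:
            handle.close()


def write_sample_sheet(sheet: SampleSheet, destination) -> None:
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        handle: IO[str] = open(destination, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["barcode", "target", "round", "wash", "amplified"])
        for meta in sheet:
            writer.writerow(
                [meta.barcode, meta.target, meta.round, meta.wash,
                 "true" if meta.amplified else "false"]
            )
    finally:
        if close:
            handle.close()
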