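"""Per-read extraction of barcoded peptide inserts.

Each read is pushed through six ordered steps; the first failure fixes the
read's fate:

1. length prefilter — reads too short to contain the whole variable region
   are discarded;
2. orientation + barcode — the 5' end is scanned for an exact occurrence of
   the forward or reverse primer anchor; the ``barcode_length`` bases
   immediately 3' of the matched anchor are the sample tag;
3. insert extraction — the variable region is cut out between exact matches
   of the constant border sequences (reverse reads are searched with the
   reverse-complemented borders and the extract is flipped back to
   message sense);
4. quality-guided repair — an over-length extract is trimmed back to
   ``3*insert_codons`` nt by iteratively dropping the lowest-quality base;
   an under-length extract is discarded;
5. codon validation — every codon must belong to the NNK degenerate scheme
   (third base G or T) and no stop codon may appear (the amber codon TAG is
   configurable: reject, or suppress to Gln as in supE hosts);
6. translation — standard genetic code, one residue per codon.

All matching is exact; there is no fuzzy primer matching or quality
trimming beyond the repair step.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Data.CodonTable import standard_dna_table

from .amplicon import ConstructLayout, SampleSheet, min_read_length
from .io_seq import SeqRead

__all__ = [
    "InsertRecord",
    "FORWARD",
    "REVERSE",
    "ACCEPTED",
    "DISCARDED",
    "DISCARD_REASONS",
    "NNK_CODONS",
    "STOP_CODONS",
    "reverse_complement",
    "length_prefilter",
    "orient_and_barcode",
    "extract_insert",
    "repair_insert",
    "validate_codons",
    "translate_insert",
    "deconvolve_read",
    "deconvolve_stream",
    "summarize_fates",
]

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"
ACCEPTED = "accepted"
DISCARDED = "discarded"

TOO_SHORT = "too_short"
NO_ANCHOR_MATCH = "no_anchor_match"
INCOMPLETE_BARCODE = "incomplete_barcode"
BORDER_NOT_FOUND = "border_not_found"
UNDER_LENGTH = "under_length"
REPAIR_FAILED = "repair_failed"
CODON_INVALID = "codon_invalid"
STOP_CODON = "stop_codon"
AMBIGUOUS_ORIENTATION = "ambiguous_orientation"

DISCARD_REASONS = (
    TOO_SHORT,
    NO_ANCHOR_MATCH,
    INCOMPLETE_BARCODE,
    BORDER_NOT_FOUND,
    UNDER_LENGTH,
    REPAIR_FAILED,
    CODON_INVALID,
    STOP_CODON,
    AMBIGUOUS_ORIENTATION,
)

#: The 32 NNK codons: any base at positions 1-2, G or T at position 3.
NNK_CODONS = frozenset(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class InsertRecord:
    """Outcome of deconvolving one read.

    ``fate`` is ``accepted`` or ``discarded``; a discarded record carries a
    ``discard_reason`` and no peptide.  For reverse reads ``insert_nt`` is
    stored in forward (message-sense) orientation.  ``assigned`` is False
    when the barcode is valid but absent from the sample sheet (the record
    is retained, not discarded).
    """

    read_id: str
    fate: str
    discard_reason: str | None = None
    orientation: str | None = None
    barcode: str | None = None
    assigned: bool | None = None
    raw_insert: str | None = None
    insert_nt: str | None = None
    peptide: str | None = None


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement non-nucleotide characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def length_prefilter(read: SeqRead, layout: ConstructLayout) -> bool:
    """True iff the read is long enough to contain the whole variable region."""
    return len(read.bases) >= min_read_length(layout)


def _locate_anchor(bases: str, anchor: str, barcode_length: int) -> int:
    """Index just past an anchor occurring wholly within the 5' search window,
    or -1.  Window = first (anchor length + barcode_length + 8) bases."""
    window_end = len(anchor) + barcode_length + 8
    pos = bases.find(anchor, 0, window_end)
    return -1 if pos < 0 else pos + len(anchor)


def orient_and_barcode(read: SeqRead, layout: ConstructLayout):
    """Determine read orientation and extract the inline barcode.

    Returns ``(orientation, barcode)`` or a discard reason string:
    ``no_anchor_match`` if neither anchor occurs in the 5' window,
    ``ambiguous_orientation`` if both do, ``incomplete_barcode`` if fewer
    than ``barcode_length`` bases (or any N) follow the anchor.
    """
    bases = read.bases
    bl = layout.barcode_length
    fwd_end = _locate_anchor(bases, layout.fwd_anchor_match, bl)
    rev_end = _locate_anchor(bases, layout.rev_anchor_match, bl)
    if fwd_end < 0 and rev_end < 0:
        return NO_ANCHOR_MATCH
    if fwd_end >= 0 and rev_end >= 0:
        return AMBIGUOUS_ORIENTATION
    orientation = FORWARD if fwd_end >= 0 else REVERSE
    anchor_end = fwd_end if fwd_end >= 0 else rev_end
    barcode = bases[anchor_end:anchor_end + bl]
    if len(barcode) < bl or "N" in barcode:
        return INCOMPLETE_BARCODE
    return orientation, barcode


def extract_insert(read: SeqRead, orientation: str, layout: ConstructLayout):
    """Extract the variable region between the border sequences.

    Returns ``(raw_insert, raw_quals)`` in message-sense orientation (raw
    quals reversed for reverse reads, or None when the read carries no
    qualities), or the string ``border_not_found``.

    Forward reads: substring strictly between the first occurrence of
    ``left_border`` after the barcode and the next following occurrence of
    ``right_border``.  Reverse reads: the same single-pass scan with both
    borders reverse-complemented (the downstream border is then encountered
    first), after which the extract is reverse-complemented back.
    """
    bases = read.bases
    bl = layout.barcode_length
    if orientation == FORWARD:
        anchor_end = _locate_anchor(bases, layout.fwd_anchor_match, bl)
        first, second = layout.left_border, layout.right_border
    elif orientation == REVERSE:
        anchor_end = _locate_anchor(bases, layout.rev_anchor_match, bl)
        first = reverse_complement(layout.right_border)
        second = reverse_complement(layout.left_border)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if anchor_end < 0:
        raise ValueError("extract_insert called on a read without an anchor match")
    search_from = anchor_end + bl
    i = bases.find(first, search_from)
    if i < 0:
        return BORDER_NOT_FOUND
    start = i + len(first)
    j = bases.find(second, start)
    if j < 0:
        return BORDER_NOT_FOUND
    raw = bases[start:j]
    quals = None if read.quals is None else read.quals[start:j]
    if orientation == REVERSE:
        raw = reverse_complement(raw)
        quals = None if quals is None else quals[::-1]
    return raw, quals


def repair_insert(
    raw_insert: str,
    raw_quals: list[int] | None,
    layout: ConstructLayout,
    tie: str = "threeprime",
):
    """Trim an over-length extract back to the expected insert length.

    Returns ``(insert_nt, None)`` on success or ``(None, reason)`` with
    reason ``under_length`` (too short to repair) or ``repair_failed``
    (over-length but no qualities available).

    Repair iteratively removes the single base with the current minimum
    quality, re-evaluating after each removal, until the target length is
    reached.  Ties on the minimum are broken toward the 3' end by default
    (454 quality degrades toward 3'), or toward the 5' end with
    ``tie='fiveprime'``.
    """
    target = 3 * layout.insert_codons
    n = len(raw_insert)
    if n == target:
        return raw_insert, None
    if n < target:
        return None, UNDER_LENGTH
    if raw_quals is None:
        return None, REPAIR_FAILED
    if tie not in ("threeprime", "fiveprime"):
        raise ValueError(f"unknown tie rule {tie!r}")
    bases = list(raw_insert)
    quals = list(raw_quals)
    while len(bases) > target:
        qmin = min(quals)
        if tie == "threeprime":
            idx = len(quals) - 1 - quals[::-1].index(qmin)
        else:
            idx = quals.index(qmin)
        del bases[idx]
        del quals[idx]
    return "".join(bases), None


def validate_codons(
    insert_nt: str, scheme: str = "NNK", amber_policy: str = "reject"
) -> str | None:
    """Check every codon of the insert against the library's codon scheme.

    Returns None on pass, or ``stop_codon`` / ``codon_invalid``.  Codons
    are checked left to right; a stop codon takes precedence over a scheme
    violation for the same codon.  Under ``amber_policy='suppress'`` the
    amber codon TAG is allowed (it is the single NNK stop, read through as
    Gln in supE hosts).  Any N renders the codon invalid.
    """
    if scheme != "NNK":
        raise ValueError(f"unsupported codon scheme {scheme!r}")
    if len(insert_nt) % 3:
        raise ValueError(
            f"insert length {len(insert_nt)} is not a multiple of 3"
        )
    for i in range(0, len(insert_nt), 3):
        codon = insert_nt[i:i + 3]
        if "N" in codon:
            return CODON_INVALID
        if codon in STOP_CODONS and not (
            codon == "TAG" and amber_policy == "suppress"
        ):
            return STOP_CODON
        if codon not in NNK_CODONS:
            return CODON_INVALID
    return None


def translate_insert(insert_nt: str, amber_policy: str = "reject") -> str:
    """Translate a validated insert with the standard genetic code.

    With ``amber_policy='suppress'`` the amber codon TAG translates to Q.
    Any other stop codon (impossible after validation) is a hard error.
    """
    if len(insert_nt) % 3:
        raise ValueError(f"insert length {len(insert_nt)} is not a multiple of 3")
    residues = []
    for i in range(0, len(insert_nt), 3):
        codon = insert_nt[i:i + 3]
        aa = standard_dna_table.forward_table.get(codon)
        if aa is None:
            if codon == "TAG" and amber_policy == "suppress":
                aa = "Q"
            else:
                raise ValueError(f"untranslatable codon {codon!r} at position {i}")
        residues.append(aa)
    return "".join(residues)


def deconvolve_read(
    read: SeqRead,
    layout: ConstructLayout,
    sheet: SampleSheet | None = None,
    *,
    amber_policy: str = "reject",
    repair_tie: str = "threeprime",
) -> InsertRecord:
    """Run the full six-step extraction on one read.

    Always returns exactly one :class:`InsertRecord`; the first failing
    step fixes ``fate`` and ``discard_reason``.  Barcodes absent from the
    sample sheet are retained but flagged ``assigned=False``.
    """
    rec = InsertRecord(read_id=read.read_id, fate=DISCARDED)

    if not length_prefilter(read, layout):
        rec.discard_reason = TOO_SHORT
        return rec

    oriented = orient_and_barcode(read, layout)
    if isinstance(oriented, str):
        rec.discard_reason = oriented
        return rec
    rec.orientation, rec.barcode = oriented
    if sheet is not None:
        rec.assigned = rec.barcode in sheet

    extracted = extract_insert(read, rec.orientation, layout)
    if isinstance(extracted, str):
        rec.discard_reason = extracted
        return rec
    rec.raw_insert, raw_quals = extracted

    insert_nt, reason = repair_insert(rec.raw_insert, raw_quals, layout, tie=repair_tie)
    if insert_nt is None:
        rec.discard_reason = reason
        return rec

    reason = validate_codons(insert_nt, amber_policy=amber_policy)
    if reason is not None:
        rec.discard_reason = reason
        return rec

    rec.insert_nt = insert_nt
    rec.peptide = translate_insert(insert_nt, amber_policy=amber_policy)
    rec.fate = ACCEPTED
    rec.discard_reason = None
    return rec


def deconvolve_stream(
    reads: Iterable[SeqRead],
    layout: ConstructLayout,
    sheet: SampleSheet | None = None,
    **options,
) -> Iterator[InsertRecord]:
    """Deconvolve a stream of reads, yielding one record per read."""
    for read in reads:
        rec = deconvolve_read(read, layout, sheet, **options)
        logger.debug("read %s -> %s%s", rec.read_id, rec.fate,
                     f" ({rec.discard_reason})" if rec.discard_reason else "")
        yield rec


def summarize_fates(records: Iterable[InsertRecord]) -> dict[str, int]:
    """Count records by outcome: ``accepted`` plus one key per discard reason.

    The counts always partition the input: their sum equals the number of
    records.
    """
    counter: Counter[str] = Counter()
    for rec in records:
        counter[rec.discard_reason if rec.fate == DISCARDED else ACCEPTED] += 1
    return dict(counter)
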