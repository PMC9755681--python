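"""Synthetic 454-style amplicon reads with known composition.

The simulator emits full-length amplicon reads of a barcoded Ph.D.-12
style construct so that every pipeline stage can be tested against ground
truth.  It emulates the features of the platform and experiment that the
extraction algorithm must cope with:

* inline trinucleotide barcodes on both primers, read on either strand
  (reads are emitted forward or reverse-complemented with equal
  probability);
* NNK-encoded random 12-mer inserts flanked by constant borders, with the
  Gly-Gly-Gly-Ser spacer immediately 3' of the insert;
* wild-type (insert-less) phage contamination, whose amplicon lacks the
  insert and the spacer;
* per-base substitution errors and the platform's dominant error mode,
  +/-1 homopolymer-length errors; inserted bases carry a conspicuously
  low quality score so that quality-guided repair is exercised
  realistically.

Everything is deterministic given the config seed: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .amplicon import ConstructLayout, SampleMeta, SampleSheet
from .deconvolve import FORWARD, NNK_CODONS, REVERSE, reverse_complement
from .io_seq import SeqRead, write_fasta_qual, write_fastq

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConstructRegions",
    "encode_peptide_nnk",
    "build_regions",
    "assemble_library_amplicon",
    "assemble_wt_amplicon",
    "simulate_reads",
    "fixture_layout",
    "fixture_sheet",
    "fixture_spectra",
    "fixture_config",
    "FIXTURE_PEPTIDES",
]

# NNK codons per residue (TAG excluded so encodings always pass validation
# under the strict amber policy).  Tryptophan has the single codon TGG.
_NNK_BY_AA: dict[str, list[str]] = {}
for _codon in sorted(NNK_CODONS):
    _aa = standard_dna_table.forward_table.get(_codon)
    if _aa is not None:
        _NNK_BY_AA.setdefault(_aa, []).append(_codon)


def encode_peptide_nnk(peptide: str, rng: np.random.Generator) -> str:
    """Encode a peptide as DNA, drawing a uniform NNK codon per residue.

    The output always passes codon validation with the amber codon
    rejected, and translates back to the input peptide for any seed.
    """
    codons = []
    for res in peptide:
        options = _NNK_BY_AA.get(res)
        if options is None:
            raise ValueError(f"cannot NNK-encode non-standard residue {res!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Construct assembly


@dataclass(frozen=True)
class ConstructRegions:
    """The invariant filler sequences of the simulated construct.

    ``pre_left`` sits between the barcode and the left border (vector
    sequence); ``downstream`` spans spacer-to-reverse-primer (gIII plus
    adapter).  Both are fixed properties of the construct, generated once
    per layout and checked to create no spurious anchor or border
    occurrences with any sample barcode.
    """

    pre_left: str
    downstream: str


_BASES = np.frombuffer(b"ACGT", dtype="S1")
_REGION_SEED = 20101454  # construct sequence is a constant, not a per-run draw


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def assemble_library_amplicon(
    layout: ConstructLayout, regions: ConstructRegions, barcode: str, insert: str
) -> str:
    """Forward-strand amplicon of an insert-bearing clone."""
    return (
        layout.fwd_anchor
        + barcode
        + regions.pre_left
        + layout.left_border
        + insert
        + layout.right_border
        + regions.downstream
        + reverse_complement(barcode)
        + reverse_complement(layout.rev_anchor)
    )


def assemble_wt_amplicon(
    layout: ConstructLayout, regions: ConstructRegions, barcode: str
) -> str:
    """Forward-strand amplicon of a wild-type phage: no insert, no spacer."""
    return (
        layout.fwd_anchor
        + barcode
        + regions.pre_left
        + layout.left_border
        + regions.downstream
        + reverse_complement(barcode)
        + reverse_complement(layout.rev_anchor)
    )


def _regions_ok(
    layout: ConstructLayout, regions: ConstructRegions, barcodes: list[str]
) -> bool:
    lb, rb = layout.left_border, layout.right_border
    fwd_m, rev_m = layout.fwd_anchor_match, layout.rev_anchor_match
    dummy = "GCT" * layout.insert_codons
    motifs = {lb, rb, reverse_complement(lb), reverse_complement(rb),
              fwd_m, rev_m, reverse_complement(fwd_m), reverse_complement(rev_m)}
    if any(m in dummy for m in motifs):
        dummy = "TGT" * layout.insert_codons
    for bc in barcodes:
        lib = assemble_library_amplicon(layout, regions, bc, dummy)
        wt = assemble_wt_amplicon(layout, regions, bc)
        checks = (
            lib.count(lb) == 1
            and lib.count(rb) == 1
            and lib.count(reverse_complement(lb)) == 0
            and lib.count(reverse_complement(rb)) == 0
            and lib.count(fwd_m) == 1
            and lib.count(rev_m) == 0
            and lib.count(reverse_complement(fwd_m)) == 0
            and lib.count(reverse_complement(rev_m)) == 1
            and wt.count(lb) == 1
            and wt.count(rb) == 0
            and wt.count(reverse_complement(lb)) == 0
            and wt.count(reverse_complement(rb)) == 0
            and wt.count(fwd_m) == 1
            and wt.count(rev_m) == 0
            and wt.count(reverse_complement(fwd_m)) == 0
            and wt.count(reverse_complement(rev_m)) == 1
        )
        if not checks:
            return False
    return True


_REGION_CACHE: dict[tuple, ConstructRegions] = {}


def build_regions(layout: ConstructLayout, barcodes: list[str]) -> ConstructRegions:
    """Deterministic filler sequences sized so that the assembled amplicons
    match the layout's nominal lengths (wild type and insert-bearing).

    The wild-type amplicon must total ``wt_amplicon_length`` nt, so the two
    fillers share the slack left after anchors, barcodes and the left
    border.  Generation retries (deterministically) until no filler creates
    a spurious border or anchor occurrence with any of the given barcodes.
    """
    key = (layout, tuple(sorted(set(barcodes))))
    cached = _REGION_CACHE.get(key)
    if cached is not None:
        return cached
    fixed = (
        len(layout.fwd_anchor)
        + 2 * layout.barcode_length
        + len(layout.left_border)
        + len(layout.rev_anchor)
    )
    slack = layout.wt_amplicon_length - fixed
    if slack < 0:
        raise ValueError(
            "wt_amplicon_length too short for the layout's constant regions"
        )
    pre_len = min(30, slack)
    down_len = slack - pre_len
    rng = np.random.default_rng(_REGION_SEED)
    for _ in range(500):
        regions = ConstructRegions(
            pre_left=_random_dna(rng, pre_len),
            downstream=_random_dna(rng, down_len),
        )
        if _regions_ok(layout, regions, list(barcodes)):
            _REGION_CACHE[key] = regions
            return regions
    raise RuntimeError("could not generate clean construct filler sequences")


# ---------------------------------------------------------------------------
# Simulation config and ground truth


@dataclass
class SimConfig:
    """Generative settings for one simulated sequencing run.

    ``spectra`` maps each sample barcode to its peptide -> read count
    spectrum (expected counts; each planned read may be replaced by a
    wild-type read with probability ``wt_rate``).  Error rates are per base
    (``sub_rate``) and per homopolymer run (``homopolymer_indel_rate``,
    +/-1 length with equal probability).  Base qualities follow a linear
    Phred ramp ``qual_mean + qual_slope * position`` with +/-2 jitter,
    clamped to [20, 40]; substituted bases are flagged at quality 10 and
    inserted bases at quality 6, strictly below any correct base.
    """

    layout: ConstructLayout
    sheet: SampleSheet
    spectra: dict[str, dict[str, int]]
    wt_rate: float = 0.05
    sub_rate: float = 0.002
    homopolymer_indel_rate: float = 0.003
    qual_mean: float = 34.0
    qual_slope: float = -0.02
    sub_qual: int = 10
    indel_qual: int = 6
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("wt_rate", "sub_rate", "homopolymer_indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for bc, spectrum in self.spectra.items():
            if bc not in self.sheet:
                raise ValueError(f"spectra barcode {bc!r} not in sample sheet")
            for pep, n in spectrum.items():
                if n < 0:
                    raise ValueError(f"negative depth for {pep!r} in sample {bc!r}")


@dataclass
class GroundTruth:
    """True per-sample composition and per-read provenance of a simulation."""

    counts: dict[str, Counter]
    wt_counts: dict[str, int]
    reads: list[tuple] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def to_count_table(self, sheet: SampleSheet):
        """The emitted library-read counts as a CountTable (for comparison
        with the pipeline's tabulation)."""
        import pandas as pd

        from .enrich import CountTable

        peptides = sorted({p for c in self.counts.values() for p in c})
        frame = pd.DataFrame(0, index=peptides, columns=sheet.barcodes, dtype="int64")
        for bc, counter in self.counts.items():
            for pep, n in counter.items():
                frame.at[pep, bc] = n
        return CountTable(frame, {m.barcode: m for m in sheet})

    def write_tsv(self, destination) -> None:
        import csv

        close = False
        if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
            handle = open(destination, "w", encoding="utf-8", newline="")
            close = True
        else:
            handle = destination
        try:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["read_id", "barcode", "kind", "peptide", "orientation",
                 "n_sub", "n_ins", "n_del"]
            )
            for row in self.reads:
                writer.writerow(row)
        finally:
            if close:
                handle.close()


def _apply_errors(
    seq: str, rng: np.random.Generator, config: SimConfig
) -> tuple[str, list[int], int, int, int]:
    """Inject substitution and homopolymer +/-1 errors; return the called
    bases, their qualities and the error tallies."""
    n = len(seq)
    ramp = np.rint(config.qual_mean + config.qual_slope * np.arange(n)).astype(int)
    quals_arr = np.clip(ramp + rng.integers(-2, 3, n), 20, 40)
    bases = list(seq)
    quals = quals_arr.tolist()

    n_sub = 0
    if config.sub_rate > 0:
        hits = np.nonzero(rng.random(n) < config.sub_rate)[0]
        for i in hits:
            others = [b for b in "ACGT" if b != bases[i]]
            bases[i] = others[rng.integers(3)]
            quals[i] = config.sub_qual
            n_sub += 1

    n_ins = n_del = 0
    if config.homopolymer_indel_rate > 0:
        runs = []
        i = 0
        m = len(bases)
        while i < m:
            j = i + 1
            while j < m and bases[j] == bases[i]:
                j += 1
            if j - i >= 2:
                runs.append((i, j))
            i = j
        for start, end in reversed(runs):  # right-to-left keeps indices valid
            if rng.random() < config.homopolymer_indel_rate:
                if rng.random() < 0.5:
                    bases.insert(end, bases[start])
                    quals.insert(end, config.indel_qual)
                    n_ins += 1
                else:
                    del bases[end - 1]
                    del quals[end - 1]
                    n_del += 1
    return "".join(bases), quals, n_sub, n_ins, n_del


def simulate_reads(
    config: SimConfig,
    fasta_out,
    qual_out,
    truth_out=None,
    fastq_out=None,
) -> GroundTruth:
    """Generate a full simulated run: FASTA + QUAL (and optionally FASTQ)
    plus the ground-truth table.

    Reads are emitted sample by sample in sheet order.  Each planned
    library read is replaced by a wild-type (insert-less, spacer-less)
    read with probability ``wt_rate``; every read lands on the forward or
    reverse strand with equal probability.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    regions = build_regions(config.layout, config.sheet.barcodes)
    counts: dict[str, Counter] = {bc: Counter() for bc in config.spectra}
    wt_counts: dict[str, int] = {bc: 0 for bc in config.spectra}
    truth = GroundTruth(counts=counts, wt_counts=wt_counts)
    reads: list[SeqRead] = []
    idx = 0
    for meta in config.sheet:
        spectrum = config.spectra.get(meta.barcode)
        if not spectrum:
            continue
        for pep, depth in spectrum.items():
            for _ in range(depth):
                read_id = f"r{idx:06d}"
                idx += 1
                is_wt = config.wt_rate > 0 and rng.random() < config.wt_rate
                if is_wt:
                    seq = assemble_wt_amplicon(config.layout, regions, meta.barcode)
                    wt_counts[meta.barcode] += 1
                else:
                    insert = encode_peptide_nnk(pep, rng)
                    seq = assemble_library_amplicon(
                        config.layout, regions, meta.barcode, insert
                    )
                    counts[meta.barcode][pep] += 1
                orientation = REVERSE if rng.random() < 0.5 else FORWARD
                if orientation == REVERSE:
                    seq = reverse_complement(seq)
                bases, quals, n_sub, n_ins, n_del = _apply_errors(seq, rng, config)
                reads.append(SeqRead(read_id, bases, quals))
                truth.reads.append(
                    (read_id, meta.barcode, "wt" if is_wt else "library",
                     "" if is_wt else pep, orientation, n_sub, n_ins, n_del)
                )
    write_fasta_qual(reads, fasta_out, qual_out)
    if fastq_out is not None:
        write_fastq(reads, fastq_out)
    if truth_out is not None:
        truth.write_tsv(truth_out)
    return truth


# ---------------------------------------------------------------------------
# Reference fixture: the experiment's design at desk scale

#: Six target-selected peptides, six parental-biased background peptides,
#: and eight generic library fillers (all 12-mers).
FIXTURE_PEPTIDES = (
    # ubiquitin/NEDD8-selected
    "FIPAQLHFHWRS",
    "AKFDMHIATRLS",
    "HMGRHMHEGASS",
    "WPLFHFHERGSH",
    "HYTHTHQYTYSM",
    "QHFHIGESGSLL",
    # propagation-biased background (abundant in the parental library)
    "ALWPPNLHAWVP",
    "AHSANNFDVKGI",
    "TPMVERNYNAAD",
    "MPLMSEPALEML",
    "YSAHNYIGDSGP",
    "SHHHLPAQWRTK",  # nickel-plate poly-His binder
    # generic library members
    "SLKDPNWRTFAE",
    "GQTYMNDWKLRA",
    "NERWTSLGDAYK",
    "KPLANQSYTWDE",
    "DTWNARLEGSYQ",
    "MSYWDQRATNLG",
    "RFGELSWNQTDK",
    "PWDNSYRGTKLE",
)

_FILLERS = FIXTURE_PEPTIDES[12:]


def fixture_layout() -> ConstructLayout:
    """Reference construct layout for tests and the bundled simulator.

    Anchors are invented 12-mers (real primer sequences are instrument- and
    lab-specific); the left border is the Ph.D.-12 vector sequence directly
    upstream of the insert and the right border is the four spacer codons
    (Gly-Gly-Gly-Ser: GGT GGA GGT TCG).
    """
    return ConstructLayout(
        fwd_anchor="GACTGCGTACCA",
        rev_anchor="TGGAGCTTGACG",
        left_border="TATTCTCACTCT",
        right_border="GGTGGAGGTTCG",
        barcode_length=3,
        insert_codons=12,
        spacer_codons=4,
        wt_amplicon_length=381,
        anchor_min_length=12,
    )


def fixture_sheet() -> SampleSheet:
    """Five barcoded samples: the parental library plus three unamplified
    ubiquitin rounds (slow wash) and one amplified round-1 pool."""
    return SampleSheet(
        [
            SampleMeta("AAA", "parental", 0, "none", False),
            SampleMeta("ATC", "ubiquitin", 1, "slow", False),
            SampleMeta("AGG", "ubiquitin", 2, "slow", False),
            SampleMeta("ACT", "ubiquitin", 3, "slow", False),
            SampleMeta("ACG", "ubiquitin", 1, "slow", True),
        ]
    )


def _scaled_counts(props: dict[str, float], depth: int) -> dict[str, int]:
    """Largest-remainder apportionment of `depth` reads over proportions."""
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, expected 1")
    floors = {p: int(depth * f) for p, f in props.items()}
    remainder = depth - sum(floors.values())
    order = sorted(
        props, key=lambda p: (depth * props[p]) - floors[p], reverse=True
    )
    for p in order[:remainder]:
        floors[p] += 1
    return {p: n for p, n in floors.items() if n > 0}


def _even(peps, total: float) -> dict[str, float]:
    return {p: total / len(peps) for p in peps}


def fixture_spectra(depth: int = 2000) -> dict[str, dict[str, int]]:
    """Per-sample peptide spectra replaying the experiment's qualitative
    structure at the given per-sample depth.

    The parental library is dominated by propagation-biased peptides
    (ALWPPNLHAWVP at 3.5%); FIPAQLHFHWRS is absent from round 1, rises to
    ~73% of round 2 and ~97% of round 3 under slow washes, and the
    amplified round-1 pool shows both the hit and amplification-advantaged
    background.
    """
    parental = {
        "ALWPPNLHAWVP": 0.035,
        "AHSANNFDVKGI": 0.030,
        "TPMVERNYNAAD": 0.027,
        "MPLMSEPALEML": 0.025,
        "YSAHNYIGDSGP": 0.022,
        "SHHHLPAQWRTK": 0.020,
        **_even(_FILLERS, 0.841),
    }
    round1 = {
        "WPLFHFHERGSH": 0.11,
        "AKFDMHIATRLS": 0.06,
        "HMGRHMHEGASS": 0.05,
        "HYTHTHQYTYSM": 0.02,
        "QHFHIGESGSLL": 0.02,
        "ALWPPNLHAWVP": 0.09,
        "AHSANNFDVKGI": 0.07,
        "TPMVERNYNAAD": 0.06,
        "MPLMSEPALEML": 0.05,
        "YSAHNYIGDSGP": 0.05,
        "SHHHLPAQWRTK": 0.04,
        **_even(_FILLERS, 0.38),
    }
    round2 = {
        "FIPAQLHFHWRS": 0.73,
        "AKFDMHIATRLS": 0.05,
        "HMGRHMHEGASS": 0.04,
        "WPLFHFHERGSH": 0.03,
        "HYTHTHQYTYSM": 0.01,
        "QHFHIGESGSLL": 0.01,
        "ALWPPNLHAWVP": 0.03,
        "AHSANNFDVKGI": 0.02,
        "TPMVERNYNAAD": 0.02,
        "MPLMSEPALEML": 0.01,
        "YSAHNYIGDSGP": 0.01,
        "SHHHLPAQWRTK": 0.01,
        **_even(_FILLERS, 0.03),
    }
    round3 = {
        "FIPAQLHFHWRS": 0.97,
        "HMGRHMHEGASS": 0.010,
        "AKFDMHIATRLS": 0.008,
        "WPLFHFHERGSH": 0.002,
        "HYTHTHQYTYSM": 0.002,
        "QHFHIGESGSLL": 0.002,
        "SHHHLPAQWRTK": 0.002,
        **_even(_FILLERS, 0.004),
    }
    round1_amp = {
        "FIPAQLHFHWRS": 0.25,
        "ALWPPNLHAWVP": 0.12,
        "AHSANNFDVKGI": 0.09,
        "TPMVERNYNAAD": 0.08,
        "MPLMSEPALEML": 0.07,
        "YSAHNYIGDSGP": 0.06,
        "SHHHLPAQWRTK": 0.05,
        "AKFDMHIATRLS": 0.04,
        "HMGRHMHEGASS": 0.03,
        "WPLFHFHERGSH": 0.03,
        "HYTHTHQYTYSM": 0.01,
        "QHFHIGESGSLL": 0.01,
        **_even(_FILLERS, 0.16),
    }
    return {
        "AAA": _scaled_counts(parental, depth),
        "ATC": _scaled_counts(round1, depth),
        "AGG": _scaled_counts(round2, depth),
        "ACT": _scaled_counts(round3, depth),
        "ACG": _scaled_counts(round1_amp, depth),
    }


def fixture_config(
    seed: int = 1,
    depth: int = 2000,
    wt_rate: float = 0.05,
    sub_rate: float = 0.002,
    homopolymer_indel_rate: float = 0.003,
) -> SimConfig:
    """The bundled reference simulation: 5 barcodes x 20 peptides."""
    return SimConfig(
        layout=fixture_layout(),
        sheet=fixture_sheet(),
        spectra=fixture_spectra(depth),
        wt_rate=wt_rate,
        sub_rate=sub_rate,
        homopolymer_indel_rate=homopolymer_indel_rate,
        seed=seed,
    )
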