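# Methods

This note documents the models, parameter choices and numerical conventions
behind `phagedeconv`, and what the synthetic-data tests do and do not
demonstrate about real sequencing runs.

## Amplicon model

The pipeline assumes a PCR amplicon of a peptide-display construct with this
forward-strand architecture:

```
[fwd primer → anchor][barcode][vector][left border][insert, 3k nt]
[right border = spacer][gIII/adapter][rc(barcode)][rc(rev anchor)]
```

- **Anchors** are the primer fragments immediately 5' of the barcode slot on
  each strand. Matching is exact; the effective match sequence is the
  3'-most `anchor_min_length` bases (default 12 nt) of each anchor, i.e. the
  fragment adjacent to the barcode. Twelve exact bases give a false-match
  probability of ~4⁻¹² per offset, negligible within the bounded search
  window (anchor length + barcode length + 8 nt).
- **Barcodes** are read positionally: the `barcode_length` (default 3) bases
  directly 3' of the matched anchor. Both primers carry the barcode, so
  forward and reverse reads demultiplex identically.
- **Borders** flank the variable region. In the bundled reference layout the
  left border is the Ph.D.-12 vector sequence directly upstream of the insert
  (`TATTCTCACTCT`) and the right border is the four spacer codons
  (Gly-Gly-Gly-Ser → `GGTGGAGGTTCG`), so "right border" and "spacer start"
  coincide. The anchors in the reference layout are invented 12-mers:
  real primer sequences are specific to the sequencing chemistry and lab, so
  the layout is user-supplied configuration (`layout.yaml`), not a constant.
- **Lengths**: a wild-type (insert-less, spacer-less) phage yields a
  `wt_amplicon_length` (381 nt) amplicon; an insert-bearing clone adds
  `3·(insert_codons + spacer_codons)` nt (429 nt for k = 12, 4 spacer
  codons).

## Extraction algorithm: conventions and tie-breaks

All coordinates are 0-based half-open. The six steps run strictly in order
and the first failure fixes the read's fate, so the per-reason discard counts
always partition the input — an invariant the test suite asserts on every
simulated run.

- **Border search** is first-occurrence-after-the-barcode, single pass: the
  first left-border match, then the next right-border match after it. A
  border string recurring inside the insert is taken at face value; for an
  NNK-constrained insert the reference borders cannot occur in-frame (their
  third-position bases violate the G/T rule at every codon offset except one
  rare four-residue pattern), so in practice this convention is exact.
- **Repair tie rule**: when several bases share the minimal quality, the
  3'-most one is removed first, then the procedure re-evaluates. 454-style
  quality degrades toward the 3' end, which makes the 3'-most minimal base
  the most likely error; `--repair-tie fiveprime` selects the opposite
  convention. Because removals do not alter the other bases' qualities, the
  iterative procedure is equivalent to removing the multiset of
  `(length − 3k)` lowest-quality positions ordered by (quality, then 3'-most
  first) — the brute-force oracle the tests compare against.
- **Amber policy**: TAG is the single stop codon inside the NNK set. Default
  is `reject` (any stop codon discards the read); `suppress` accepts TAG and
  translates it to Gln, matching propagation of the library in supE hosts.
  TAA/TGA are always stops (and are non-NNK anyway).
- **N handling**: tolerated on input (any unexpected symbol is normalized to
  N), but an N in the barcode discards as `incomplete_barcode` and an N in
  the final insert as `codon_invalid` — exact-match semantics throughout.
- **Ambiguity**: a read whose 5' window contains both anchors is discarded
  (`ambiguous_orientation`) rather than guessed.

## Filters

- **Poly-His filter**, default `run3`: remove iff the peptide contains a
  contiguous `HHH` run. The alternative `total3` (≥ 3 His anywhere) is
  stricter; `run3` is the default because known target-specific binders with
  three dispersed histidines (e.g. HMGRHMHEGASS, HYTHTHQYTYSM) must survive.
- **Parental filter**, default `parental_max = 2`: a peptide observed more
  than twice in the unpanned parental library is removed from every sample,
  as its abundance reflects a bacterial propagation advantage rather than
  target binding. A stricter "more than once" variant is `parental_max = 1`.
- Both filters are idempotent and commute (His membership is
  count-independent and the parental counts of surviving peptides are
  unchanged by either filter), which the suite checks on random tables.

## Enrichment definitions

- `sample_fraction(p, s)` = counts[p, s] / column-sum(s): the peptide's share
  of the sample's accepted reads. This is the only depth-robust definition
  when per-barcode sequencing depth varies by orders of magnitude.
- `round_trajectory` fixes (target, wash, amplified) and reports
  (round, pooled count, pooled fraction) in ascending round order.
- `target_overlap` reports both Jaccard (|A∩B|/|A∪B|) and min-denominator
  (|A∩B|/min(|A|,|B|)) metrics, labelled — the appropriate denominator for a
  "percent overlap" claim depends on the question, so both are given rather
  than guessed. Input sets default to all post-filter peptides per target,
  pooled over rounds.
- The consensus string of a position frequency matrix calls a residue only
  where its frequency strictly exceeds 0.5 and prints `x` otherwise; an even
  two-way split is indeterminate, not a call. This is a lightweight summary,
  not a substitute for a proper motif-discovery tool on clustered subsets.

## Synthetic data generator

The simulator emulates the features of a pooled 454 amplicon run that the
extraction algorithm must handle:

- full-length amplicons assembled from the layout, with deterministic
  synthetic filler for the constant vector/gIII regions (generated once from
  a fixed internal seed, with a rejection check that no spurious anchor or
  border occurrences arise for any sample barcode);
- uniform random NNK codon choice per residue (so the same peptide maps to
  many nucleotide inserts, as in a real library);
- strand symmetry: each read is emitted forward or reverse-complemented with
  probability 1/2;
- wild-type contamination: each planned read is replaced by an insert-less,
  spacer-less amplicon with probability `wt_rate`;
- substitution errors per base (`sub_rate`) and the platform's dominant
  error mode, ±1 homopolymer-length errors per run of ≥ 2 identical bases
  (`homopolymer_indel_rate`, insertion or deletion with equal probability);
- a linear Phred ramp (mean 34, slope −0.02/nt, ±2 jitter, clamped to
  [20, 40]) with substituted bases flagged at quality 10 and inserted bases
  at quality 6 — strictly below any correct base, so quality-guided repair
  is exercised under the conditions it was designed for.

The bundled fixture replays the experiment's qualitative design at desk
scale: 5 barcodes (parental `AAA`; ubiquitin rounds 1–3 slow-wash unamplified
`ATC`/`AGG`/`ACT`; amplified round-1 `ACG`), 20 peptides, 2,000 reads per
sample. The spectrum places FIPAQLHFHWRS at 0% of round 1, 73% of round 2 and
97% of round 3, puts ALWPPNLHAWVP at 3.5% of the parental pool, and includes
a contiguous-HHH nickel binder. Default error settings (5% wild type, 0.2%
substitutions, 0.3% homopolymer indels) are in the range reported for 454
chemistry, where indels at homopolymers dominate.

**What the simulator does not model**: flowgram-level base calling, PCR
chimeras, primer synthesis errors, affinity-driven panning dynamics, and
quality-correlated error bursts. Passing tests therefore demonstrate the
correctness of the deconvolution logic under realistic error *rates*, not
performance on any particular instrument's error *profile*.

## Problem sizes and verification strategy

- The exact zero-error round trip (simulate → deconvolve → tabulate equals
  the generating spectra, identically) runs at the full fixture scale of
  10,000 reads.
- Oracle equivalences are exhaustive where the space is small (all 64 codons
  for the NNK validator) and sampled where it is not (1,000 random
  over-length inserts for repair; 1,000 clean reads for strand symmetry).
- Noisy recovery uses 50 replicates of a 2-sample × 1,000-read design at
  0.5% substitution + 0.5% homopolymer-indel rates, with top-5 spectrum
  fractions 0.30/0.22/0.16/0.11/0.07; errors thin every peptide's counts
  near-uniformly (survival ≈ 0.65 per read), so the designed gaps keep
  adjacent ranks ≳ 4σ apart and the per-sample top-5 rank order is required
  to be recovered in ≥ 95% of replicates.

## Known limitations

- Exact anchor/border matching means systematic primer-synthesis errors or
  very low-quality 5' ends discard reads wholesale; there is deliberately no
  fuzzy matching (a design choice that favours precision of barcode
  assignment over yield).
- Repair assumes the extracted window is correct and only over-length;
  borders are not re-searched after repair, and under-length extracts
  (deletions) are unrecoverable by design.
- The parental filter needs a sequenced parental pool; without one it
  refuses to run rather than silently passing background through
  (`--no-parental-filter` to opt out).
- Count tables are held in memory (pandas); this is comfortable for
  454-scale runs (10⁴–10⁵ reads) and fine for typical Illumina amplicon
  runs, but the per-read stage streams and could be re-tabulated
  incrementally if needed.
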