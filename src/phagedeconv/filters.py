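"""Background-peptide filters for nickel-plate panning experiments.

Two classes of non-specific peptides are removed after tabulation:

* poly-histidine binders that stick to the nickel-coated plate used to
  immobilize the His-tagged target (his filter);
* peptides abundant in the unpanned parental library, whose persistence
  reflects a phage propagation advantage in bacteria rather than target
  binding (parental filter).

Both filters act on the post-deconvolution count table rather than per
read, so the report can show exactly what was removed and why.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .enrich import AA_ORDER, CountTable

__all__ = [
    "FilterPolicy",
    "his_filter",
    "parental_filter",
    "apply_filters",
]

_AA = frozenset(AA_ORDER)


@dataclass(frozen=True)
class FilterPolicy:
    """Configuration of the background filters.

    ``his_mode='run3'`` removes peptides containing a contiguous HHH run;
    ``'total3'`` removes peptides with three or more histidines anywhere.
    The default is ``run3``: known target-specific hits with three
    dispersed histidines (e.g. HMGRHMHEGASS) must survive the filter.

    ``parental_max`` is the highest parental-library count a peptide may
    have and still be kept; anything observed more often in the unpanned
    library is removed from every sample.
    """

    his_mode: str = "run3"
    parental_max: int = 2

    def __post_init__(self) -> None:
        if self.his_mode not in ("run3", "total3"):
            raise ValueError(f"unknown his_mode {self.his_mode!r}")
        if self.parental_max < 0:
            raise ValueError("parental_max must be >= 0")


def _check_peptide(peptide: str) -> None:
    bad = set(peptide) - _AA
    if bad:
        raise ValueError(
            f"peptide {peptide!r} contains non-amino-acid characters {sorted(bad)}"
        )


def his_filter(
    peptides: Sequence[str], policy: FilterPolicy | None = None
) -> tuple[list[str], list[str]]:
    """Partition peptides into (kept, removed) by the poly-His rule.

    Under ``run3`` a peptide is removed iff it contains ``HHH`` as a
    contiguous substring; under ``total3`` iff it has >= 3 histidines
    anywhere.  The partition is exhaustive and disjoint, preserving input
    order.
    """
    policy = policy or FilterPolicy()
    kept: list[str] = []
    removed: list[str] = []
    for pep in peptides:
        _check_peptide(pep)
        if policy.his_mode == "run3":
            hit = "HHH" in pep
        else:
            hit = pep.count("H") >= 3
        (removed if hit else kept).append(pep)
    return kept, removed


def _parental_barcodes(table: CountTable) -> list[str]:
    barcodes = [bc for bc, m in table.samples.items() if m.target == "parental"]
    if not barcodes:
        barcodes = [bc for bc, m in table.samples.items() if m.round == 0]
    return barcodes


def parental_filter(
    table: CountTable, policy: FilterPolicy | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Remove parental-library-biased peptides from every sample.

    A peptide whose count in the parental (round 0) sample exceeds
    ``policy.parental_max`` is dropped from all samples; the removed
    peptides are reported with their parental counts.  A table without a
    parental sample is a hard error: mark one in the sample sheet or skip
    this filter.
    """
    policy = policy or FilterPolicy()
    barcodes = _parental_barcodes(table)
    if not barcodes:
        raise ValueError(
            "no parental sample in table: mark one sample as target='parental' "
            "(or round 0) in the sample sheet, or skip the parental filter"
        )
    parental_counts = table.counts[barcodes].sum(axis=1)
    removed_mask = parental_counts > policy.parental_max
    removed = pd.DataFrame(
        {
            "peptide": list(parental_counts.index[removed_mask]),
            "parental_count": list(parental_counts[removed_mask].astype(int)),
        }
    )
    kept_table = table.drop_peptides(removed["peptide"])
    return kept_table, removed


def apply_filters(
    table: CountTable, policy: FilterPolicy | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Apply the his filter then the parental filter (they commute).

    Returns the filtered table and a report with columns
    ``peptide, rule, parental_count`` (parental_count empty for his-rule
    removals).
    """
    policy = policy or FilterPolicy()
    _, his_removed = his_filter(table.peptides, policy)
    after_his = table.drop_peptides(his_removed)
    kept, parental_removed = parental_filter(after_his, policy)
    rows = [
        {"peptide": p, "rule": f"his_{policy.his_mode}", "parental_count": pd.NA}
        for p in his_removed
    ]
    rows.extend(
        {
            "peptide": r.peptide,
            "rule": f"parental_gt_{policy.parental_max}",
            "parental_count": int(r.parental_count),
        }
        for r in parental_removed.itertuples()
    )
    report = pd.DataFrame(rows, columns=["peptide", "rule", "parental_count"])
    return kept, report
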