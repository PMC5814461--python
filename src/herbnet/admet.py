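"""Rule-based ADME/T pre-filter for herbal ingredient libraries.

A compound is discarded when any of four pharmacokinetic red flags holds:
extremely low aqueous solubility (solubility level below -8), low blood-brain
barrier penetration (BBB level 3), predicted CYP2D6 inhibition, or very low
intestinal absorption (absorption level 3). Each removal carries the full set
of violated-rule codes so the attrition per rule stays auditable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chem import DescriptorRecord, FormulaTable
from .errors import IntegrityError

log = logging.getLogger(__name__)

SOLUBILITY = "SOLUBILITY"
BBB = "BBB"
CYP2D6 = "CYP2D6"
ABSORPTION = "ABSORPTION"
MISSING = "MISSING"

RULE_CODES = (SOLUBILITY, BBB, CYP2D6, ABSORPTION)


@dataclass(frozen=True)
class AdmetThresholds:
    """Removal criteria; defaults match the conventional extremely-low cutoffs.

    solubility_below: removed when solubility_level < this value (strict).
    bbb_low / absorption_low: removed when the ordinal level equals this value.
    """

    solubility_below: float = -8.0
    bbb_low: int = 3
    absorption_low: int = 3


@dataclass
class FilterResult:
    retained: list[str]
    removed: list[tuple[str, list[str]]]

    def __post_init__(self):
        r, d = set(self.retained), {cid for cid, _ in self.removed}
        if r & d:
            raise IntegrityError(f"ids both retained and removed: {sorted(r & d)[:5]}")
        for cid, codes in self.removed:
            if not codes:
                raise IntegrityError(f"removed compound {cid!r} carries no violation code")

    @property
    def removed_ids(self) -> list[str]:
        return [cid for cid, _ in self.removed]

    @property
    def all_ids(self) -> list[str]:
        return self.retained + self.removed_ids


def violated_rules(record: DescriptorRecord, thresholds: AdmetThresholds | None = None) -> list[str]:
    """Codes of the removal rules a single record violates (possibly empty)."""
    t = thresholds or AdmetThresholds()
    codes: list[str] = []
    if record.solubility_level is not None and record.solubility_level < t.solubility_below:
        codes.append(SOLUBILITY)
    if record.bbb_level is not None and record.bbb_level == t.bbb_low:
        codes.append(BBB)
    if record.cyp2d6 is True:
        codes.append(CYP2D6)
    if record.absorption_level is not None and record.absorption_level == t.absorption_low:
        codes.append(ABSORPTION)
    if not record.complete:
        codes.append(MISSING)
    return codes


def apply_admet_rules(
    records: Sequence[DescriptorRecord],
    thresholds: AdmetThresholds | None = None,
) -> FilterResult:
    """Partition compounds into retained and removed (with per-rule reason codes).

    Input order is preserved in both lists. A record with any missing
    descriptor value is removed with code MISSING (and a warning), in addition
    to whatever rules its present values violate.
    """
    retained: list[str] = []
    removed: list[tuple[str, list[str]]] = []
    for rec in records:
        codes = violated_rules(rec, thresholds)
        if codes:
            if MISSING in codes:
                log.warning("compound %s removed: missing descriptor value(s)", rec.compound_id)
            removed.append((rec.compound_id, codes))
        else:
            retained.append(rec.compound_id)
    return FilterResult(retained, removed)


def filter_summary(result: FilterResult, formula: FormulaTable) -> pd.DataFrame:
    """Per-herb (n_input, n_retained) table with a TOTAL row.

    Every compound in the result must be assigned to a herb in the formula.
    """
    for cid in result.all_ids:
        if cid not in formula:
            raise IntegrityError(f"compound {cid!r} absent from formula table")
    retained = set(result.retained)
    rows = {}
    counted = set(result.all_ids)
    for herb, members in formula.herbs.items():
        present = [c for c in members if c in counted]
        rows[herb] = {
            "n_input": len(present),
            "n_retained": sum(1 for c in present if c in retained),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["TOTAL"] = df.sum()
    return df


def write_filter_table(
    result: FilterResult, formula: FormulaTable, path: str | Path
) -> None:
    """TSV export: compound_id, herb_code, status, codes."""
    lines = ["compound_id\therb_code\tstatus\tcodes"]
    for cid in result.retained:
        lines.append(f"{cid}\t{formula.herb_of(cid)}\tretained\t")
    for cid, codes in result.removed:
        lines.append(f"{cid}\t{formula.herb_of(cid)}\tremoved\t{','.join(codes)}")
    Path(path).write_text("\n".join(lines) + "\n")
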