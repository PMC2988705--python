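"""High-frequency subset selection and workload summaries.

Adverse-event record counts are extremely concentrated: a small fraction
of unique preferred terms accounts for the bulk of records, so mapping
effort is focused on the minimal prefix of terms (by descending count)
that collectively accounts for a target share — 95% by default, the
threshold also used by vocabulary CORE-subset initiatives.  Ties at the
cut-off count are always included so the selection can be stated as
"every term with at least N records".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Optional, Sequence, Tuple

from .model import FrequencyTable

__all__ = [
    "SubsetResult",
    "WorkloadSummary",
    "select_high_frequency",
    "workload_summary",
    "summarize_counts",
    "outcome_tally",
]


@dataclass(frozen=True)
class SubsetResult:
    """Outcome of high-frequency selection."""

    selected_codes: Tuple[str, ...]
    cumulative_share: float
    count_threshold: int


@dataclass(frozen=True)
class WorkloadSummary:
    """Row-A-to-F style workload statistics for a mapping effort."""

    n_unique: int
    n_mapped: int
    pct_mapped: float
    n_highfreq: int
    pct_highfreq: float
    n_highfreq_mapped: int
    pct_highfreq_mapped: float
    n_manual: int
    n_records: Optional[int] = None


def _pct(numerator: int, denominator: int) -> float:
    """100 * ratio, rounded half-up to one decimal (printed precision)."""
    if denominator == 0:
        return 0.0
    value = Decimal(numerator * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def select_high_frequency(freq: FrequencyTable, share: float = 0.95) -> SubsetResult:
    """Minimal descending-count prefix reaching the target record share.

    Codes are ordered by (count desc, code asc); the shortest prefix whose
    cumulative count reaches ``share`` of the total is taken and then
    extended with every code tied at the last included count, so the
    result is expressible as a count threshold.  Raises on an empty table.
    """
    if not 0 < share <= 1:
        raise ValueError("share must be in (0, 1]")
    if not len(freq):
        raise ValueError("frequency table is empty")
    total = freq.total()
    if total == 0:
        raise ValueError("frequency table has zero total records")
    ordered = freq.items_by_count()
    cumulative = 0
    cut = 0
    for i, (_, count) in enumerate(ordered):
        cumulative += count
        if cumulative / total >= share:
            cut = i + 1
            break
    threshold = ordered[cut - 1][1]
    while cut < len(ordered) and ordered[cut][1] == threshold:
        cumulative += ordered[cut][1]
        cut += 1
    return SubsetResult(
        selected_codes=tuple(code for code, _ in ordered[:cut]),
        cumulative_share=cumulative / total,
        count_threshold=threshold,
    )


def summarize_counts(
    n_unique: int,
    n_mapped: int,
    n_highfreq: int,
    n_highfreq_mapped: int,
    n_records: Optional[int] = None,
) -> WorkloadSummary:
    """Fill a workload summary from raw counts.

    Percentages are relative to the natural denominators: mapped and
    high-frequency counts against unique terms, high-frequency-mapped
    against the high-frequency subset.  The manual-mapping workload is
    the unmapped remainder of the high-frequency subset.
    """
    return WorkloadSummary(
        n_unique=n_unique,
        n_mapped=n_mapped,
        pct_mapped=_pct(n_mapped, n_unique),
        n_highfreq=n_highfreq,
        pct_highfreq=_pct(n_highfreq, n_unique),
        n_highfreq_mapped=n_highfreq_mapped,
        pct_highfreq_mapped=_pct(n_highfreq_mapped, n_highfreq),
        n_manual=n_highfreq - n_highfreq_mapped,
        n_records=n_records,
    )


def workload_summary(
    freq: FrequencyTable,
    mapped_codes: Iterable[str],
    subset: SubsetResult,
) -> WorkloadSummary:
    """Workload statistics for a frequency table and a mapped-code set."""
    mapped = set(mapped_codes)
    codes = set(freq.entries)
    selected = set(subset.selected_codes)
    return summarize_counts(
        n_unique=len(codes),
        n_mapped=len(codes & mapped),
        n_highfreq=len(selected),
        n_highfreq_mapped=len(selected & mapped),
        n_records=freq.total(),
    )


def outcome_tally(results: Sequence) -> Dict[str, int]:
    """Count mapping results per outcome category; total equals len()."""
    tally = {"EXACT": 0, "COMPOSED_2": 0, "COMPOSED_3": 0, "UNMAPPED": 0}
    for result in results:
        tally[result.outcome] += 1
    return tally
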