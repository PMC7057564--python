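"""Coverage, contribution, and frequency statistics for concept inventories.

These are the bookkeeping operations of an ontology coverage study: what
fraction of a test concept set a candidate terminology contains (by exact
pre-coordinated CUI match), which source vocabularies contributed the
concepts of a merged ontology, how often each concept recurs in a mapped
corpus of findings, and per-case summary statistics.

All underlying proportions are kept at full precision; display helpers
round half-even to the conventions of the printed tables (whole percents
for coverage and contribution, one decimal for frequencies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyInputError
from .hierarchy import ConceptHierarchy

#: Label under which concepts with no source vocabulary are aggregated.
UNLABELED_SOURCE = "Miscellaneous"


def percent_display(proportion: float, decimals: int = 0) -> str:
    """Render a proportion in [0, 1] as a percent string, half-even rounded.

    >>> percent_display(412 / 601)
    '69%'
    >>> percent_display(47 / 2386, decimals=1)
    '2.0%'
    """
    return f"{proportion * 100:.{decimals}f}%"


@dataclass
class CoverageReport:
    """Coverage of a test concept set by a candidate inventory."""

    n_test: int
    n_covered: int
    missing: list[str]  # sorted uncovered CUIs

    @property
    def proportion(self) -> float:
        return self.n_covered / self.n_test

    @property
    def percent(self) -> str:
        return percent_display(self.proportion)


def coverage(test_concepts: Iterable[str], inventory: Iterable[str]) -> CoverageReport:
    """How many test concepts an inventory contains, by exact CUI match.

    Matching is pre-coordinated only: a concept counts as covered iff its
    CUI is literally present in the inventory.
    """
    test = set(test_concepts)
    if not test:
        raise EmptyInputError("test concept set is empty")
    inv = set(inventory)
    missing = sorted(test - inv)
    return CoverageReport(
        n_test=len(test), n_covered=len(test) - len(missing), missing=missing
    )


@dataclass
class ContributionReport:
    """Per-source concept counts for a merged ontology."""

    rows: list[tuple[str, int, float]]  # (source, count, proportion), count desc
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["source", "count", "proportion"]
        )


def source_contribution(h: ConceptHierarchy) -> ContributionReport:
    """Count concepts per source-terminology label.

    Concepts without a source label are aggregated under
    ``"Miscellaneous"``.  Rows are sorted by count descending (ties by
    label) and proportions are taken against the total concept count.
    """
    counts: dict[str, int] = {}
    for c in h.concepts.values():
        label = c.source or UNLABELED_SOURCE
        counts[label] = counts.get(label, 0) + 1
    total = len(h)
    rows = [
        (label, n, n / total)
        for label, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return ContributionReport(rows=rows, total=total)


@dataclass
class FrequencyTable:
    """Concept recurrence counts over a mapped corpus of findings."""

    rows: list[tuple[str, str, int, float]]  # (cui, name, count, proportion)
    total_findings: int

    @property
    def n_distinct(self) -> int:
        return len(self.rows)

    @property
    def recurrence_mean(self) -> float:
        """Mean occurrences per distinct concept."""
        return self.total_findings / self.n_distinct

    @property
    def recurrence_sd(self) -> float:
        """Sample standard deviation of occurrences per distinct concept."""
        if self.n_distinct < 2:
            return 0.0
        counts = [r[2] for r in self.rows]
        m = self.recurrence_mean
        return math.sqrt(sum((c - m) ** 2 for c in counts) / (len(counts) - 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["cui", "name", "count", "proportion"]
        )

    def head(self, n: int = 15) -> "FrequencyTable":
        return FrequencyTable(rows=self.rows[:n], total_findings=self.total_findings)


def concept_frequency(
    mapped: Sequence[str], names: Mapping[str, str] | None = None
) -> FrequencyTable:
    """Frequency table of mapped concepts, one input CUI per finding.

    Rows are sorted by count descending (ties by CUI); proportions are
    count / total findings.  *names* optionally supplies display names.
    """
    if not mapped:
        raise EmptyInputError("no mapped concepts given")
    counts = pd.Series(list(mapped)).value_counts()
    total = len(mapped)
    names = names or {}
    rows = [
        (cui, names.get(cui, ""), int(n), int(n) / total)
        for cui, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return FrequencyTable(rows=rows, total_findings=total)


@dataclass
class CaseStats:
    """Per-case finding counts summarized over a case series."""

    n_cases: int
    total_findings: int
    mean_per_case: float
    sd_per_case: float  # sample (n-1) definition

    @property
    def display(self) -> str:
        return f"{self.mean_per_case:.1f} ± {self.sd_per_case:.1f}"


def case_statistics(per_case_counts: Sequence[int]) -> CaseStats:
    """Mean and sample standard deviation of findings per case."""
    if not per_case_counts:
        raise EmptyInputError("no per-case counts given")
    n = len(per_case_counts)
    total = sum(per_case_counts)
    mean = total / n
    if n < 2:
        sd = 0.0
    else:
        sd = math.sqrt(sum((c - mean) ** 2 for c in per_case_counts) / (n - 1))
    return CaseStats(
        n_cases=n, total_findings=total, mean_per_case=mean, sd_per_case=sd
    )
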