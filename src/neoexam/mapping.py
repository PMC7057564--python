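"""Normalize free-text finding phrases and map them to concept identifiers.

Mapping goes through a synonym lexicon of normalized terms, in the spirit
of the UMLS normalized concept names: the same clinical meaning phrased
many ways ("bilateral Babinski signs", "both plantars were upgoing", ...)
resolves to one CUI.  Laterality qualifiers (right/left/bilateral/...) are
deliberately ignored as a final fallback, so "left ataxia" maps to the
non-lateralized concept ataxia.  Matching is exact on normalized keys --
no fuzzy matching -- so every mapping is deterministic and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import csv

from .errors import EmptyInputError, LexiconConflictError
from .hierarchy import is_valid_cui

#: Whole-word laterality qualifiers stripped by the fallback match stage.
LATERALITY_TOKENS = frozenset({"right", "left", "bilateral", "bilaterally", "both"})

MATCH_KINDS = ("exact", "normalized", "laterality_stripped", "unmapped")


def normalize_phrase(text: str) -> str:
    """Lowercase, replace punctuation with spaces, collapse whitespace.

    Idempotent: normalizing an already-normalized phrase is a no-op.
    """
    lowered = text.lower()
    cleaned = "".join(ch if ch.isalnum() else " " for ch in lowered)
    return " ".join(cleaned.split())


def strip_laterality(normalized: str) -> str:
    """Remove whole-word laterality tokens from an already-normalized phrase.

    Only the five qualifier words are touched; all other tokens pass
    through unchanged, so applying this twice equals applying it once.
    """
    return " ".join(
        tok for tok in normalized.split() if tok not in LATERALITY_TOKENS
    )


@dataclass
class Lexicon:
    """Synonym table: normalized term -> CUI, with optional provenance."""

    entries: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def cuis(self) -> set[str]:
        return set(self.entries.values())


def build_lexicon(
    entries: Iterable[tuple[str, str] | tuple[str, str, str]]
) -> Lexicon:
    """Build a lexicon from (term, cui[, source]) tuples.

    Terms are stored under their normalized form.  Many terms may share a
    CUI; one normalized term mapping to two different CUIs is an ambiguity
    and is rejected, so lookups never face ties.
    """
    table: dict[str, str] = {}
    provenance: dict[str, str] = {}
    n = 0
    for entry in entries:
        term, cui = entry[0], entry[1]
        n += 1
        if not term:
            raise EmptyInputError("empty term in lexicon entries")
        if not is_valid_cui(cui):
            raise LexiconConflictError(
                f"term {term!r}: {cui!r} is not a valid CUI"
            )
        key = normalize_phrase(term)
        if key in table and table[key] != cui:
            raise LexiconConflictError(
                f"term {term!r} (normalized {key!r}) maps to both "
                f"{table[key]} and {cui}"
            )
        table[key] = cui
        if len(entry) > 2 and entry[2]:
            provenance[key] = entry[2]
    if n == 0:
        raise EmptyInputError("no lexicon entries given")
    return Lexicon(entries=table, provenance=provenance)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a CSV file with header ``term,cui[,source]``."""
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["term", "cui"]:
            raise LexiconConflictError(
                f"{path}: expected header term,cui[,source]"
            )
        return build_lexicon(
            tuple(cell.strip() for cell in row) for row in reader if row
        )


@dataclass(frozen=True)
class MappingResult:
    """The outcome of mapping one phrase."""

    phrase: str
    normalized: str
    cui: str | None
    match_kind: str  # one of MATCH_KINDS; cui is None iff "unmapped"


def map_phrase(lex: Lexicon, phrase: str) -> MappingResult:
    """Map one phrase to a CUI.

    Stages, in order: exact key match on the raw text; match on the
    normalized text; match on the laterality-stripped text; else unmapped.
    The recorded match kind is the first stage that succeeded, so a
    concept whose own name contains a laterality word (e.g. "bilateral
    extensor plantar response") is still reachable before stripping.
    """
    if not lex.entries:
        raise EmptyInputError("lexicon is empty")
    normalized = normalize_phrase(phrase)
    if phrase in lex.entries:
        return MappingResult(phrase, normalized, lex.entries[phrase], "exact")
    if normalized in lex.entries:
        return MappingResult(phrase, normalized, lex.entries[normalized], "normalized")
    stripped = strip_laterality(normalized)
    if stripped in lex.entries:
        return MappingResult(
            phrase, normalized, lex.entries[stripped], "laterality_stripped"
        )
    return MappingResult(phrase, normalized, None, "unmapped")


@dataclass
class CorpusMappingReport:
    """Batch mapping results with yield accounting."""

    results: list[MappingResult]

    @property
    def n_phrases(self) -> int:
        return len(self.results)

    @property
    def n_mapped(self) -> int:
        return sum(1 for r in self.results if r.cui is not None)

    @property
    def mapping_yield(self) -> float:
        return self.n_mapped / self.n_phrases

    @property
    def distinct_cuis(self) -> set[str]:
        return {r.cui for r in self.results if r.cui is not None}

    def mapped_cuis(self) -> list[str]:
        """CUIs of the mapped phrases, in input order (for frequency analysis)."""
        return [r.cui for r in self.results if r.cui is not None]


def map_corpus(lex: Lexicon, phrases: Sequence[str]) -> CorpusMappingReport:
    """Map a batch of phrases, preserving input order."""
    if not phrases:
        raise EmptyInputError("no phrases given")
    return CorpusMappingReport(results=[map_phrase(lex, p) for p in phrases])


def write_mapping_csv(report: CorpusMappingReport, path: str | Path) -> Path:
    """Write per-phrase results as CSV ``phrase,normalized,cui,match_kind``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phrase", "normalized", "cui", "match_kind"])
        for r in report.results:
            writer.writerow([r.phrase, r.normalized, r.cui or "", r.match_kind])
    return path
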