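"""In-memory model of spontaneous adverse-event reports.

A *report* is one submission to a spontaneous reporting system (FAERS-style):
it carries the drugs the reporter listed and the adverse reactions, the
latter already recoded to standardized preferred terms.  Several reports may
describe the same underlying *case*: the first one is the initial report
(sequence 0) and later ones are follow-ups sharing its case identifier.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class DrugRole(enum.Enum):
    """Reporter-assigned role of a drug within a report."""

    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"

    @classmethod
    def from_code(cls, code: str) -> "DrugRole":
        try:
            return cls(code.strip().upper())
        except ValueError:
            raise ValueError(f"unknown drug role code: {code!r}") from None


@dataclass(frozen=True, slots=True)
class DrugMention:
    """One drug line of a report, as the reporter wrote it.

    ``verbatim_name`` is the raw string (possibly a trade name or a
    misspelling); ``resolved_ingredient`` is filled in by the vocabulary
    layer when the string is recognized.
    """

    verbatim_name: str
    role: DrugRole = DrugRole.PRIMARY_SUSPECT
    resolved_ingredient: str | None = None

    def __post_init__(self) -> None:
        if not self.verbatim_name:
            raise ValueError("drug mention requires a non-empty verbatim name")


@dataclass(frozen=True, slots=True)
class ReactionMention:
    """One reaction line: a case-normalized preferred term."""

    preferred_term: str

    def __post_init__(self) -> None:
        if not self.preferred_term:
            raise ValueError("reaction mention requires a non-empty term")
        object.__setattr__(self, "preferred_term", self.preferred_term.strip().lower())


@dataclass(slots=True)
class ReportRecord:
    """One spontaneous report.

    ``report_sequence`` is 0 for the initial report of a case and positive
    for follow-ups; period membership is derived from the receipt year.
    """

    report_id: str
    case_id: str
    report_sequence: int
    receipt_date: datetime.date
    drugs: tuple[DrugMention, ...] = ()
    reactions: tuple[ReactionMention, ...] = ()

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.report_sequence < 0:
            raise ValueError("report_sequence must be >= 0")
        self.drugs = tuple(self.drugs)
        self.reactions = tuple(self.reactions)

    @property
    def is_initial(self) -> bool:
        return self.report_sequence == 0

    @property
    def period_label(self) -> str:
        """Calendar year of receipt, the analysis stratum."""
        return str(self.receipt_date.year)

    def reaction_terms(self) -> frozenset[str]:
        return frozenset(r.preferred_term for r in self.reactions)


@dataclass
class ReportDatabase:
    """A collection of reports with unique report identifiers.

    Equality is up to record ordering (databases are compared sorted by
    ``report_id``), which is the natural identity for files whose row order
    carries no meaning.
    """

    records: list[ReportRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate report_id in database: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReportRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportDatabase):
            return NotImplemented
        key = lambda r: r.report_id  # noqa: E731
        return sorted(self.records, key=key) == sorted(other.records, key=key)

    def case_ids(self) -> set[str]:
        return {r.case_id for r in self.records}

    def periods(self) -> set[str]:
        return {r.period_label for r in self.records}

    def subset(self, predicate) -> "ReportDatabase":
        return ReportDatabase([r for r in self.records if predicate(r)])

    def extend(self, records: Iterable[ReportRecord]) -> None:
        self.records.extend(records)
        self.__post_init__()
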