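"""Reading and writing report databases in a legacy-FAERS-style ASCII layout.

A quarter (or any batch) of reports is stored as three flat delimited tables
keyed by ``report_id``:

* ``header.txt`` — report_id, case_id, sequence, receipt_date
* ``drug.txt``   — report_id, verbatim_name, role_code (PS/SS/C/I)
* ``reac.txt``   — report_id, preferred_term

The legacy AERS convention uses ``$`` as the field delimiter; the dialect is
configurable because the FDA changed details of the layout over the years.
Dates are kept as ISO dates in memory and rendered per dialect on disk.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .records import DrugMention, DrugRole, ReactionMention, ReportDatabase, ReportRecord

logger = logging.getLogger(__name__)

HEADER_FILE = "header.txt"
DRUG_FILE = "drug.txt"
REAC_FILE = "reac.txt"

_HEADER_COLS = ("report_id", "case_id", "sequence", "receipt_date")
_DRUG_COLS = ("report_id", "verbatim_name", "role_code")
_REAC_COLS = ("report_id", "preferred_term")


@dataclass(frozen=True)
class FileDialect:
    """On-disk conventions for the three flat tables."""

    field_delimiter: str = "$"
    encoding: str = "ascii"
    date_format: str = "%Y%m%d"
    has_header: bool = True

    def __post_init__(self) -> None:
        if len(self.field_delimiter) != 1:
            raise ValueError("field delimiter must be a single character")


@dataclass
class ParseSummary:
    """Row-level accounting for one read: parsed + skipped + orphaned = total."""

    header_rows: int = 0
    drug_rows: int = 0
    reaction_rows: int = 0
    records_parsed: int = 0
    records_skipped_bad_date: int = 0
    records_skipped_no_reactions: int = 0
    orphan_drug_rows: int = 0
    orphan_reaction_rows: int = 0
    cases_without_initial: int = 0

    @property
    def records_skipped(self) -> int:
        return self.records_skipped_bad_date + self.records_skipped_no_reactions


class QuarterIOError(OSError):
    """Raised when a quarter directory cannot be written or read."""


def _escape_check(value: str, dialect: FileDialect, report_id: str) -> str:
    if dialect.field_delimiter in value:
        raise QuarterIOError(
            f"field value {value!r} in report {report_id!r} contains the "
            f"dialect delimiter {dialect.field_delimiter!r}"
        )
    if "\n" in value or "\r" in value:
        raise QuarterIOError(f"field value in report {report_id!r} contains a newline")
    return value


def write_quarter(db: ReportDatabase, directory: str | Path, dialect: FileDialect | None = None) -> set[Path]:
    """Write ``db`` as the three flat tables under ``directory``.

    The writer is lossless with respect to every :class:`ReportRecord`
    field; a value containing the dialect delimiter is rejected (naming the
    offending report) rather than silently corrupting the table.
    """
    dialect = dialect or FileDialect()
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise QuarterIOError(f"cannot create output directory {directory}: {exc}") from exc

    sep = dialect.field_delimiter
    paths = {name: directory / name for name in (HEADER_FILE, DRUG_FILE, REAC_FILE)}
    try:
        with (
            open(paths[HEADER_FILE], "w", encoding=dialect.encoding, newline="") as fh,
            open(paths[DRUG_FILE], "w", encoding=dialect.encoding, newline="") as fd,
            open(paths[REAC_FILE], "w", encoding=dialect.encoding, newline="") as fr,
        ):
            if dialect.has_header:
                fh.write(sep.join(_HEADER_COLS) + "\n")
                fd.write(sep.join(_DRUG_COLS) + "\n")
                fr.write(sep.join(_REAC_COLS) + "\n")
            for rec in db:
                rid = rec.report_id
                row = (
                    _escape_check(rid, dialect, rid),
                    _escape_check(rec.case_id, dialect, rid),
                    str(rec.report_sequence),
                    rec.receipt_date.strftime(dialect.date_format),
                )
                fh.write(sep.join(row) + "\n")
                for drug in rec.drugs:
                    fd.write(
                        sep.join(
                            (rid, _escape_check(drug.verbatim_name, dialect, rid), drug.role.value)
                        )
                        + "\n"
                    )
                for reac in rec.reactions:
                    fr.write(sep.join((rid, _escape_check(reac.preferred_term, dialect, rid))) + "\n")
    except OSError as exc:
        if isinstance(exc, QuarterIOError):
            raise
        raise QuarterIOError(f"cannot write quarter files under {directory}: {exc}") from exc
    return set(paths.values())


def _read_rows(path: Path, dialect: FileDialect, n_cols: int) -> list[list[str]]:
    if not path.is_file():
        raise QuarterIOError(f"missing quarter file: {path}")
    rows: list[list[str]] = []
    with open(path, "r", encoding=dialect.encoding, newline="") as fh:
        lines = fh.read().splitlines()
    start = 1 if dialect.has_header and lines else 0
    for line in lines[start:]:
        if not line:
            continue
        parts = line.split(dialect.field_delimiter)
        if len(parts) != n_cols:
            raise QuarterIOError(f"malformed row in {path.name}: expected {n_cols} fields, got {len(parts)}")
        rows.append(parts)
    return rows


def read_quarter(
    directory: str | Path, dialect: FileDialect | None = None
) -> tuple[ReportDatabase, ParseSummary]:
    """Read the three flat tables under ``directory`` into a database.

    Drug and reaction rows are joined to header rows by ``report_id``;
    orphan rows (no matching header) are counted and ignored, records with
    an unparseable date or zero reactions are skipped, and the returned
    :class:`ParseSummary` accounts for every input row.
    """
    dialect = dialect or FileDialect()
    directory = Path(directory)
    summary = ParseSummary()

    header_rows = _read_rows(directory / HEADER_FILE, dialect, len(_HEADER_COLS))
    drug_rows = _read_rows(directory / DRUG_FILE, dialect, len(_DRUG_COLS))
    reac_rows = _read_rows(directory / REAC_FILE, dialect, len(_REAC_COLS))
    summary.header_rows = len(header_rows)
    summary.drug_rows = len(drug_rows)
    summary.reaction_rows = len(reac_rows)

    known_ids = {row[0] for row in header_rows}
    drugs_by_id: dict[str, list[DrugMention]] = {}
    for rid, verbatim, role_code in drug_rows:
        if rid not in known_ids:
            summary.orphan_drug_rows += 1
            logger.warning("orphan drug row for unknown report_id %r", rid)
            continue
        drugs_by_id.setdefault(rid, []).append(
            DrugMention(verbatim_name=verbatim, role=DrugRole.from_code(role_code))
        )
    reacs_by_id: dict[str, list[ReactionMention]] = {}
    for rid, term in reac_rows:
        if rid not in known_ids:
            summary.orphan_reaction_rows += 1
            logger.warning("orphan reaction row for unknown report_id %r", rid)
            continue
        reacs_by_id.setdefault(rid, []).append(ReactionMention(preferred_term=term))

    records: list[ReportRecord] = []
    for rid, case_id, seq, date_str in header_rows:
        try:
            date = datetime.datetime.strptime(date_str, dialect.date_format).date()
        except ValueError:
            summary.records_skipped_bad_date += 1
            logger.warning("report %r skipped: unparseable date %r", rid, date_str)
            continue
        reactions = reacs_by_id.get(rid, [])
        if not reactions:
            summary.records_skipped_no_reactions += 1
            logger.warning("report %r skipped: no reaction rows", rid)
            continue
        records.append(
            ReportRecord(
                report_id=rid,
                case_id=case_id,
                report_sequence=int(seq),
                receipt_date=date,
                drugs=tuple(drugs_by_id.get(rid, [])),
                reactions=tuple(reactions),
            )
        )
    summary.records_parsed = len(records)
    return ReportDatabase(records), summary
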