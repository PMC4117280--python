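"""Reference counts and fixture databases for the dopamine-agonist analysis.

``REFERENCE_COUNTS`` holds the published 2004 and 2007 FAERS cell counts for
behavioral addictions versus the five dopamine agonists: per period, the
total number of initial reports, the number mentioning at least one
dopamine agonist, and per term group the exposed-case (a) and
unexposed-case (b) counts.  :func:`build_reference_database` materializes a
synthetic report database realizing exactly those counts, so the complete
pipeline can be exercised end to end against the published statistics.
The fixture is synthetic: real report content is not redistributable, only
the aggregate counts are public.
"""

from __future__ import annotations

import datetime

from .records import DrugMention, DrugRole, ReactionMention, ReportDatabase, ReportRecord

#: Published per-period counts: total initial reports, dopamine-agonist
#: reports, and (exposed cases, unexposed cases) per behavioral addiction.
REFERENCE_COUNTS: dict[str, dict] = {
    "2004": {
        "n_reports": 199_754,
        "n_exposed": 927,
        "groups": {
            "binge_eating": (0, 251),
            "compulsive_shopping": (0, 0),
            "hypersexuality": (4, 87),
            "pathological_gambling": (28, 5),
        },
    },
    "2007": {
        "n_reports": 254_162,
        "n_exposed": 2_345,
        "groups": {
            "binge_eating": (6, 322),
            "compulsive_shopping": (0, 0),
            "hypersexuality": (30, 65),
            "pathological_gambling": (170, 14),
        },
    },
}

#: Case-defining term per group (the group's primary preferred term).
_GROUP_TERM = {
    "binge_eating": "binge eating",
    "hypersexuality": "hypersexuality",
    "pathological_gambling": "pathological gambling",
}

#: Verbatim drug strings cycled across exposed reports: generic names, trade
#: names and odd casing, all of which must resolve to an ingredient.
_DA_VERBATIMS = (
    "pramipexole",
    "MIRAPEX",
    "ropinirole",
    "Requip",
    "cabergoline",
    "DOSTINEX",
    "pergolide",
    "Permax",
    "bromocriptine",
    "PARLODEL",
)

_NEUTRAL_TERM = "nausea"


def build_reference_database(period: str) -> ReportDatabase:
    """A synthetic database whose 2×2 counts equal ``REFERENCE_COUNTS[period]``.

    Every record is an initial report dated within the period.  Exposed
    records carry one dopamine-agonist mention (cycling through generic and
    trade spellings); case records carry the group's primary preferred
    term, all other records a neutral background term.
    """
    spec = REFERENCE_COUNTS[period]
    year = int(period)
    n_total, n_exposed = spec["n_reports"], spec["n_exposed"]
    records: list[ReportRecord] = []
    i = 0

    def add(exposed: bool, term: str) -> None:
        nonlocal i
        drugs = (
            (DrugMention(verbatim_name=_DA_VERBATIMS[i % len(_DA_VERBATIMS)],
                         role=DrugRole.PRIMARY_SUSPECT if i % 2 else DrugRole.CONCOMITANT),)
            if exposed
            else ()
        )
        date = datetime.date(year, 1, 1) + datetime.timedelta(days=i % 365)
        records.append(
            ReportRecord(
                report_id=f"R{period}-{i:07d}",
                case_id=f"C{period}-{i:07d}",
                report_sequence=0,
                receipt_date=date,
                drugs=drugs,
                reactions=(ReactionMention(preferred_term=term),),
            )
        )
        i += 1

    exposed_cases = 0
    for gid, (a, b) in spec["groups"].items():
        if a or b:
            term = _GROUP_TERM[gid]
            for _ in range(a):
                add(True, term)
            for _ in range(b):
                add(False, term)
            exposed_cases += a
    for _ in range(n_exposed - exposed_cases):
        add(True, _NEUTRAL_TERM)
    while i < n_total:
        add(False, _NEUTRAL_TERM)
    return ReportDatabase(records)
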