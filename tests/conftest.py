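import datetime
import random
import string

import pytest
from hypothesis import HealthCheck, settings

from pvsignal.records import (
    DrugMention,
    DrugRole,
    ReactionMention,
    ReportDatabase,
    ReportRecord,
)
from pvsignal.vocabulary import build_default_lexicon, build_default_term_groups

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon():
    return build_default_lexicon()


@pytest.fixture(scope="session")
def term_groups():
    return build_default_term_groups()


def make_random_db(n: int, seed: int, year: int = 2004) -> ReportDatabase:
    """A quirky random database: odd casing, spaces, varying mention counts."""
    rng = random.Random(seed)
    alphabet = string.ascii_letters + " -.'()"
    names = ["pramipexole", "MIRAPEX", "aspirin", "Requip", "ibuprofen"]
    terms = ["nausea", "pathological gambling", "Headache", "libido increased", "fall"]

    def rand_token():
        return "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 12))).strip() or "x"

    records = []
    for i in range(n):
        drugs = tuple(
            DrugMention(
                verbatim_name=rng.choice(names + [rand_token()]),
                role=rng.choice(list(DrugRole)),
            )
            for _ in range(rng.randint(0, 3))
        )
        reactions = tuple(
            ReactionMention(preferred_term=rng.choice(terms + [rand_token()]))
            for _ in range(rng.randint(1, 4))
        )
        records.append(
            ReportRecord(
                report_id=f"R{i:05d}",
                case_id=f"C{rng.randint(0, max(1, n // 2)):05d}-{i}",
                report_sequence=0,
                receipt_date=datetime.date(year, 1, 1)
                + datetime.timedelta(days=rng.randint(0, 364)),
                drugs=drugs,
                reactions=reactions,
            )
        )
    return ReportDatabase(records)
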