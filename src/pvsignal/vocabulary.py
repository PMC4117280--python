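"""Term groups, substring-based term discovery, and drug-name matching.

The analysis targets four behavioral addictions — binge eating, compulsive
shopping, hypersexuality, and pathological gambling — each represented as a
group of MedDRA-style preferred terms, and five dopamine agonists captured
through generic names, trade names, curated misspellings, and an
edit-distance fallback for verbatim drug strings the curated list misses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import edlib
import yaml

from .records import ReportRecord

logger = logging.getLogger(__name__)

INGREDIENTS = ("bromocriptine", "cabergoline", "pergolide", "pramipexole", "ropinirole")

#: Minimum verbatim length for the edit-distance fallback; short strings
#: produce too many spurious near-matches.
FUZZY_MIN_LENGTH = 6
DEFAULT_MAX_EDIT_DISTANCE = 2


def _norm(s: str) -> str:
    return " ".join(s.strip().lower().split())


@dataclass(frozen=True)
class TermGroup:
    """A behavioral-addiction group: a primary preferred term plus related ones.

    A group whose behavior has no matching preferred term in the vocabulary
    (compulsive shopping) carries no terms and is not evaluable; downstream
    stages must report it as a dash row rather than compute on it.
    """

    group_id: str
    primary_term: str | None
    related_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "primary_term", _norm(self.primary_term) if self.primary_term else None
        )
        related = frozenset(_norm(t) for t in self.related_terms)
        if self.primary_term in related:
            raise ValueError(f"group {self.group_id}: primary term repeated in related terms")
        object.__setattr__(self, "related_terms", related)

    @property
    def evaluable(self) -> bool:
        return self.primary_term is not None

    @property
    def terms(self) -> frozenset[str]:
        if self.primary_term is None:
            return frozenset()
        return self.related_terms | {self.primary_term}


@dataclass(frozen=True)
class LexiconEntry:
    generic_names: frozenset[str]
    trade_names: frozenset[str]
    misspelling_variants: frozenset[str]

    @property
    def canonical_names(self) -> frozenset[str]:
        return self.generic_names | self.trade_names

    @property
    def all_names(self) -> frozenset[str]:
        return self.canonical_names | self.misspelling_variants


@dataclass(frozen=True)
class DrugLexicon:
    """Per-ingredient name sets; all entries case-normalized and pairwise
    disjoint across ingredients."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ingredient, entry in self.entries.items():
            for name in entry.all_names:
                if name in seen and seen[name] != ingredient:
                    raise ValueError(
                        f"name {name!r} listed for both {seen[name]!r} and {ingredient!r}"
                    )
                seen[name] = ingredient

    @property
    def ingredients(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def __contains__(self, ingredient: str) -> bool:
        return ingredient in self.entries

    def __getitem__(self, ingredient: str) -> LexiconEntry:
        return self.entries[ingredient]


@dataclass(frozen=True)
class SubstringQuery:
    """Case-insensitive substring search over a preferred-term vocabulary,
    with exact-term exclusions (e.g. shop-lifting when searching *shop*)."""

    include_substrings: frozenset[str]
    exclude_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        include = frozenset(_norm(s) for s in self.include_substrings)
        if not include or any(not s for s in include):
            raise ValueError("include_substrings must be non-empty strings")
        object.__setattr__(self, "include_substrings", include)
        object.__setattr__(self, "exclude_terms", frozenset(_norm(t) for t in self.exclude_terms))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pvsignal").joinpath("data", name)))


def load_term_groups(path: str | Path | None = None) -> list[TermGroup]:
    """Load term groups from YAML (the bundled defaults when no path given)."""
    path = Path(path) if path is not None else _data_path("term_groups.yaml")
    raw = yaml.safe_load(path.read_text())
    groups = [
        TermGroup(
            group_id=gid,
            primary_term=spec.get("primary_term"),
            related_terms=frozenset(spec.get("related_terms") or []),
        )
        for gid, spec in raw.items()
    ]
    all_terms: set[str] = set()
    for g in groups:
        if g.terms & all_terms:
            raise ValueError(f"term groups are not pairwise disjoint at group {g.group_id}")
        all_terms |= g.terms
    return groups


def build_default_term_groups() -> list[TermGroup]:
    """The four bundled behavioral-addiction groups.

    Binge eating, hypersexuality, and pathological gambling carry preferred
    terms; compulsive shopping has none (no preferred term for the behavior
    exists in the vocabulary) and is flagged non-evaluable.
    """
    return load_term_groups()


def load_lexicon(path: str | Path | None = None) -> DrugLexicon:
    """Load a drug lexicon from YAML (the bundled defaults when no path given)."""
    path = Path(path) if path is not None else _data_path("lexicon.yaml")
    raw = yaml.safe_load(path.read_text())
    entries = {
        _norm(ingredient): LexiconEntry(
            generic_names=frozenset(_norm(n) for n in spec.get("generic_names") or []),
            trade_names=frozenset(_norm(n) for n in spec.get("trade_names") or []),
            misspelling_variants=frozenset(_norm(n) for n in spec.get("misspelling_variants") or []),
        )
        for ingredient, spec in raw.items()
    }
    return DrugLexicon(entries)


def build_default_lexicon() -> DrugLexicon:
    """The bundled lexicon for the five dopamine agonists."""
    return load_lexicon()


def discover_terms(vocabulary: set[str] | frozenset[str], query: SubstringQuery) -> set[str]:
    """Terms of ``vocabulary`` containing any include substring, minus the
    exact exclusions.  Monotone in the vocabulary."""
    hits = set()
    for term in vocabulary:
        t = _norm(term)
        if t in query.exclude_terms:
            continue
        if any(sub in t for sub in query.include_substrings):
            hits.add(term)
    return hits


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two strings."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def match_drug_name(
    verbatim: str,
    lexicon: DrugLexicon,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
) -> str | None:
    """Resolve a verbatim drug string to an ingredient, or ``None``.

    An exact (case-insensitive) hit on any generic, trade, or curated
    misspelling string wins outright.  Otherwise strings of at least
    :data:`FUZZY_MIN_LENGTH` characters fall back to edit distance against
    the generic and trade names; the nearest ingredient within
    ``max_edit_distance`` is returned, and a distance tie between different
    ingredients yields no match (logged).
    """
    if not verbatim:
        raise ValueError("verbatim drug name must be non-empty")
    v = _norm(verbatim)
    for ingredient, entry in lexicon.entries.items():
        if v in entry.all_names:
            return ingredient
    if max_edit_distance <= 0 or len(v) < FUZZY_MIN_LENGTH:
        return None

    best: tuple[int, str] | None = None
    tied = False
    for ingredient, entry in lexicon.entries.items():
        dist = min((levenshtein(v, name) for name in entry.canonical_names), default=None)
        if dist is None or dist > max_edit_distance:
            continue
        if best is None or dist < best[0]:
            best, tied = (dist, ingredient), False
        elif dist == best[0] and ingredient != best[1]:
            tied = True
    if best is None:
        return None
    if tied:
        logger.warning("verbatim %r ties between ingredients at distance %d; no match", verbatim, best[0])
        return None
    return best[1]


def resolve_report_exposures(
    record: ReportRecord,
    lexicon: DrugLexicon,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
    _cache: dict[str, str | None] | None = None,
) -> set[str]:
    """Ingredients a report is exposed to: the union of matches over all its
    drug mentions, regardless of reporter-assigned role (primary suspect,
    concomitant, ...), deduplicated.

    ``_cache`` lets callers memoize verbatim→ingredient lookups across a
    whole database scan.
    """
    exposures: set[str] = set()
    for mention in record.drugs:
        v = mention.verbatim_name
        if _cache is not None and v in _cache:
            hit = _cache[v]
        else:
            hit = match_drug_name(v, lexicon, max_edit_distance)
            if _cache is not None:
                _cache[v] = hit
        if hit is not None:
            exposures.add(hit)
    return exposures
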