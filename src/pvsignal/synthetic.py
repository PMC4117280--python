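"""Synthetic spontaneous-report databases with known ground truth.

The generator emulates the reporting process behind a FAERS-style database
well enough to exercise every pipeline stage offline: year-stratified
batches of initial reports, drug exposures as independent Bernoulli draws,
reaction terms as independent Bernoulli draws whose probabilities are
multiplied by planted drug–group reporting-rate ratios, misspelled drug
names, and follow-up duplicates.  Every report is guaranteed at least one
reaction: reports sampling zero reactions are resampled, implemented as
exact conditional (≥ 1 success) sampling so the cost stays linear.

Because each mechanism is an independent Bernoulli draw, the reporting-rate
ratio a planted multiplier induces — and hence the PRR a correct pipeline
should estimate — has a closed form, provided by :func:`expected_prr`.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .records import DrugMention, DrugRole, ReactionMention, ReportDatabase, ReportRecord
from .stats import ContingencyTable
from .vocabulary import DrugLexicon, TermGroup, build_default_lexicon, build_default_term_groups

#: Common ADR preferred terms that anchor each report with a plausible
#: background reaction, so that conditioning on "at least one reaction"
#: barely perturbs the behavioral-addiction term frequencies.
DEFAULT_NEUTRAL_TERMS = (
    "nausea",
    "headache",
    "dizziness",
    "vomiting",
    "fatigue",
    "rash",
    "pruritus",
    "diarrhoea",
    "dyspnoea",
    "drug ineffective",
    "fall",
    "death",
)


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic reporting process.

    Defaults mirror the scale of the 2004/2007 FAERS snapshots the pipeline
    targets: per-period totals of 199,754 and 254,162 initial reports,
    roughly half a percent of reports mentioning a dopamine agonist, and
    behavioral-addiction terms appearing in the order of 10⁻⁴ of reports.
    """

    model_config = ConfigDict(frozen=True)

    n_reports_per_period: int | dict[str, int] = Field(
        default_factory=lambda: {"2004": 199_754, "2007": 254_162}
    )
    periods: tuple[str, ...] = ("2004", "2007")
    drug_exposure_prob: float = 1e-3
    background_term_prob: float = 1e-4
    neutral_term_prob: float = 0.25
    association_multipliers: dict[str, dict[str, float]] = Field(default_factory=dict)
    misspelling_prob: float = 0.05
    followup_prob: float = 0.2
    random_seed: int

    @field_validator("drug_exposure_prob", "background_term_prob", "neutral_term_prob",
                     "misspelling_prob", "followup_prob")
    @classmethod
    def _check_prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("association_multipliers")
    @classmethod
    def _check_multipliers(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        for ingredient, groups in v.items():
            for gid, m in groups.items():
                if m < 0:
                    raise ValueError(f"multiplier for ({ingredient}, {gid}) must be >= 0")
        return v

    @model_validator(mode="after")
    def _check_counts(self) -> "SyntheticConfig":
        if not self.periods:
            raise ValueError("at least one period required")
        counts = self.n_reports_per_period
        if isinstance(counts, int):
            if counts < 0:
                raise ValueError("n_reports_per_period must be >= 0")
        else:
            missing = set(self.periods) - set(counts)
            if missing:
                raise ValueError(f"n_reports_per_period missing periods: {sorted(missing)}")
            if any(n < 0 for n in counts.values()):
                raise ValueError("n_reports_per_period must be >= 0")
        return self

    def n_reports(self, period: str) -> int:
        if isinstance(self.n_reports_per_period, int):
            return self.n_reports_per_period
        return self.n_reports_per_period[period]

    def multiplier(self, ingredient: str, group_id: str) -> float:
        return self.association_multipliers.get(ingredient, {}).get(group_id, 1.0)


@dataclass(frozen=True)
class GroundTruthCell:
    """Planted rate ratio and realized 2×2 counts for one
    (ingredient, group, period) triple."""

    multiplier: float
    table: ContingencyTable


@dataclass
class GroundTruth:
    """Realized per-(ingredient, group, period) counts of a generated database."""

    cells: dict[tuple[str, str, str], GroundTruthCell]

    def table(self, ingredient: str, group_id: str, period: str) -> ContingencyTable:
        return self.cells[(ingredient, group_id, period)].table


def default_vocabulary(term_groups: Sequence[TermGroup] | None = None) -> list[str]:
    """Group terms plus the neutral background terms, in stable order."""
    groups = list(term_groups) if term_groups is not None else build_default_term_groups()
    terms: list[str] = []
    for g in groups:
        if g.evaluable:
            terms.append(g.primary_term)  # type: ignore[arg-type]
            terms.extend(sorted(g.related_terms))
    terms.extend(DEFAULT_NEUTRAL_TERMS)
    return terms


def _sample_reactions_at_least_one(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample an (n, T) Bernoulli matrix conditioned on >= 1 success per row.

    Equivalent in distribution to redrawing rows that sample zero
    reactions, but runs in O(n·T): factorize the conditional law by the
    chain rule — while a row has no success yet, term t succeeds with
    p_t / (1 − P(no success among terms t..T−1)).
    """
    n, n_terms = prob.shape
    fail_tail = np.cumprod((1.0 - prob)[:, ::-1], axis=1)[:, ::-1]
    if np.any(fail_tail[:, 0] >= 1.0):
        raise ValueError("some reports have zero total reaction probability; "
                         "cannot guarantee a reaction per report")
    out = np.zeros((n, n_terms), dtype=bool)
    no_success = np.ones(n, dtype=bool)
    for t in range(n_terms):
        p_eff = prob[:, t].copy()
        cond = no_success
        p_eff[cond] = prob[cond, t] / (1.0 - fail_tail[cond, t])
        draw = rng.random(n) < p_eff
        out[:, t] = draw
        no_success &= ~draw
    return out


def _period_start(period: str) -> datetime.date:
    return datetime.date(int(period), 1, 1)


def _period_days(period: str) -> int:
    year = int(period)
    return (datetime.date(year + 1, 1, 1) - datetime.date(year, 1, 1)).days


def generate_reports(
    config: SyntheticConfig,
    lexicon: DrugLexicon | None = None,
    vocabulary: Sequence[str] | None = None,
    term_groups: Sequence[TermGroup] | None = None,
) -> tuple[ReportDatabase, GroundTruth]:
    """Generate initial reports for every configured period.

    Per report, each ingredient is an independent Bernoulli(drug_exposure_prob)
    exposure; each vocabulary term is an independent Bernoulli draw whose
    probability is the background rate (group terms) or the neutral rate
    (terms outside every group), multiplied by the product of the planted
    multipliers of the ingredients present, capped at 1.  Drug mentions use
    canonical generic names (misspellings are a separate, later injection);
    the first mention is the primary suspect and the rest concomitant.

    Returns the database (initial reports only, exactly
    ``n_reports_per_period`` each) and the realized ground-truth counts.
    """
    lexicon = lexicon or build_default_lexicon()
    groups = list(term_groups) if term_groups is not None else build_default_term_groups()
    vocab = list(vocabulary) if vocabulary is not None else default_vocabulary(groups)
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    if not lexicon.ingredients:
        raise ValueError("lexicon must be non-empty")
    for ingredient, by_group in config.association_multipliers.items():
        if ingredient not in lexicon:
            raise ValueError(f"multiplier references unknown ingredient {ingredient!r}")
        known = {g.group_id for g in groups}
        unknown = set(by_group) - known
        if unknown:
            raise ValueError(f"multiplier references unknown group(s) {sorted(unknown)}")

    ingredients = list(lexicon.ingredients)
    group_of_term = {t: g.group_id for g in groups for t in g.terms}
    base_prob = np.array(
        [
            config.background_term_prob if t in group_of_term else config.neutral_term_prob
            for t in vocab
        ]
    )
    canonical_name = {
        ing: min(lexicon[ing].generic_names or {ing}) for ing in ingredients
    }

    seed_root = np.random.SeedSequence(config.random_seed)
    period_seeds = seed_root.spawn(len(config.periods))

    records: list[ReportRecord] = []
    cells: dict[tuple[str, str, str], GroundTruthCell] = {}
    for period, seed in zip(config.periods, period_seeds):
        rng = np.random.default_rng(seed)
        n = config.n_reports(period)
        exposure = rng.random((n, len(ingredients))) < config.drug_exposure_prob

        prob = np.broadcast_to(base_prob, (n, len(vocab))).copy()
        for j, ing in enumerate(ingredients):
            by_group = config.association_multipliers.get(ing)
            if not by_group:
                continue
            for ti, term in enumerate(vocab):
                gid = group_of_term.get(term)
                if gid is not None and gid in by_group:
                    prob[exposure[:, j], ti] *= by_group[gid]
        np.clip(prob, 0.0, 1.0, out=prob)

        if n > 0:
            reactions = _sample_reactions_at_least_one(prob, rng)
            day_offsets = rng.integers(0, _period_days(period), size=n)
        else:
            reactions = np.zeros((0, len(vocab)), dtype=bool)
            day_offsets = np.zeros(0, dtype=int)

        start = _period_start(period)
        for i in range(n):
            drug_idx = np.flatnonzero(exposure[i])
            mentions = tuple(
                DrugMention(
                    verbatim_name=canonical_name[ingredients[j]],
                    role=DrugRole.PRIMARY_SUSPECT if k == 0 else DrugRole.CONCOMITANT,
                )
                for k, j in enumerate(drug_idx)
            )
            reacs = tuple(
                ReactionMention(preferred_term=vocab[t]) for t in np.flatnonzero(reactions[i])
            )
            records.append(
                ReportRecord(
                    report_id=f"R{period}-{i:07d}",
                    case_id=f"C{period}-{i:07d}",
                    report_sequence=0,
                    receipt_date=start + datetime.timedelta(days=int(day_offsets[i])),
                    drugs=mentions,
                    reactions=reacs,
                )
            )

        group_case = {
            g.group_id: reactions[:, [ti for ti, t in enumerate(vocab) if t in g.terms]].any(axis=1)
            if g.evaluable and n > 0
            else np.zeros(n, dtype=bool)
            for g in groups
        }
        for j, ing in enumerate(ingredients):
            exp_j = exposure[:, j]
            for g in groups:
                case = group_case[g.group_id]
                a = int(np.count_nonzero(exp_j & case))
                b = int(np.count_nonzero(~exp_j & case))
                c = int(np.count_nonzero(exp_j & ~case))
                d = n - a - b - c
                cells[(ing, g.group_id, period)] = GroundTruthCell(
                    multiplier=config.multiplier(ing, g.group_id),
                    table=ContingencyTable(a, b, c, d),
                )
    return ReportDatabase(records), GroundTruth(cells)


def inject_followups(db: ReportDatabase, followup_prob: float, seed: int) -> ReportDatabase:
    """Add follow-up duplicates the dedup stage must later remove.

    Each case independently receives follow-ups with probability
    ``followup_prob``; the number of follow-ups is geometric (mean 1/0.6,
    capped at 5).  Follow-ups share the case identifier, copy the initial
    report's drug and reaction content, carry fresh report identifiers and
    increasing sequence numbers, and are dated 1–90 days after the initial
    report, truncated at the end of its calendar year so they stay within
    the period.
    """
    if not 0.0 <= followup_prob <= 1.0:
        raise ValueError("followup_prob must lie in [0, 1]")
    if any(not r.is_initial for r in db):
        raise ValueError("inject_followups requires a database of initial reports only")
    rng = np.random.default_rng(seed)
    out = list(db.records)
    for rec in db:
        if followup_prob == 0.0 or rng.random() >= followup_prob:
            continue
        k = min(int(rng.geometric(0.6)), 5)
        offsets = np.sort(rng.integers(1, 91, size=k))
        year_end = datetime.date(rec.receipt_date.year, 12, 31)
        for seq, off in enumerate(offsets, start=1):
            date = min(rec.receipt_date + datetime.timedelta(days=int(off)), year_end)
            out.append(
                ReportRecord(
                    report_id=f"{rec.report_id}-F{seq}",
                    case_id=rec.case_id,
                    report_sequence=seq,
                    receipt_date=date,
                    drugs=rec.drugs,
                    reactions=rec.reactions,
                )
            )
    return ReportDatabase(out)


def inject_misspellings(
    db: ReportDatabase, misspelling_prob: float, lexicon: DrugLexicon, seed: int
) -> ReportDatabase:
    """Rewrite drug mentions as lexicon misspelling variants.

    Each mention is independently rewritten with probability
    ``misspelling_prob`` to a variant drawn uniformly from its ingredient's
    ``misspelling_variants``; mentions whose ingredient has no variants (or
    that are not in the lexicon) are left unchanged.  Because the variants
    live in the lexicon, misspelling-aware matching downstream recovers the
    same exposures, so ingredient-level ground truth is unchanged.
    """
    if not 0.0 <= misspelling_prob <= 1.0:
        raise ValueError("misspelling_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    name_to_ing = {
        name: ing for ing in lexicon.ingredients for name in lexicon[ing].all_names
    }
    out: list[ReportRecord] = []
    for rec in db:
        new_mentions = []
        changed = False
        for m in rec.drugs:
            if misspelling_prob > 0.0 and rng.random() < misspelling_prob:
                ing = name_to_ing.get(m.verbatim_name.strip().lower())
                variants = sorted(lexicon[ing].misspelling_variants) if ing else []
                if variants:
                    new_mentions.append(
                        DrugMention(
                            verbatim_name=variants[int(rng.integers(len(variants)))],
                            role=m.role,
                        )
                    )
                    changed = True
                    continue
            new_mentions.append(m)
        if changed:
            out.append(
                ReportRecord(
                    report_id=rec.report_id,
                    case_id=rec.case_id,
                    report_sequence=rec.report_sequence,
                    receipt_date=rec.receipt_date,
                    drugs=tuple(new_mentions),
                    reactions=rec.reactions,
                )
            )
        else:
            out.append(rec)
    return ReportDatabase(out)


def simulate_database(
    config: SyntheticConfig,
    lexicon: DrugLexicon | None = None,
    vocabulary: Sequence[str] | None = None,
    term_groups: Sequence[TermGroup] | None = None,
) -> tuple[ReportDatabase, GroundTruth]:
    """Full simulation: generate initial reports, then inject follow-ups and
    misspellings per the config.  Ground truth refers to the initial reports."""
    lexicon = lexicon or build_default_lexicon()
    db, truth = generate_reports(config, lexicon, vocabulary, term_groups)
    sub = np.random.SeedSequence(config.random_seed).spawn(len(config.periods) + 2)
    fu_seed, ms_seed = (int(s.generate_state(1)[0] % (2**31)) for s in sub[-2:])
    db = inject_followups(db, config.followup_prob, fu_seed)
    db = inject_misspellings(db, config.misspelling_prob, lexicon, ms_seed)
    return db, truth


def expected_prr(
    config: SyntheticConfig,
    ingredient: str,
    group_id: str,
    lexicon: DrugLexicon | None = None,
    vocabulary: Sequence[str] | None = None,
    term_groups: Sequence[TermGroup] | None = None,
) -> float:
    """Analytic PRR the generative model implies for one (ingredient, group).

    Computes P(case | exposed, ≥1 reaction) / P(case | unexposed, ≥1
    reaction) exactly, marginalizing over the presence of every *other*
    ingredient that carries a multiplier (exposures are independent
    Bernoulli draws, so the marginal is a sum over at most 2^k subsets).
    The ≥1-reaction conditioning is included because the generator
    resamples zero-reaction reports.
    """
    lexicon = lexicon or build_default_lexicon()
    groups = list(term_groups) if term_groups is not None else build_default_term_groups()
    vocab = list(vocabulary) if vocabulary is not None else default_vocabulary(groups)
    group_of_term = {t: g.group_id for g in groups for t in g.terms}
    target_terms = next(g.terms for g in groups if g.group_id == group_id)
    if not target_terms:
        raise ValueError(f"group {group_id!r} has no terms")

    others = [
        ing
        for ing in lexicon.ingredients
        if ing != ingredient and config.association_multipliers.get(ing)
    ]
    p_drug = config.drug_exposure_prob

    def probs(present: set[str]) -> np.ndarray:
        out = np.empty(len(vocab))
        for ti, term in enumerate(vocab):
            gid = group_of_term.get(term)
            p = config.background_term_prob if gid is not None else config.neutral_term_prob
            if gid is not None:
                for ing in present:
                    p *= config.multiplier(ing, gid)
            out[ti] = min(p, 1.0)
        return out

    target_idx = [ti for ti, t in enumerate(vocab) if t in target_terms]

    def rate(exposed: bool) -> float:
        num = den = 0.0
        for mask in range(2 ** len(others)):
            present = {others[k] for k in range(len(others)) if mask >> k & 1}
            w = math.prod(p_drug if o in present else 1 - p_drug for o in others)
            if exposed:
                present = present | {ingredient}
            p = probs(present)
            p_case = 1.0 - np.prod(1.0 - p[target_idx])
            p_any = 1.0 - np.prod(1.0 - p)
            num += w * p_case
            den += w * p_any
        return num / den

    return rate(True) / rate(False)
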