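"""End-to-end analysis: validate, split, search, sample, classify, summarise.

``run_analysis`` wires the whole method together: validate microchip
fields and split the corpus into valid/invalid cohorts, rank the search
terms on the valid cohort and pick the winner (Search A), draw a random
sample of hits per cohort (separate Mersenne-Twister seeds derived from
the master seed), classify each sampled hit with the rule set, then
compute PPVs, cohort comparisons, implantation-timing summaries,
concurrent-event tables, broad-vs-narrow differential words and the
duplicate-chip linkage report. The report is self-auditing: every
statistic travels with its input counts, the convention flags that
produced it, and the seeds used.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .classify import (
    ClassificationTable,
    ConcurrentEvent,
    HitCategory,
    RuleSet,
    classify_hit,
    default_ruleset,
    detect_litter,
    extract_concurrent,
    sample_hits,
    tabulate_classifications,
)
from .epr import CorpusCounts, EPRRecord, Species, count_corpus, read_corpus, split_cohorts
from .linkage import LinkageReport, linkage_report
from .search import (
    DEFAULT_TERMS,
    TermRanking,
    WordFrequencyTable,
    differential_words,
    find_hits,
    rank_terms,
)
from .stats import (
    AgeSummary,
    CategoryComparison,
    ChiSqResult,
    Extrapolation,
    LogTTestResult,
    TwoByTwo,
    age_days,
    chisq_2x2,
    compare_category_proportions,
    compliance_fraction,
    extrapolate_events,
    log_t_test,
    ppv,
    summarize_ages,
)

__all__ = ["CohortResult", "AnalysisReport", "run_analysis", "export_tables"]

#: Statutory microchipping deadline in most Australian jurisdictions (12 weeks).
DEFAULT_DEADLINE_DAYS = 84


@dataclass
class CohortResult:
    """Per-cohort search, sampling and classification outcome."""

    name: str
    n_records: int
    n_hits: int
    n_sampled: int
    sample_seed: int
    table: ClassificationTable
    ppv: float | None
    n_implantation: int
    n_litter: int
    n_individual: int
    ages_individual: dict[str, list[int]]  # per species value
    n_missing_dob: int
    concurrent_counts: dict[str, int]


@dataclass
class AnalysisReport:
    corpus_counts: CorpusCounts
    ranking: TermRanking
    search_term: str
    cohorts: dict[str, CohortResult]
    chisq_ppv: ChiSqResult | None
    chisq_litter: ChiSqResult | None
    comparisons: list[CategoryComparison]
    age_summaries: dict[str, AgeSummary]
    log_t_dogs_vs_cats: LogTTestResult | None
    compliance: dict[str, float]
    deadline_days: int
    concurrent_by_species: dict[str, dict[str, int]]
    concurrent_species_tests: dict[str, ChiSqResult]
    differential: WordFrequencyTable
    linkage: LinkageReport
    extrapolation: Extrapolation | None
    conventions: dict[str, Any]
    seed: int

    def to_dict(self) -> dict[str, Any]:
        return _jsonify(dataclasses.asdict(self))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {_key(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonify(v) for v in obj)
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, date):
        return obj.isoformat()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _key(k: Any) -> str:
    if isinstance(k, enum.Enum):
        return str(k.value)
    return str(k)


def _analyse_cohort(
    name: str,
    cohort: Sequence[EPRRecord],
    term: str,
    rules: RuleSet,
    sample_size: int,
    seed: int,
) -> CohortResult:
    hits = find_hits(cohort, term)
    n_sampled = min(sample_size, hits.n_records)
    refs = sample_hits(hits, n_sampled, seed) if n_sampled else []
    labels = [classify_hit(cohort[r], rules) for r in refs]
    table = tabulate_classifications(labels)

    impl_refs = [
        r for r, lab in zip(refs, labels) if lab is HitCategory.IMPLANTATION_EVENT
    ]
    litter_flags = {r: detect_litter(cohort[r], rules) for r in impl_refs}
    n_litter = sum(litter_flags.values())
    individual = [r for r in impl_refs if not litter_flags[r]]

    ages: dict[str, list[int]] = {Species.DOG.value: [], Species.CAT.value: []}
    missing_dob = 0
    concurrent_counts = {ev.value: 0 for ev in ConcurrentEvent}
    for r in individual:
        rec = cohort[r]
        for ev in extract_concurrent(rec, rules):
            concurrent_counts[ev.value] += 1
        if rec.date_of_birth is None:
            missing_dob += 1
        else:
            ages[rec.species.value].append(age_days(rec.date_of_birth, rec.visit_date))

    return CohortResult(
        name=name,
        n_records=len(cohort),
        n_hits=hits.n_records,
        n_sampled=n_sampled,
        sample_seed=seed,
        table=table,
        ppv=ppv(len(impl_refs), n_sampled) if n_sampled else None,
        n_implantation=len(impl_refs),
        n_litter=n_litter,
        n_individual=len(individual),
        ages_individual=ages,
        n_missing_dob=missing_dob,
        concurrent_counts=concurrent_counts,
    )


def _safe_chisq(a: int, b: int, c: int, d: int) -> ChiSqResult | None:
    try:
        return chisq_2x2(TwoByTwo(a, b, c, d))
    except ValueError:
        return None


def run_analysis(
    corpus: Sequence[EPRRecord] | str | Path,
    *,
    rules: RuleSet | None = None,
    terms: Sequence[str] = DEFAULT_TERMS,
    reference: str = "microc",
    narrow_term: str = "microch",
    sample_size: int = 1000,
    seed: int = 0,
    deadline_days: int = DEFAULT_DEADLINE_DAYS,
) -> AnalysisReport:
    """Run the full pipeline on a corpus (or a corpus CSV path).

    Reproducible bit for bit given the same corpus, configuration and
    seed; the two cohort samples use independent seeds derived from the
    master seed. A corpus with zero hits yields empty tables rather than
    an error.
    """
    if isinstance(corpus, (str, Path)):
        corpus = read_corpus(corpus)
    rules = rules if rules is not None else default_ruleset()

    counts = count_corpus(corpus)
    valid, invalid = split_cohorts(corpus)
    ranking = rank_terms(valid, list(terms), reference)
    term = ranking.best_term

    seed_valid, seed_invalid = (
        int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(2)
    )
    cv = _analyse_cohort("valid", valid, term, rules, sample_size, seed_valid)
    ci = _analyse_cohort("invalid", invalid, term, rules, sample_size, seed_invalid)

    chisq_ppv = (
        _safe_chisq(
            cv.n_implantation,
            cv.n_sampled - cv.n_implantation,
            ci.n_implantation,
            ci.n_sampled - ci.n_implantation,
        )
        if cv.n_sampled and ci.n_sampled
        else None
    )
    chisq_litter = (
        _safe_chisq(cv.n_litter, cv.n_individual, ci.n_litter, ci.n_individual)
        if cv.n_implantation and ci.n_implantation
        else None
    )
    comparisons = (
        compare_category_proportions(cv.table, ci.table)
        if cv.n_sampled and ci.n_sampled
        else []
    )

    # Implantation timing: individual events pooled over both cohorts.
    dog_ages = cv.ages_individual["dog"] + ci.ages_individual["dog"]
    cat_ages = cv.ages_individual["cat"] + ci.ages_individual["cat"]
    all_ages = dog_ages + cat_ages
    age_summaries: dict[str, AgeSummary] = {}
    if all_ages:
        age_summaries["individual_all"] = summarize_ages(all_ages)
    if dog_ages:
        age_summaries["individual_dogs"] = summarize_ages(dog_ages)
    if cat_ages:
        age_summaries["individual_cats"] = summarize_ages(cat_ages)
    log_t = (
        log_t_test(dog_ages, cat_ages) if len(dog_ages) > 1 and len(cat_ages) > 1 else None
    )
    compliance = {}
    if dog_ages:
        compliance["dogs"] = compliance_fraction(dog_ages, deadline_days)
    if cat_ages:
        compliance["cats"] = compliance_fraction(cat_ages, deadline_days)

    # Concurrent interactions per species (individual implantations only).
    conc_species: dict[str, dict[str, int]] = {
        sp.value: {ev.value: 0 for ev in ConcurrentEvent} for sp in Species
    }
    for cohort, res in ((valid, cv), (invalid, ci)):
        hits = find_hits(cohort, term)
        refs = sample_hits(hits, res.n_sampled, res.sample_seed) if res.n_sampled else []
        for r in refs:
            rec = cohort[r]
            if classify_hit(rec, rules) is not HitCategory.IMPLANTATION_EVENT:
                continue
            if detect_litter(rec, rules):
                continue
            for ev in extract_concurrent(rec, rules):
                conc_species[rec.species.value][ev.value] += 1

    n_dogs_ind = sum(conc_species["dog"].values())
    n_cats_ind = sum(conc_species["cat"].values())
    conc_tests: dict[str, ChiSqResult] = {}
    for ev in ConcurrentEvent:
        kd, kc = conc_species["dog"][ev.value], conc_species["cat"][ev.value]
        if kd + kc >= 10 and n_dogs_ind and n_cats_ind:
            res = _safe_chisq(kd, n_dogs_ind - kd, kc, n_cats_ind - kc)
            if res is not None:
                conc_tests[ev.value] = res

    differential = differential_words(valid, reference, narrow_term)
    linkage = linkage_report(corpus)
    extrapolation = (
        extrapolate_events(cv.n_hits, cv.ppv) if cv.ppv is not None else None
    )

    conventions = {
        "yates_correction": True,
        "comparison_denominator": "full cohort sample size",
        "percentage_denominator": "false-positive total",
        "quantile_method": "linear interpolation",
        "t_test": "welch on natural-log ages, zero ages shifted +1 day",
        "sampling_rng": "numpy RandomState (MT19937), per-cohort seeds from master",
        "deadline_days": deadline_days,
    }
    return AnalysisReport(
        corpus_counts=counts,
        ranking=ranking,
        search_term=term,
        cohorts={"valid": cv, "invalid": ci},
        chisq_ppv=chisq_ppv,
        chisq_litter=chisq_litter,
        comparisons=comparisons,
        age_summaries=age_summaries,
        log_t_dogs_vs_cats=log_t,
        compliance=compliance,
        deadline_days=deadline_days,
        concurrent_by_species=conc_species,
        concurrent_species_tests=conc_tests,
        differential=differential,
        linkage=linkage,
        extrapolation=extrapolation,
        conventions=conventions,
        seed=seed,
    )


def export_tables(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the report as 7 CSV tables plus report.json; returns the paths.

    Re-exporting the same report produces byte-identical files; the output
    directory is created if missing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        p = out / name
        frame.to_csv(p, index=False)
        paths.append(p)

    _write("term_ranking.csv", report.ranking.to_frame())

    cv, ci = report.cohorts["valid"], report.cohorts["invalid"]
    _write(
        "classification.csv",
        pd.DataFrame(
            {
                "category": [c.value for c in HitCategory],
                "count_valid": [cv.table[c] for c in HitCategory],
                "count_invalid": [ci.table[c] for c in HitCategory],
            }
        ),
    )

    _write(
        "category_comparison.csv",
        pd.DataFrame(
            [
                {
                    "category": row.category.value,
                    "count_valid": row.count_valid,
                    "count_invalid": row.count_invalid,
                    "pct_valid_of_false_positives": row.pct_valid,
                    "pct_invalid_of_false_positives": row.pct_invalid,
                    "chisq": row.chisq.statistic if row.chisq else "",
                    "p_value": row.chisq.p_value if row.chisq else "",
                    "note": row.note,
                }
                for row in report.comparisons
            ]
        ),
    )

    _write(
        "age_summaries.csv",
        pd.DataFrame(
            [
                {
                    "group": name,
                    "n": s.n,
                    "median_days": s.median_days,
                    "iqr_days": s.iqr_days,
                }
                for name, s in report.age_summaries.items()
            ]
        ),
    )

    _write(
        "concurrent_events.csv",
        pd.DataFrame(
            [
                {
                    "event": ev.value,
                    "valid": cv.concurrent_counts[ev.value],
                    "invalid": ci.concurrent_counts[ev.value],
                    "dogs": report.concurrent_by_species["dog"][ev.value],
                    "cats": report.concurrent_by_species["cat"][ev.value],
                }
                for ev in ConcurrentEvent
            ]
        ),
    )

    _write("differential_words.csv", report.differential.to_frame())
    _write("linkage.csv", report.linkage.to_frame())

    json_path = out / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    paths.append(json_path)
    return paths
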