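"""End-to-end study orchestration: ingest -> dedup -> select -> screen ->
prioritize -> stratify -> regress -> TTO, with a run manifest.

Every stage's output is written as TSV under the output directory; the
manifest records the filter chain (raw rows >= deduplicated >=
deleted-removed >= target-selected) and every exclusion counter so a run
can be audited box by box.  Reruns with the same config and seed are
byte-identical (wall-clock timestamps are recorded only on request).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from . import faers_io, prioritize, signals, stratified, tto
from .config import RunConfig
from .faers_io import CaseReport, normalize_drug_name, normalize_synonyms
from .synthetic import generate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    counts: dict[str, int]
    exclusions: dict[str, dict]
    version: str
    config_hash: str
    seed: int
    timestamps: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "exclusions": self.exclusions,
                "version": self.version,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "timestamps": self.timestamps,
                "notes": self.notes,
            },
            indent=1,
            sort_keys=True,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _term_list(inline: Iterable[str], path: str | None) -> frozenset[str]:
    terms = set(inline)
    if path:
        terms |= faers_io.load_term_list(path)
    return frozenset(terms)


def run_analysis(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full study and write all result tables plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    exclusions: dict[str, dict] = {}
    notes: list[str] = []
    stamps: dict[str, str] = {}

    def stamp(stage: str) -> None:
        if config.record_timestamps:
            stamps[stage] = datetime.now(timezone.utc).isoformat()

    # --- ingest -----------------------------------------------------------
    stage = "ingest"
    stamp(stage)
    try:
        if config.input_mode == "synthetic":
            data_dir, truth = generate_dataset(config.synthetic, out / "synthetic_input")
            tables = faers_io.read_quarter(data_dir, config.synthetic.quarter)
            pt_to_soc = faers_io.load_pt_soc_map(data_dir / "pt_soc_map.tsv")
            counts["generator_reports"] = truth.n_reports
        else:
            quarters = [
                faers_io.read_quarter(config.faers_dir, q) for q in config.quarters
            ]
            tables = faers_io.merge_quarters(quarters)
            pt_to_soc = faers_io.load_pt_soc_map(config.pt_soc_path)
        counts["raw_demo_rows"] = len(tables.demo)
        exclusions["parse"] = tables.parse_issues.get("demo", {}) if isinstance(
            tables.parse_issues.get("demo", {}), dict
        ) else {}
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, exc) from exc

    # --- dedup + deleted-case removal ------------------------------------
    stage = "deduplicate"
    stamp(stage)
    try:
        retained = faers_io.deduplicate(tables.demo)
        counts["after_dedup"] = len(retained)
        retained = faers_io.remove_deleted_cases(
            retained, tables.deleted_caseids, tables.demo
        )
        counts["after_deleted_removed"] = len(retained)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- target selection -------------------------------------------------
    stage = "select"
    stamp(stage)
    try:
        target_ids = faers_io.select_drug_reports(
            tables.drug, config.target_synonyms, role="PS"
        )
        target_ids &= retained
        counts["target_selected"] = len(target_ids)
        cases = faers_io.assemble_cases(
            tables, target_ids, pt_to_soc, config.target_synonyms
        )
        if config.indication_filter:
            before = len(cases)
            cases = [c for c in cases if config.indication_filter in c.indications]
            exclusions["indication_filter"] = {"removed": before - len(cases)}
        counts["cases_assembled"] = len(cases)
        counts["target_pt_records"] = sum(c.n_records for c in cases)
        records = faers_io.pt_record_table(tables, retained, pt_to_soc)
        counts["total_pt_records"] = len(records)
        _write(faers_io.case_table(cases), out / "case_table.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- primary + sensitivity screens ------------------------------------
    stage = "screen"
    stamp(stage)
    try:
        primary_pt = signals.screen_all(
            records, target_ids, level="PT",
            min_cases=config.min_cases, bcpnn_variant=config.bcpnn_variant,
        )
        primary_soc = signals.screen_all(
            records, target_ids, level="SOC",
            min_cases=config.min_cases, bcpnn_variant=config.bcpnn_variant,
        )
        _write(signals.signal_table(primary_pt), out / "signals_pt.tsv")
        _write(signals.signal_table(primary_soc), out / "signals_soc.tsv")

        mono_cases = signals.restrict_monotherapy(cases, config.target_synonyms)
        counts["monotherapy_cases"] = len(mono_cases)
        poly_ids = {c.primaryid for c in cases} - {c.primaryid for c in mono_cases}
        mono_records = records[~records["primaryid"].astype(str).isin(poly_ids)]
        mono_results = signals.screen_all(
            mono_records, {c.primaryid for c in mono_cases},
            level="PT", analysis_tag="monotherapy", min_cases=config.min_cases,
        ) if mono_cases else []
        _write(signals.signal_table(mono_results), out / "signals_monotherapy.tsv")

        comparator_results: dict[str, list[signals.SignalResult]] = {}
        for name, syn in sorted(config.comparators.items()):
            res = signals.comparator_screen(
                records, tables.drug, syn, name,
                level="PT", min_cases=config.min_cases,
            )
            comparator_results[name] = res
            _write(signals.signal_table(res), out / f"signals_comparator_{name}.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- prioritization + origin ------------------------------------------
    stage = "prioritize"
    stamp(stage)
    try:
        label_terms = _term_list(config.label_terms, config.label_terms_path)
        dme = _term_list(config.dme_terms, config.dme_terms_path)
        ime = _term_list(config.ime_terms, config.ime_terms_path)
        total_records = counts["target_pt_records"]
        deaths_by_term: Counter = Counter()
        for c in cases:
            if c.fatal:
                deaths_by_term.update(c.pts)
        flagged = [r for r in primary_pt if r.flagged]
        comp_flagged = {
            name: {r.term for r in res if r.flagged}
            for name, res in comparator_results.items()
        }
        scores, origins = [], {}
        for r in flagged:
            relevance = "DME" if r.term in dme else ("IME" if r.term in ime else "none")
            scores.append(
                prioritize.score_priority(
                    r.term, r.n_cases, total_records, r.ror_low,
                    deaths_by_term.get(r.term, 0), relevance,
                )
            )
            origins[r.term] = prioritize.classify_signal_origin(
                r.term, label_terms,
                {name: r.term in terms for name, terms in comp_flagged.items()},
            )
        counts["flagged_signals"] = len(flagged)
        _write(prioritize.priority_table(scores, origins), out / "priority.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stratified screens ------------------------------------------------
    stage = "stratify"
    stamp(stage)
    try:
        strat_records = _target_pt_records_with_strata(cases)
        for var, g1, g2 in config.strata:
            res = stratified.subgroup_screen(
                strat_records, var, g1, g2,
                min_cases=config.min_cases, alpha=config.alpha,
            )
            _write(stratified.volcano_table(res), out / f"volcano_{var}.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- regression ---------------------------------------------------------
    stage = "regress"
    stamp(stage)
    try:
        if any(config.outcome_pt in c.pts for c in cases):
            uni, multi = stratified.regression_workflow(
                cases, config.outcome_pt,
                target_synonyms=config.target_synonyms,
                alpha_enter=config.alpha,
            )
            _write(uni, out / "regression_univariate.tsv")
            multi_df = (
                multi.summary_frame() if multi is not None
                else pd.DataFrame(columns=["term", "coef", "odds_ratio",
                                           "ci_low", "ci_high", "p"])
            )
            _write(multi_df, out / "regression_multivariate.tsv")
        else:
            notes.append(
                f"regression skipped: outcome PT {config.outcome_pt!r} absent"
            )
            _write(pd.DataFrame(), out / "regression_univariate.tsv")
            _write(pd.DataFrame(), out / "regression_multivariate.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- time to onset -------------------------------------------------------
    stage = "tto"
    stamp(stage)
    try:
        samples, tto_excl = tto.compute_tto(cases)
        exclusions["tto"] = dict(tto_excl)
        counts["tto_samples"] = len(samples)
        _write(tto.tto_sample_table(samples), out / "tto_samples.tsv")
        _write(tto.binned_counts(samples), out / "tto_bins.tsv")
        _write(tto.soc_tto_summary(samples), out / "tto_soc_summary.tsv")
        weib: dict = {}
        if len(samples) >= 10:
            fit = tto.weibull_fit([s.days for s in samples])
            weib = {
                "shape": fit.shape, "scale": fit.scale,
                "shape_ci": list(fit.shape_ci), "scale_ci": list(fit.scale_ci),
                "n": fit.n, "failure_class": fit.failure_class,
            }
        (out / "tto_weibull.json").write_text(
            json.dumps(weib, indent=1, sort_keys=True), encoding="utf-8"
        )
        _write(_tto_test_table(samples), out / "tto_tests.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- descriptive ----------------------------------------------------------
    stage = "describe"
    stamp(stage)
    try:
        _write(descriptive_tables(cases), out / "descriptive.tsv")
        _write(
            concomitant_top(cases, 10, config.target_synonyms),
            out / "concomitant_top.tsv",
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    cfg_hash = hashlib.sha256(config.to_json().encode()).hexdigest()[:16]
    manifest = RunManifest(
        counts=counts, exclusions=exclusions, version=__version__,
        config_hash=cfg_hash, seed=config.seed, timestamps=stamps, notes=notes,
    )
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def _target_pt_records_with_strata(cases: Sequence[CaseReport]) -> pd.DataFrame:
    rows = []
    for c in cases:
        strata = {
            "sex": c.sex,
            "age_group": tto.age_group(c.age_years),
            "weight_group": tto.weight_group(c.weight_kg),
            "frequency": c.frequency,
            "dose": c.dose,
            "fatal": str(c.fatal),
        }
        for pt in sorted(c.pts):
            rows.append({"primaryid": c.primaryid, "pt": pt, **strata})
    return pd.DataFrame(rows)


def _tto_test_table(samples: Sequence[tto.TTOSample]) -> pd.DataFrame:
    """Log-rank / rank-sum comparisons for whichever strata have >=2 groups."""
    rows = []
    for var in ("sex", "age_group", "weight_group", "frequency", "fatal"):
        groups: dict[str, list[int]] = {}
        for s in samples:
            v = s.strata.get(var)
            if v is not None:
                groups.setdefault(str(v), []).append(s.days)
        usable = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            continue
        keys = sorted(usable)
        chi2, df, p = tto.logrank_test([usable[k] for k in keys])
        row = {"stratum": var, "groups": "|".join(keys),
               "logrank_chi2": round(chi2, 4), "df": df, "logrank_p": p}
        if len(keys) == 2:
            _, wp = tto.wilcoxon_rank_sum(usable[keys[0]], usable[keys[1]])
            row["wilcoxon_p"] = wp
        rows.append(row)
    return pd.DataFrame(rows)


def descriptive_tables(case_reports: Sequence[CaseReport]) -> pd.DataFrame:
    """Category counts and percentages with explicit missing rows.

    Percentages are over all reports; the outcome tabulation counts a
    report once per distinct outcome code.
    """
    n = len(case_reports)

    def tab(variable: str, values: Iterable) -> list[dict]:
        c = Counter("missing" if v is None else str(v) for v in values)
        return [
            {
                "variable": variable,
                "category": k,
                "n": v,
                "percent": round(100.0 * v / n, 2) if n else 0.0,
            }
            for k, v in sorted(c.items())
        ]

    rows: list[dict] = []
    rows += tab("year", (c.year for c in case_reports))
    rows += tab("reporter", (c.reporter for c in case_reports))
    rows += tab("age_group", (tto.age_group(c.age_years) for c in case_reports))
    rows += tab("sex", (c.sex for c in case_reports))
    rows += tab("weight_group", (tto.weight_group(c.weight_kg) for c in case_reports))
    rows += tab(
        "indication",
        (sorted(c.indications)[0] if c.indications else None for c in case_reports),
    )
    rows += tab("frequency", (c.frequency for c in case_reports))
    rows += tab("dose", (c.dose for c in case_reports))
    outcome_counter: Counter = Counter()
    for c in case_reports:
        if c.outcomes:
            outcome_counter.update(c.outcomes)
        else:
            outcome_counter["missing"] += 1
    rows += [
        {"variable": "outcome", "category": k, "n": v,
         "percent": round(100.0 * v / n, 2) if n else 0.0}
        for k, v in sorted(outcome_counter.items())
    ]
    rows += tab("country", (c.country for c in case_reports))
    return pd.DataFrame(rows, columns=["variable", "category", "n", "percent"])


def concomitant_top(
    case_reports: Sequence[CaseReport], k: int, target_synonyms: Iterable[str]
) -> pd.DataFrame:
    """Top-k co-reported (non-target) drug names by report count.

    A report naming a concomitant drug twice counts once; ties break
    alphabetically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    syn = normalize_synonyms(target_synonyms)
    counter: Counter = Counter()
    for c in case_reports:
        counter.update(name for name in c.all_drug_names if name not in syn)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(ranked, columns=["drugname", "n_reports"])
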