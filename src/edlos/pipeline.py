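"""End-to-end orchestration: simulate -> extract -> features -> compare.

Every stage persists its artifacts under the output directory and a
manifest records the config, master seed and a checksum per artifact,
so two runs with the same config and seed are byte-identical.  With
``resume=True`` stages whose artifacts already exist are skipped and
only downstream stages are recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .config import RunConfig, derive_seed
from .extraction import (
    extract_cohort_concepts,
    extract_mentions,
    read_stay_concepts_json,
    write_mentions_csv,
    write_stay_concepts_json,
)
from .features import FEATURE_SETS, build_feature_matrix, derive_stay_features, srf_report, concept_incidence
from .modeling import ComparisonReport, run_comparison
from .synthetic import (
    generate_cohort,
    generate_thesaurus,
    read_notes_jsonl,
    read_stays_csv,
    write_notes_jsonl,
    write_stays_csv,
)
from .synthetic import CCMU_ALPHABET
from .thesaurus import ThesaurusFormatError, load_thesaurus, save_thesaurus

__all__ = ["run_all", "validate_inputs", "render_markdown_report"]

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "simulate": ("thesaurus.tsv", "stays.csv", "notes.jsonl"),
    "extract": ("mentions.csv", "stay_concepts.json"),
    "features": tuple(
        f"features_{s}.{ext}" for s in FEATURE_SETS for ext in ("csv", "json")
    ) + ("srf_report.csv",),
    "compare": ("report.json", "report.md"),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(out: Path, stage: str) -> bool:
    return all((out / name).exists() for name in ARTIFACTS[stage])


def run_all(config: RunConfig, out_dir: str | Path, resume: bool = False) -> ComparisonReport:
    """Execute the full pipeline and persist all artifacts.

    Returns the model comparison; writes ``manifest.json`` last.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cues = config.resolved_cues()
    t0 = time.perf_counter()

    # -- simulate --------------------------------------------------------
    if resume and _stage_done(out, "simulate"):
        logger.info("simulate: artifacts present, skipping")
        th = load_thesaurus(out / "thesaurus.tsv")
        stays_df = read_stays_csv(out / "stays.csv")
        notes = read_notes_jsonl(out / "notes.jsonl")
    else:
        gen_config = dataclasses.replace(
            config.generator, seed=derive_seed(config.seed, "simulate")
        )
        th = generate_thesaurus(gen_config)
        stays, notes = generate_cohort(gen_config, th)
        save_thesaurus(th, out / "thesaurus.tsv")
        write_stays_csv(stays, out / "stays.csv")
        write_notes_jsonl(notes, out / "notes.jsonl")
        stays_df = read_stays_csv(out / "stays.csv")
        logger.info("simulate: %d stays, %d notes, %d concepts [%.1fs]",
                    len(stays), len(notes), len(th), time.perf_counter() - t0)

    # -- extract ---------------------------------------------------------
    if resume and _stage_done(out, "extract"):
        logger.info("extract: artifacts present, skipping")
        concepts_by_stay = read_stay_concepts_json(out / "stay_concepts.json")
    else:
        t1 = time.perf_counter()
        notes_by_stay: dict[str, list[dict]] = {}
        mentions = []
        for note in notes:
            notes_by_stay.setdefault(note.stay_id, []).append({"sentences": list(note.sentences)})
            mentions.extend(extract_mentions(note.stay_id, list(note.sentences), th, cues))
        concepts_by_stay = extract_cohort_concepts(notes_by_stay, th, cues)
        write_mentions_csv(mentions, out / "mentions.csv")
        write_stay_concepts_json(concepts_by_stay, out / "stay_concepts.json")
        logger.info("extract: %d mentions over %d stays [%.1fs]",
                    len(mentions), len(concepts_by_stay), time.perf_counter() - t1)

    # -- features --------------------------------------------------------
    derived = derive_stay_features(stays_df)
    if resume and _stage_done(out, "features"):
        logger.info("features: artifacts present, skipping")
    else:
        t2 = time.perf_counter()
        for fs in FEATURE_SETS:
            m = build_feature_matrix(derived, concepts_by_stay, fs, config.srf)
            m.to_frame().to_csv(out / f"features_{fs}.csv")
            (out / f"features_{fs}.json").write_text(
                json.dumps({"feature_set": fs, "columns": m.column_names}, indent=1) + "\n"
            )
        labels_by_stay = dict(zip(derived["stay_id"], derived["long_stay"]))
        incidence = concept_incidence(
            {sid: concepts_by_stay.get(sid, set()) for sid in derived["stay_id"]},
            labels_by_stay,
        )
        srf_report(incidence, config.srf).to_csv(out / "srf_report.csv", index=False)
        logger.info("features: matrices for %s [%.1fs]", FEATURE_SETS, time.perf_counter() - t2)

    # -- compare ---------------------------------------------------------
    t3 = time.perf_counter()
    report = run_comparison(
        derived,
        concepts_by_stay,
        srf_params=config.srf,
        space=config.search,
        train_fraction=config.train_fraction,
        seed=derive_seed(config.seed, "compare"),
        icu_subgroup=config.icu_subgroup,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
    (out / "report.md").write_text(render_markdown_report(report))
    logger.info("compare: accuracy structured %.3f / unstructured %.3f [%.1fs]",
                report.structured.accuracy, report.unstructured.accuracy, time.perf_counter() - t3)

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": {
            name: _sha256(out / name)
            for stage in ARTIFACTS
            for name in ARTIFACTS[stage]
            if (out / name).exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return report


def render_markdown_report(report: ComparisonReport) -> str:
    """Human-readable paired-metrics table plus concordance."""
    lines = [
        f"# Model comparison ({report.subgroup} stays)",
        "",
        f"Train / test: {report.n_train} / {report.n_test} stays; "
        f"majority-class rate {report.majority_rate:.3f}",
        "",
        "| Metric | Structured | Unstructured | Difference (pts) |",
        "|---|---|---|---|",
    ]
    for m in ("recall", "specificity", "precision", "accuracy", "f1"):
        s = getattr(report.structured, m)
        u = getattr(report.unstructured, m)
        lines.append(f"| {m} | {s:.1%} | {u:.1%} | {100 * (u - s):+.2f} |")
    lines += [
        "",
        f"Concordance: {report.concordance:.1%} of test stays received the same "
        f"prediction from both models.",
        "",
        f"Agreement table: {json.dumps(report.agreement_table, sort_keys=True)}",
        "",
        f"Best hyperparameters: {json.dumps(report.best_params, sort_keys=True)}",
        "",
    ]
    if report.icu is not None:
        lines += ["", render_markdown_report(report.icu)]
    return "\n".join(lines) + "\n"


def validate_inputs(
    stays_path: str | Path, notes_path: str | Path, thesaurus_path: str | Path
) -> list[str]:
    """Schema and referential-integrity checks on pipeline inputs.

    Returns a list of human-readable violations (empty when clean); row
    numbers are 1-based data rows of the stay CSV.
    """
    violations: list[str] = []
    try:
        stays = read_stays_csv(stays_path)
    except (ValueError, OSError) as exc:
        return [f"stays: unreadable or malformed: {exc}"]

    for i, row in stays.iterrows():
        rowno = int(i) + 1
        if pd.isna(row["ed_entry_time"]) or pd.isna(row["ed_exit_time"]):
            violations.append(f"stays row {rowno}: missing ED timestamps")
            continue
        if row["ed_exit_time"] <= row["ed_entry_time"]:
            violations.append(f"stays row {rowno}: ED exit not after entry")
        if row["total_los_days"] <= 0:
            violations.append(f"stays row {rowno}: non-positive total LOS")
        if str(row["ccmu"]) not in CCMU_ALPHABET:
            violations.append(f"stays row {rowno}: illegal CCMU value {row['ccmu']!r}")
        if not 1 <= int(row["gemsa"]) <= 6:
            violations.append(f"stays row {rowno}: GEMSA outside 1..6")
        code = str(row["icd10"])
        if not (3 <= len(code) <= 5 and code.isalnum()):
            violations.append(f"stays row {rowno}: malformed ICD-10 code {code!r}")
    if stays["stay_id"].duplicated().any():
        violations.append("stays: duplicate stay ids")

    try:
        notes = read_notes_jsonl(notes_path)
    except (ValueError, OSError, KeyError) as exc:
        violations.append(f"notes: unreadable or malformed: {exc}")
        notes = []
    known = set(stays["stay_id"])
    for note in notes:
        if note.stay_id not in known:
            violations.append(f"notes: unknown stay_id {note.stay_id!r}")

    try:
        load_thesaurus(thesaurus_path)
    except (ThesaurusFormatError, OSError) as exc:
        violations.append(f"thesaurus: {exc}")
    return violations
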