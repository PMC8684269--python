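"""Synthetic ED cohort generator.

Emits a stay table, free-text note documents with ground-truth planted
concept mentions, and a toy hierarchical thesaurus, with the statistical
shape the length-of-stay analysis assumes: ~5,000 ED-admitted stays over
a nine-month window, a long-tailed total LOS (median ~6 days) driven by
a latent severity, a near-ubiquitous concept (~98% of notes), ~17
planted concepts per note, negated and family-context sentences, ~13%
of stays with a prior ED visit within 7 days, and sparse severity-linked
ICD-10 primary diagnoses.

Everything is a deterministic function of (config, seed).  The latent
severity is ground truth for testing only: it is carried on the
in-memory records but never written to the stay CSV, and no downstream
feature may read it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, GeneratorConfig
from .thesaurus import Concept, ConceptThesaurus

__all__ = [
    "StayRecord",
    "NoteDocument",
    "generate_thesaurus",
    "generate_cohort",
    "stays_to_frame",
    "write_stays_csv",
    "read_stays_csv",
    "write_notes_jsonl",
    "read_notes_jsonl",
]

CCMU_ALPHABET = ("1", "2", "3", "4", "5", "P", "D")
ICU_WARD = "intensive care"

# head concepts (term, synonym); the first head stays childless so the
# ubiquitous concept is a leaf of the hierarchy
_HEADS = [
    ("blood pressure", "arterial tension"),
    ("pain", "dolor"),
    ("fever", "pyrexia"),
    ("cough", "tussis"),
    ("nausea", "queasiness"),
    ("headache", "cephalalgia"),
    ("fracture", "broken bone"),
    ("bleeding", "hemorrhage"),
    ("rash", "exanthema"),
    ("dizziness", "vertigo"),
    ("dyspnea", "breathlessness"),
    ("vomiting", "emesis"),
    ("diarrhea", "loose stools"),
    ("seizure", "convulsion"),
    ("fatigue", "asthenia"),
    ("palpitations", "racing heart"),
    ("confusion", "disorientation"),
    ("edema", "swelling"),
    ("jaundice", "icterus"),
    ("anemia", "low hemoglobin"),
]
_MODIFIERS = [
    "abdominal", "chest", "acute", "chronic", "severe", "mild",
    "lumbar", "cervical", "diffuse", "nocturnal", "recurrent", "postoperative",
]

_TEMPLATES = {
    "en": {
        "affirm": [
            "the patient reports {} since yesterday",
            "examination shows {}",
            "{} noted on arrival",
            "complains of {} this morning",
        ],
        "affirm2": ["{} and {} reported at triage"],
        "negation": [
            "no {} at admission",
            "the patient denies {}",
            "without {} today",
        ],
        "family": [
            "mother treated for {}",
            "family history of {}",
        ],
        "family_negation": [
            "no {} in the family",
            "father without {}",
        ],
        "filler": [
            "parameters stable during observation",
            "seen by the duty physician",
            "monitoring continued overnight",
        ],
    },
    "fr": {
        "affirm": [
            "le patient signale {} depuis hier",
            "examen retrouve {}",
            "{} constate a l'arrivee",
        ],
        "affirm2": ["{} et {} signales au tri"],
        "negation": [
            "pas de {} a l'admission",
            "le patient nie {}",
            "sans {} ce jour",
        ],
        "family": [
            "mère traitee pour {}",
            "antecedent dans la famille de {}",
        ],
        "family_negation": [
            "pas de {} dans la famille",
            "père sans {}",
        ],
        "filler": [
            "parametres stables durant la surveillance",
            "vu par le medecin de garde",
        ],
    },
}

_WARDS = [
    ("pulmonology", 0.188),
    ("digestive system", 0.165),
    ("cardiovascular medicine", 0.109),
    ("trauma and orthopaedics", 0.101),
    ("nervous system", 0.101),
    ("urology nephrology", 0.072),
    ("rheumatology", 0.068),
    ("endocrinology", 0.042),
    ("hematology", 0.042),
    ("other", 0.112),
]

_ZIPS = [f"10{i:03d}" for i in range(0, 15)]


@dataclass(frozen=True)
class StayRecord:
    """One ED-admitted hospital stay (total LOS includes the ED hours)."""

    stay_id: str
    patient_id: str
    age: int
    gender: str
    zip_code: str
    ed_entry_time: datetime
    ed_exit_time: datetime
    ed_los_hours: float
    ward: str
    ccmu_raw: str
    gemsa: int
    icd10: str
    total_los_days: float
    latent_severity: float  # generator-only ground truth


@dataclass(frozen=True)
class NoteDocument:
    """Free-text note of one stay with planted ground truth.

    ``ground_truth`` holds one entry per planted mention:
    (sentence_index, concept_id, subject, polarity, planted term).
    The term appears verbatim in the indexed sentence.
    """

    stay_id: str
    sentences: tuple[str, ...]
    ground_truth: tuple[tuple[int, str, str, str, str], ...] = field(default_factory=tuple)

    def patient_affirmation_concepts(self) -> set[str]:
        return {
            cid
            for (_, cid, subject, polarity, _) in self.ground_truth
            if subject == "patient" and polarity == "affirmation"
        }


def generate_thesaurus(config: GeneratorConfig) -> ConceptThesaurus:
    """Build the toy hierarchy: a root, head concepts, and modifier children.

    Children reuse the parent's head word ("pain" -> "abdominal pain"),
    so parent/child term-substring pairs always exist and most-precise
    matching is exercised.  Deterministic for a given config.
    """
    config.validate()
    n = config.n_concepts
    capacity = 1 + len(_HEADS) + (len(_HEADS) - 1) * len(_MODIFIERS)
    if n > capacity:
        raise ConfigError(f"n_concepts must be <= {capacity}")

    concepts = [Concept("C0000", None, "clinical finding")]
    head_ids: list[str] = []
    next_id = 1

    def take_id() -> str:
        nonlocal next_id
        cid = f"C{next_id:04d}"
        next_id += 1
        return cid

    n_heads = min(len(_HEADS), n - 1)
    for term, syn in _HEADS[:n_heads]:
        cid = take_id()
        head_ids.append(cid)
        concepts.append(Concept(cid, "C0000", term, frozenset({syn})))

    # round-robin modifier children over heads 2..k (head 1 stays a leaf)
    remaining = n - len(concepts)
    child_heads = head_ids[1:]
    depth = 0
    while remaining > 0:
        for hi, head_cid in enumerate(child_heads):
            if remaining == 0:
                break
            if depth >= len(_MODIFIERS):
                break
            head_term, head_syn = _HEADS[hi + 1]
            mod = _MODIFIERS[depth]
            concepts.append(
                Concept(
                    take_id(),
                    head_cid,
                    f"{mod} {head_term}",
                    frozenset({f"{mod} {head_syn}"}),
                )
            )
            remaining -= 1
        depth += 1
        if depth >= len(_MODIFIERS):
            break
    return ConceptThesaurus(concepts)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _seasonal_entry_times(rng, n, start: datetime, end: datetime):
    days = int((end - start).days)
    t = np.arange(days + 1)
    weights = 1.0 + 0.35 * np.sin(2 * np.pi * t / max(days, 1) * 1.5 + 0.7)
    weights /= weights.sum()
    day_idx = rng.choice(days + 1, size=n, p=weights)
    seconds = rng.integers(0, 86400, size=n)
    return [start + timedelta(days=int(d), seconds=int(s)) for d, s in zip(day_idx, seconds)]


def _sample_icd_codes(rng, severity):
    """Severity-tilted categorical over a sparse ICD-10-like code pool."""
    frequent = ["J189", "R53", "R060", "R104", "S7200"]
    tail = []
    for letter in "JRSKMINC":
        for i in range(8):
            tail.append(f"{letter}{10 + 7 * i}{i}")  # 4-char codes
    pool = frequent + tail
    base = np.array([4.2, 3.8, 3.5, 2.4, 2.4] + [3.0 / (r + 2) for r in range(len(tail))])
    base /= base.sum()
    # alternate codes between severe-leaning and mild-leaning
    tilt = np.array([(1 if i % 2 == 0 else -1) * 0.8 for i in range(len(pool))])
    codes = []
    for s in severity:
        w = base * np.exp(tilt * 0.8 * s)
        w /= w.sum()
        codes.append(pool[int(rng.choice(len(pool), p=w))])
    return codes


def _build_note(rng, stay_id, planted, lang):
    """Render planted (concept_id, term, subject, polarity) mentions into sentences."""
    tpl = _TEMPLATES[lang]
    sentences: list[str] = []
    ground_truth: list[tuple[int, str, str, str, str]] = []

    affirm = [(cid, term) for cid, term, subj, pol in planted if subj == "patient" and pol == "affirmation"]
    others = [(cid, term, subj, pol) for cid, term, subj, pol in planted if not (subj == "patient" and pol == "affirmation")]

    i = 0
    while i < len(affirm):
        if len(affirm) - i >= 2 and rng.random() < 0.35:
            (c1, t1), (c2, t2) = affirm[i], affirm[i + 1]
            idx = len(sentences)
            sentences.append(tpl["affirm2"][0].format(t1, t2))
            ground_truth.append((idx, c1, "patient", "affirmation", t1))
            ground_truth.append((idx, c2, "patient", "affirmation", t2))
            i += 2
        else:
            cid, term = affirm[i]
            idx = len(sentences)
            sentences.append(tpl["affirm"][int(rng.integers(len(tpl["affirm"])))].format(term))
            ground_truth.append((idx, cid, "patient", "affirmation", term))
            i += 1

    for cid, term, subj, pol in others:
        if subj == "patient":
            bank = tpl["negation"]
        elif pol == "affirmation":
            bank = tpl["family"]
        else:
            bank = tpl["family_negation"]
        idx = len(sentences)
        sentences.append(bank[int(rng.integers(len(bank)))].format(term))
        ground_truth.append((idx, cid, subj, pol, term))

    n_fill = int(rng.integers(1, 3))
    for _ in range(n_fill):
        sentences.append(tpl["filler"][int(rng.integers(len(tpl["filler"])))])

    order = rng.permutation(len(sentences))
    remap = {int(old): new for new, old in enumerate(order)}
    sentences = [sentences[int(old)] for old in order]
    ground_truth = sorted((remap[idx], cid, s, p, t) for idx, cid, s, p, t in ground_truth)
    return NoteDocument(stay_id, tuple(sentences), tuple(ground_truth))


def generate_cohort(
    config: GeneratorConfig, thesaurus: ConceptThesaurus
) -> tuple[list[StayRecord], list[NoteDocument]]:
    """Generate stays and notes satisfying the inclusion rule.

    Every emitted stay spent strictly more than two days in the post-ED
    ward; total LOS = ED hours + ward days, log-normal with a linear
    latent-severity shift on the log scale.  Concepts are planted into
    notes as an antichain of thesaurus leaves: informative leaves with
    probability increasing in severity, one ubiquitous leaf at its
    configured prevalence, and noise leaves filling the mean
    mentions-per-note target.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    start = datetime.fromisoformat(config.study_start)
    end = datetime.fromisoformat(config.study_end)

    severity = rng.standard_normal(n)
    entries = _seasonal_entry_times(rng, n, start, end)
    ed_los = np.clip(rng.lognormal(math.log(7.2), 0.5, size=n), 1.0, 48.0)

    # post-ED ward stay, truncated at > 2 days (inclusion rule)
    ward_days = np.empty(n)
    for i in range(n):
        d = 0.0
        while d <= 2.05:
            d = float(
                rng.lognormal(
                    config.long_tail_loc + config.severity_effect * severity[i],
                    config.long_tail_scale,
                )
            )
        ward_days[i] = d
    total_los = ed_los / 24.0 + ward_days

    age_noise = rng.standard_normal(n)
    age = np.clip(np.round(64 + 26 * (0.45 * severity + 0.89 * age_noise)), 0, 100).astype(int)
    gender = np.where(rng.random(n) < 0.466, "M", "F")
    zip_w = np.array([1.0 / (r + 1) for r in range(len(_ZIPS))])
    zip_w /= zip_w.sum()
    zips = [_ZIPS[int(i)] for i in rng.choice(len(_ZIPS), size=n, p=zip_w)]

    # intensive-care assignment rises with severity; other wards by share
    p_icu = np.clip(config.icu_fraction * np.exp(0.6 * severity) / math.exp(0.18), 0, 1)
    is_icu = rng.random(n) < p_icu
    ward_names = [w for w, _ in _WARDS]
    ward_probs = np.array([p for _, p in _WARDS])
    ward_probs /= ward_probs.sum()
    wards = [
        ICU_WARD if icu else ward_names[int(i)]
        for icu, i in zip(is_icu, rng.choice(len(ward_names), size=n, p=ward_probs))
    ]

    ccmu_num = np.clip(np.round(2.6 + 0.8 * severity + 0.8 * rng.standard_normal(n)), 1, 5)
    ccmu = [str(int(v)) for v in ccmu_num]
    special = rng.random(n)
    for i in range(n):
        if special[i] < 0.002:
            ccmu[i] = "D"
        elif special[i] < 0.030:
            ccmu[i] = "P"
    gemsa = np.clip(np.round(3.5 + 0.3 * severity + 1.2 * rng.standard_normal(n)), 1, 6).astype(int)
    icd = _sample_icd_codes(rng, severity)

    patient_ids = [f"P{i + 1:05d}" for i in range(n)]

    # give ~second_visit_rate of stays a same-patient prior ED visit < 7 days back
    m = int(round(config.second_visit_rate * n))
    eligible = [i for i in range(n) if entries[i] >= start + timedelta(days=8)]
    rng.shuffle(eligible)
    index_stays = eligible[:m]
    pool = [i for i in range(n) if i not in set(index_stays)]
    rng.shuffle(pool)
    for idx, prior in zip(index_stays, pool):
        patient_ids[prior] = patient_ids[idx]
        gap_days = 0.5 + 6.4 * rng.random()
        prior_entry = entries[idx] - timedelta(days=float(gap_days))
        entries[prior] = prior_entry.replace(microsecond=0)

    # -- concept planting ------------------------------------------------
    leaves = [cid for cid in thesaurus.concept_ids if thesaurus.is_leaf(cid)]
    ubiq = leaves[0]
    n_inf = config.n_informative_concepts
    if n_inf is None:
        n_inf = min(12, max(1, (len(leaves) - 1) // 4))
    informative = leaves[1 : 1 + n_inf]
    noise = leaves[1 + n_inf :]
    base_inf = 0.25 + 0.2 * rng.random(len(informative))
    expected_inf = float(np.sum(base_inf)) if len(informative) else 0.0
    residual = config.concepts_per_note - config.ubiquitous_concept_prevalence - expected_inf
    q_noise = float(np.clip(residual / max(1, len(noise)), 0.01, 0.9)) if noise else 0.0

    def pick_term(cid):
        c = thesaurus.get(cid)
        terms = sorted(c.terms)
        return terms[int(rng.integers(len(terms)))]

    stays: list[StayRecord] = []
    notes: list[NoteDocument] = []
    for i in range(n):
        sid = f"S{i + 1:05d}"
        exit_time = entries[i] + timedelta(hours=float(ed_los[i]))
        stays.append(
            StayRecord(
                stay_id=sid,
                patient_id=patient_ids[i],
                age=int(age[i]),
                gender=str(gender[i]),
                zip_code=zips[i],
                ed_entry_time=entries[i],
                ed_exit_time=exit_time,
                ed_los_hours=round(float(ed_los[i]), 2),
                ward=wards[i],
                ccmu_raw=ccmu[i],
                gemsa=int(gemsa[i]),
                icd10=icd[i],
                total_los_days=round(float(total_los[i]), 3),
                latent_severity=float(severity[i]),
            )
        )

        planted_ids: list[str] = []
        if rng.random() < config.ubiquitous_concept_prevalence:
            planted_ids.append(ubiq)
        p_inf = _sigmoid(np.log(base_inf / (1 - base_inf)) + 1.5 * severity[i])
        planted_ids += [cid for cid, p in zip(informative, p_inf) if rng.random() < p]
        planted_ids += [cid for cid in noise if rng.random() < q_noise]

        planted = []
        for cid in planted_ids:
            subj = "family" if rng.random() < config.family_rate else "patient"
            pol = "negation" if rng.random() < config.negation_rate else "affirmation"
            planted.append((cid, pick_term(cid), subj, pol))
        notes.append(_build_note(rng, sid, planted, config.language))

    return stays, notes


# -- artifact I/O --------------------------------------------------------

_CSV_COLUMNS = [
    "stay_id", "patient_id", "age", "gender", "zip_code",
    "ed_entry_time", "ed_exit_time", "ed_los_hours", "ward",
    "ccmu", "gemsa", "icd10", "total_los_days",
]


def stays_to_frame(stays: list[StayRecord]) -> pd.DataFrame:
    """Public stay table (the latent severity is deliberately dropped)."""
    return pd.DataFrame(
        {
            "stay_id": [s.stay_id for s in stays],
            "patient_id": [s.patient_id for s in stays],
            "age": [s.age for s in stays],
            "gender": [s.gender for s in stays],
            "zip_code": [s.zip_code for s in stays],
            "ed_entry_time": [s.ed_entry_time.isoformat() for s in stays],
            "ed_exit_time": [s.ed_exit_time.isoformat() for s in stays],
            "ed_los_hours": [s.ed_los_hours for s in stays],
            "ward": [s.ward for s in stays],
            "ccmu": [s.ccmu_raw for s in stays],
            "gemsa": [s.gemsa for s in stays],
            "icd10": [s.icd10 for s in stays],
            "total_los_days": [s.total_los_days for s in stays],
        }
    )


def write_stays_csv(stays: list[StayRecord], path: str | Path) -> None:
    stays_to_frame(stays).to_csv(path, index=False)


def read_stays_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zip_code": str, "ccmu": str, "icd10": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stay table missing columns: {missing}")
    for col in ("ed_entry_time", "ed_exit_time"):
        df[col] = pd.to_datetime(df[col])
    return df


def write_notes_jsonl(notes: list[NoteDocument], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "stay_id": note.stay_id,
                        "sentences": list(note.sentences),
                        "ground_truth": [list(g) for g in note.ground_truth],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_notes_jsonl(path: str | Path) -> list[NoteDocument]:
    notes = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            notes.append(
                NoteDocument(
                    stay_id=obj["stay_id"],
                    sentences=tuple(obj["sentences"]),
                    ground_truth=tuple(tuple(g) for g in obj.get("ground_truth", [])),
                )
            )
    return notes
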