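"""Feature engineering for the length-of-stay classifier.

Implements the study's engineered predictors and the assembly of the
three feature sets:

* ``common``      — age, gender, zip code, ED LOS, recent-visit flag,
                    short-term ED activity index, post-ED ward;
* ``structured``  — common + CCMU (numeric), GEMSA and rolled-up ICD-10
                    one-hot blocks;
* ``unstructured``— common + a multi-hot block of srf-relevant concepts.

Anything learned from the data — srf concept selection, ICD roll-up
counts, rare-zip bucketing, category vocabularies — is fit on the
training split only and applied unchanged to the test split; unseen
categories at transform time encode to all-zero rows in their block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SrfParams
from .synthetic import CCMU_ALPHABET

__all__ = [
    "FeatureMatrix",
    "FeatureSetError",
    "label_long_stay",
    "srf_score",
    "concept_incidence",
    "filter_relevant_concepts",
    "rollup_icd10",
    "encode_ccmu",
    "recent_visit_flag",
    "prior_7day_counts",
    "activity_index",
    "derive_stay_features",
    "FeatureBuilder",
    "build_feature_matrix",
    "FEATURE_SETS",
]

logger = logging.getLogger(__name__)

FEATURE_SETS = ("common", "structured", "unstructured")

WINDOW_DAYS = 7.0  # half-open [t - 7 d, t) for both the visit flag and the activity index


class FeatureSetError(ValueError):
    """Raised when a feature matrix cannot be assembled as requested."""


@dataclass
class FeatureMatrix:
    """Stays x features numeric grid with named columns and binary labels."""

    stay_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    feature_set: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names, index=self.stay_ids)
        df.index.name = "stay_id"
        return df


# -- elementary operations -----------------------------------------------


def label_long_stay(total_los_days: float, params: SrfParams | None = None) -> int:
    """1 iff the stay is a long stay (total LOS >= 7 days by default)."""
    threshold = (params or SrfParams()).long_stay_threshold_days
    if total_los_days <= 0:
        raise ValueError(f"total LOS must be positive, got {total_los_days}")
    return int(total_los_days >= threshold)


def srf_score(a: int, c: int) -> float:
    """Symmetric relevance frequency of a concept.

    ``a`` and ``c`` are the numbers of long (>= 7 d) and short (< 7 d)
    stays containing the concept; the score is
    log2(2 + max(a / max(1, c), c / max(1, a))) — symmetric in (a, c)
    and always >= 1.
    """
    if a < 0 or c < 0:
        raise ValueError("concept incidence counts must be non-negative")
    return math.log2(2.0 + max(a / max(1, c), c / max(1, a)))


def concept_incidence(
    concepts_by_stay: dict[str, set[str]], labels_by_stay: dict[str, int]
) -> dict[str, tuple[int, int]]:
    """Per-concept (long-stay count, short-stay count) over the given stays."""
    counts: dict[str, list[int]] = {}
    for sid, concepts in concepts_by_stay.items():
        y = labels_by_stay[sid]
        for cid in concepts:
            a_c = counts.setdefault(cid, [0, 0])
            a_c[0 if y == 1 else 1] += 1
    return {cid: (a, c) for cid, (a, c) in counts.items()}


def filter_relevant_concepts(
    incidence: dict[str, tuple[int, int]], params: SrfParams | None = None
) -> set[str]:
    """Concepts whose srf strictly exceeds the cutoff.

    A concept exactly at the cutoff (e.g. a=55, c=45 at the default 45%
    prevalence threshold) is non-relevant and dropped.  Incidence counts
    must come from the training split only.
    """
    params = params or SrfParams()
    cutoff = params.srf_cutoff
    return {cid for cid, (a, c) in incidence.items() if srf_score(a, c) > cutoff}


def srf_report(
    incidence: dict[str, tuple[int, int]], params: SrfParams | None = None
) -> pd.DataFrame:
    """Tabular srf audit: concept, counts, score, kept flag."""
    params = params or SrfParams()
    cutoff = params.srf_cutoff
    rows = [
        {"concept_id": cid, "a": a, "c": c, "srf": srf_score(a, c), "kept": srf_score(a, c) > cutoff}
        for cid, (a, c) in sorted(incidence.items())
    ]
    return pd.DataFrame(rows, columns=["concept_id", "a", "c", "srf", "kept"])


def rollup_icd10(code_counts: dict[str, int]) -> dict[str, str]:
    """Roll rare ICD-10 codes up the hierarchy.

    A code pooled with everything already rolled into its prefix must
    reach 5 occurrences, else it loses its last character, down to the
    3-character level.  Demotion is sequential bottom-up (longest code
    first, ties lexicographic) and re-pools after every step, so a
    parent rescued by its child's counts is not demoted.  Returns a
    total mapping original code -> surviving code.
    """
    for code in code_counts:
        if len(code) < 3:
            raise ValueError(f"ICD-10 code shorter than 3 characters: {code!r}")
    current = {code: code for code in code_counts}
    while True:
        pooled: dict[str, int] = {}
        for orig, cur in current.items():
            pooled[cur] = pooled.get(cur, 0) + code_counts[orig]
        deficient = [c for c, n in pooled.items() if n < 5 and len(c) > 3]
        if not deficient:
            return current
        target = max(deficient, key=lambda c: (len(c), c))
        for orig, cur in current.items():
            if cur == target:
                current[orig] = target[:-1]


def encode_ccmu(raw: str) -> int:
    """CCMU triage code to number: digits unchanged, D -> 6, P -> 0."""
    if raw not in CCMU_ALPHABET:
        raise ValueError(f"illegal CCMU code {raw!r}")
    if raw == "D":
        return 6
    if raw == "P":
        return 0
    return int(raw)


def recent_visit_flag(entry_time, prior_entries) -> int:
    """1 iff a prior ED admission falls in [entry - 7 d, entry).

    ``prior_entries`` are the patient's other ED entry timestamps and
    must all precede the index admission.
    """
    entry = pd.Timestamp(entry_time)
    lo = entry - pd.Timedelta(days=WINDOW_DAYS)
    for t in prior_entries:
        t = pd.Timestamp(t)
        if t >= entry:
            raise ValueError(f"prior admission {t} is not before the index admission {entry}")
        if lo <= t < entry:
            return 1
    return 0


def prior_7day_counts(entry_times: pd.Series) -> np.ndarray:
    """For each stay, the number of cohort ED admissions in [entry - 7 d, entry)."""
    entries = pd.to_datetime(entry_times).to_numpy()
    sorted_entries = np.sort(entries)
    lo = np.searchsorted(sorted_entries, entries - np.timedelta64(7, "D"), side="left")
    hi = np.searchsorted(sorted_entries, entries, side="left")
    return (hi - lo).astype(int)


def activity_index(k: np.ndarray | list[int], ks_cohort: np.ndarray | list[int]) -> np.ndarray:
    """Short-term ED activity (crowding) index in [0, 1].

    ``k`` are prior-7-day admission counts to score; ``ks_cohort`` the
    counts over all stays, from which the 1st and 9th deciles d1, d9 are
    taken.  Below d1 the index is 0, above d9 it is 1, and in between it
    is (k - d1) / (d9 - d1).  A degenerate cohort with d1 == d9 yields a
    constant 0.5 (logged).
    """
    k = np.asarray(k, dtype=float)
    ks = np.asarray(ks_cohort, dtype=float)
    if ks.size == 0:
        raise ValueError("cohort admission counts must be non-empty")
    d1, d9 = np.quantile(ks, [0.1, 0.9])
    if d1 == d9:
        logger.warning("degenerate prior-admission distribution (d1 == d9 == %s); index set to 0.5", d1)
        return np.full_like(k, 0.5)
    return np.clip((k - d1) / (d9 - d1), 0.0, 1.0)


def derive_stay_features(stays: pd.DataFrame) -> pd.DataFrame:
    """Add outcome-free derived columns to the stay table.

    ``recent_visit``: same-patient prior ED admission within 7 days;
    ``activity_index``: cohort-wide crowding index at entry.  Both use
    operational timestamps only, so they are computed before any split.
    """
    df = stays.copy()
    entries = pd.to_datetime(df["ed_entry_time"])
    flags = np.zeros(len(df), dtype=int)
    for _, idx in df.groupby("patient_id").groups.items():
        if len(idx) < 2:
            continue
        times = entries.loc[idx]
        for i in idx:
            t = times.loc[i]
            prior = [x for j, x in times.items() if j != i and x < t]
            if prior:
                flags[df.index.get_loc(i)] = recent_visit_flag(t, prior)
    df["recent_visit"] = flags
    ks = prior_7day_counts(entries)
    df["activity_index"] = activity_index(ks, ks)
    df["long_stay"] = [label_long_stay(v) for v in df["total_los_days"]]
    return df


# -- feature-set assembly -------------------------------------------------

_COMMON_NUMERIC = ["age", "ed_los_hours", "recent_visit", "activity_index"]
_COMMON_ONEHOT = ["gender", "zip_code", "ward"]


class FeatureBuilder:
    """Fit-on-train / transform-anywhere assembler for one feature set.

    ``fit`` learns, from training stays only: one-hot vocabularies
    (with rare zip codes pooled into an ``other`` bucket, mirroring the
    ICD rarity rule), the ICD-10 roll-up mapping, and — for the
    unstructured set — the srf-relevant concept subset, which needs the
    training labels.  ``transform`` never looks at labels.
    """

    def __init__(self, feature_set: str, srf_params: SrfParams | None = None):
        if feature_set not in FEATURE_SETS:
            raise FeatureSetError(f"unknown feature set {feature_set!r}")
        self.feature_set = feature_set
        self.srf_params = srf_params or SrfParams()
        self._fitted = False

    def fit(
        self,
        stays: pd.DataFrame,
        concepts_by_stay: dict[str, set[str]] | None = None,
        labels: pd.Series | np.ndarray | None = None,
    ) -> "FeatureBuilder":
        for col in _COMMON_NUMERIC:
            if col not in stays.columns:
                raise FeatureSetError(
                    f"column {col!r} missing; run derive_stay_features first"
                )
        self.categories_: dict[str, list[str]] = {}
        zip_counts = stays["zip_code"].value_counts()
        self.frequent_zips_ = sorted(zip_counts[zip_counts >= 5].index)
        self.categories_["gender"] = sorted(stays["gender"].unique())
        self.categories_["zip_code"] = self.frequent_zips_ + ["other"]
        self.categories_["ward"] = sorted(stays["ward"].unique())

        if self.feature_set == "structured":
            self.categories_["gemsa"] = sorted(int(g) for g in stays["gemsa"].unique())
            counts = stays["icd10"].value_counts().to_dict()
            self.icd_map_ = rollup_icd10(counts)
            self.categories_["icd10"] = sorted(set(self.icd_map_.values()))
        elif self.feature_set == "unstructured":
            if concepts_by_stay is None or labels is None:
                raise FeatureSetError(
                    "the unstructured set needs stay concepts and training labels"
                )
            labels = np.asarray(labels)
            train_concepts = {
                sid: concepts_by_stay.get(sid, set()) for sid in stays["stay_id"]
            }
            labels_by_stay = dict(zip(stays["stay_id"], labels))
            incidence = concept_incidence(train_concepts, labels_by_stay)
            self.incidence_ = incidence
            self.relevant_concepts_ = sorted(
                filter_relevant_concepts(incidence, self.srf_params)
            )
        self._fitted = True
        return self

    @property
    def column_names(self) -> list[str]:
        self._require_fitted()
        cols = list(_COMMON_NUMERIC)
        for col in _COMMON_ONEHOT:
            cols += [f"{col}={v}" for v in self.categories_[col]]
        if self.feature_set == "structured":
            cols.append("ccmu")
            cols += [f"gemsa={g}" for g in self.categories_["gemsa"]]
            cols += [f"icd10={c}" for c in self.categories_["icd10"]]
        elif self.feature_set == "unstructured":
            cols += [f"concept={cid}" for cid in self.relevant_concepts_]
        return cols

    def _require_fitted(self):
        if not self._fitted:
            raise FeatureSetError("builder is not fitted")

    def transform(
        self,
        stays: pd.DataFrame,
        concepts_by_stay: dict[str, set[str]] | None = None,
    ) -> FeatureMatrix:
        self._require_fitted()
        n = len(stays)
        blocks: list[np.ndarray] = [stays[_COMMON_NUMERIC].to_numpy(dtype=float)]

        def onehot(series: pd.Series, cats: list, rare_bucket: str | None = None):
            block = np.zeros((n, len(cats)), dtype=float)
            pos = {v: j for j, v in enumerate(cats)}
            for i, v in enumerate(series):
                j = pos.get(v)
                if j is None and rare_bucket is not None:
                    j = pos[rare_bucket]
                if j is not None:  # unseen category without a bucket -> all zeros
                    block[i, j] = 1.0
            return block

        blocks.append(onehot(stays["gender"], self.categories_["gender"]))
        blocks.append(onehot(stays["zip_code"], self.categories_["zip_code"], rare_bucket="other"))
        blocks.append(onehot(stays["ward"], self.categories_["ward"]))

        if self.feature_set == "structured":
            blocks.append(
                np.array([[encode_ccmu(str(v))] for v in stays["ccmu"]], dtype=float)
            )
            blocks.append(onehot(stays["gemsa"].astype(int), self.categories_["gemsa"]))
            rolled = [self.icd_map_.get(c, _fallback_rollup(c, self.categories_["icd10"])) for c in stays["icd10"]]
            blocks.append(onehot(pd.Series(rolled), self.categories_["icd10"]))
        elif self.feature_set == "unstructured":
            block = np.zeros((n, len(self.relevant_concepts_)), dtype=float)
            pos = {cid: j for j, cid in enumerate(self.relevant_concepts_)}
            for i, sid in enumerate(stays["stay_id"]):
                for cid in (concepts_by_stay or {}).get(sid, set()):
                    j = pos.get(cid)
                    if j is not None:
                        block[i, j] = 1.0
            blocks.append(block)

        labels = stays["long_stay"].to_numpy(dtype=int) if "long_stay" in stays else np.zeros(n, dtype=int)
        return FeatureMatrix(
            stay_ids=list(stays["stay_id"]),
            column_names=self.column_names,
            values=np.hstack(blocks),
            labels=labels,
            feature_set=self.feature_set,
        )


def _fallback_rollup(code: str, known: list[str]) -> str:
    """Map an unseen test-time ICD code onto the longest known prefix."""
    known_set = set(known)
    for ln in range(len(code), 2, -1):
        if code[:ln] in known_set:
            return code[:ln]
    return code  # no known prefix -> encodes to all-zeros


def build_feature_matrix(
    stays: pd.DataFrame,
    concepts_by_stay: dict[str, set[str]] | None,
    feature_set: str,
    srf_params: SrfParams | None = None,
) -> FeatureMatrix:
    """One-shot fit+transform on a single cohort (no train/test split)."""
    df = stays if "recent_visit" in stays.columns else derive_stay_features(stays)
    labels = df["long_stay"] if "long_stay" in df else None
    builder = FeatureBuilder(feature_set, srf_params)
    builder.fit(df, concepts_by_stay, labels)
    return builder.transform(df, concepts_by_stay)
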