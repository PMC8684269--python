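"""Run configuration: generator, extraction cues, srf filter, model search.

All configs are plain dataclasses with explicit validation and a lossless
YAML round-trip.  A single master seed deterministically derives every
stage seed, so one integer reproduces a full pipeline run.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "CueConfig",
    "SrfParams",
    "SearchSpace",
    "RunConfig",
    "DEFAULT_CUES",
    "derive_seed",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed (< 2**31) deterministically from the master seed."""
    ss = np.random.SeedSequence([master_seed, abs(hash_stage(stage))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def hash_stage(stage: str) -> int:
    # stable across processes (hash() of str is salted)
    h = 2166136261
    for ch in stage.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings.

    Defaults emulate the source study's cohort: ~5,000 ED-admitted stays
    over 1 Jan - 24 Sep 2019, long-tailed total LOS with median ~6 days,
    a near-ubiquitous concept (~98% of notes), ~17 concepts per note and
    ~13% of stays with a recent prior ED visit.
    """

    n_stays: int = 5000
    seed: int = 0
    #: log-normal location/scale of the post-ED ward stay, log-day scale
    long_tail_loc: float = math.log(5.0)
    long_tail_scale: float = 0.8
    #: strength of the latent-severity -> log LOS link (log-days per SD)
    severity_effect: float = 0.8
    n_concepts: int = 80
    #: None -> min(12, one quarter of the hierarchy's leaves)
    n_informative_concepts: int | None = None
    ubiquitous_concept_prevalence: float = 0.983
    #: target mean number of planted concept mentions per note
    concepts_per_note: float = 17.2
    negation_rate: float = 0.15
    family_rate: float = 0.05
    second_visit_rate: float = 0.13
    icu_fraction: float = 0.076
    language: str = "en"
    study_start: str = "2019-01-01"
    study_end: str = "2019-09-24"

    def validate(self) -> "GeneratorConfig":
        if self.n_stays <= 0:
            raise ConfigError("n_stays must be positive")
        if self.n_concepts < 3:
            raise ConfigError("n_concepts must be >= 3")
        if (
            self.n_informative_concepts is not None
            and self.n_informative_concepts > self.n_concepts
        ):
            raise ConfigError("n_informative_concepts must be <= n_concepts")
        for name in (
            "ubiquitous_concept_prevalence",
            "negation_rate",
            "family_rate",
            "second_visit_rate",
            "icu_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.long_tail_scale <= 0:
            raise ConfigError("long_tail_scale must be positive")
        if self.study_start >= self.study_end:
            raise ConfigError("study window must be non-empty")
        if self.language not in ("en", "fr"):
            raise ConfigError(f"unsupported language {self.language!r}")
        return self


@dataclass
class CueConfig:
    """Sentence-scope cue lexicons for context classification.

    A sub-text is family-related iff any family cue occurs, negated iff
    any negation cue occurs; the two axes are independent and the absence
    of cues yields patient-affirmation (neutral counts as affirmation).
    """

    negation_cues: tuple[str, ...]
    family_cues: tuple[str, ...]
    scope: str = "sentence"

    def validate(self) -> "CueConfig":
        if not self.negation_cues or not self.family_cues:
            raise ConfigError("cue lists must be non-empty")
        if self.scope != "sentence":
            raise ConfigError("only sentence scope is supported")
        return self


DEFAULT_CUES: dict[str, CueConfig] = {
    "en": CueConfig(
        negation_cues=("no", "not", "denies", "without", "absence of", "negative for"),
        family_cues=("mother", "father", "family", "brother", "sister", "familial"),
    ),
    "fr": CueConfig(
        negation_cues=("pas de", "aucun", "aucune", "sans", "nie", "absence de"),
        family_cues=("mère", "père", "famille", "frère", "soeur", "familial"),
    ),
}


@dataclass
class SrfParams:
    """Long-stay threshold and srf relevance filter settings.

    ``srf_cutoff`` is derived from the prevalence threshold p as
    log2(2 + (1-p)/p); at the default p = 0.45 this is 1.688 (3 d.p.).
    Concepts with srf <= cutoff are non-relevant.
    """

    long_stay_threshold_days: float = 7.0
    prevalence_threshold: float = 0.45

    @property
    def srf_cutoff(self) -> float:
        p = self.prevalence_threshold
        return math.log2(2.0 + (1.0 - p) / p)

    def validate(self) -> "SrfParams":
        if self.long_stay_threshold_days <= 0:
            raise ConfigError("long_stay_threshold_days must be positive")
        if not 0.0 < self.prevalence_threshold < 0.5:
            raise ConfigError("prevalence_threshold must be in (0, 0.5)")
        return self


@dataclass
class SearchSpace:
    """Random-search space for the random-forest hyperparameters.

    Bounds are inclusive integer ranges.  The lower bound of
    ``min_samples_split`` is 5 so splits remain possible on infrequent
    diagnosis codes; 50 sampled combinations scored by mean accuracy over
    3 CV folds are the study defaults.
    """

    n_estimators: tuple[int, int] = (50, 500)
    min_samples_split: tuple[int, int] = (5, 50)
    min_samples_leaf: tuple[int, int] = (1, 20)
    n_iterations: int = 50
    n_folds: int = 3
    seed: int = 0

    def validate(self) -> "SearchSpace":
        for name in ("n_estimators", "min_samples_split", "min_samples_leaf"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        if self.min_samples_split[0] < 5:
            raise ConfigError("min_samples_split lower bound must be >= 5")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        return self


@dataclass
class RunConfig:
    """Everything needed for an end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cues: CueConfig | None = None  # None -> language default
    srf: SrfParams = field(default_factory=SrfParams)
    search: SearchSpace = field(default_factory=SearchSpace)
    train_fraction: float = 0.8
    icu_subgroup: bool = False
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.generator.validate()
        self.resolved_cues().validate()
        self.srf.validate()
        self.search.validate()
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        return self

    def resolved_cues(self) -> CueConfig:
        return self.cues if self.cues is not None else DEFAULT_CUES[self.generator.language]

    # -- YAML round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["cues"] is not None:
            d["cues"]["negation_cues"] = list(d["cues"]["negation_cues"])
            d["cues"]["family_cues"] = list(d["cues"]["family_cues"])
        for key in ("n_estimators", "min_samples_split", "min_samples_leaf"):
            d["search"][key] = list(d["search"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = GeneratorConfig(**d.get("generator", {}))
        cues_d = d.get("cues")
        cues = (
            CueConfig(
                negation_cues=tuple(cues_d["negation_cues"]),
                family_cues=tuple(cues_d["family_cues"]),
                scope=cues_d.get("scope", "sentence"),
            )
            if cues_d
            else None
        )
        srf = SrfParams(**d.get("srf", {}))
        search_d = dict(d.get("search", {}))
        for key in ("n_estimators", "min_samples_split", "min_samples_leaf"):
            if key in search_d:
                search_d[key] = tuple(search_d[key])
        search = SearchSpace(**search_d)
        return cls(
            generator=gen,
            cues=cues,
            srf=srf,
            search=search,
            train_fraction=d.get("train_fraction", 0.8),
            icu_subgroup=d.get("icu_subgroup", False),
            seed=d.get("seed", 0),
        ).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
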