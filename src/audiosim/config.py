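"""Run configuration: validated, with clinical defaults.

Every tunable of a full simulation run lives in :class:`RunConfig`. The
defaults equal the clinical constants of the automated procedures (17-word
lists, early stop after 7 words below 15%, 0-90 dB HL presentation range,
60 dB SPL fixed speech level in noise, the SNR condition orders). Unknown
keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .listener import SRT_LINK_DEFAULTS
from .procedures import ProcedureConfig
from .scoring import PREVALIDATION, ScorerConfig

__all__ = [
    "ConfigError",
    "MaterialSpec",
    "CohortSpec",
    "ScorerSpec",
    "ProcedureOptions",
    "AnalysisOptions",
    "RunConfig",
    "load_config",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialSpec(_Model):
    """Shape of the generated speech material (defaults: clinical shapes)."""

    n_lists: Optional[int] = None  # default: 20 in quiet, 5 in noise
    words_per_list: int = 17
    phonemes_per_word: int = 3
    n_vowels: int = 6
    n_consonants: int = 12

    def resolved_n_lists(self, mode: str) -> int:
        if self.n_lists is not None:
            return self.n_lists
        return 20 if mode == "quiet" else 5


class CohortSpec(_Model):
    """Virtual-listener cohort: size and parameter distributions."""

    n: int = 10
    pta_min: float = 0.0
    pta_max: Optional[float] = None  # default: 80 in quiet, 70 in noise
    slope50_min: float = 3.0
    slope50_max: float = 8.0
    link_a: Optional[float] = None  # default by axis (SRT = a*PTA + b + noise)
    link_b: Optional[float] = None
    link_sigma: Optional[float] = None
    audiogram_jitter: float = 5.0
    ceiling_rolloff: float = 0.4
    confusion_mode: Literal["substitute_uniform", "omit"] = "substitute_uniform"

    def resolved_pta_max(self, mode: str) -> float:
        if self.pta_max is not None:
            return self.pta_max
        return 80.0 if mode == "quiet" else 70.0

    def resolved_link(self, axis: str) -> tuple[float, float, float]:
        a0, b0, s0 = SRT_LINK_DEFAULTS[axis]
        return (
            self.link_a if self.link_a is not None else a0,
            self.link_b if self.link_b is not None else b0,
            self.link_sigma if self.link_sigma is not None else s0,
        )


class ScorerSpec(_Model):
    """ASR-scorer noise model; rates default to the pre-validation values."""

    p_err_given_correct: Optional[float] = None
    p_err_given_incorrect: Optional[float] = None
    error_token_policy: Literal["to_unknown", "to_random_phoneme", "mixed"] = (
        "to_unknown"
    )
    mixed_weight: float = 0.5

    def resolved(self, mode: str) -> ScorerConfig:
        rates = PREVALIDATION[mode]
        p_c = (
            self.p_err_given_correct
            if self.p_err_given_correct is not None
            else 1.0 - rates["phoneme_accuracy"]
        )
        p_i = (
            self.p_err_given_incorrect
            if self.p_err_given_incorrect is not None
            else rates["phoneme_error_rate"]
        )
        return ScorerConfig(
            p_err_given_correct=p_c,
            p_err_given_incorrect=p_i,
            error_token_policy=self.error_token_policy,
            mixed_weight=self.mixed_weight,
        )


class ProcedureOptions(_Model):
    """Adaptive-procedure constants (defaults: the clinical rules)."""

    early_stop_threshold_pct: float = 15.0
    early_stop_after_words: int = 7
    pl_min: float = 0.0
    pl_max: float = 90.0
    descend_step: float = 10.0
    ascend_step: float = 10.0
    high_level_cutoff: float = 80.0
    high_level_step: float = 5.0
    reversal_tolerance: float = 0.0
    min_interior_points: int = 3
    max_added_points: int = 5
    reference_scorer: str = "oracle"
    stimulus_level_spl: float = 60.0
    reuse_lists: bool = True

    def resolved(self) -> ProcedureConfig:
        return ProcedureConfig(**self.model_dump())


class AnalysisOptions(_Model):
    method: Literal["interpolation", "logistic_fit"] = "interpolation"
    convergence_grouping: Literal["per_subject", "per_list"] = "per_subject"


class RunConfig(_Model):
    """Everything one reproducible run needs."""

    mode: Literal["quiet", "noise"] = "quiet"
    seed: int = 0
    retest: bool = False
    material: MaterialSpec = MaterialSpec()
    cohort: CohortSpec = CohortSpec()
    scorer: ScorerSpec = ScorerSpec()
    procedure: ProcedureOptions = ProcedureOptions()
    analysis: AnalysisOptions = AnalysisOptions()


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the all-defaults configuration; unknown or
    malformed keys raise :class:`ConfigError` naming the offending key.
    """
    text = Path(path).read_text(encoding="utf-8")
    if text.strip() == "":
        return RunConfig()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping at the top level")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration in {path}: {details}") from exc
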