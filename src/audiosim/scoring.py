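"""Phoneme-level scoring of verbal responses.

Two scorers are provided. The *oracle* scorer models a human expert who
hears the patient's repetition perfectly: its transcription is exactly the
uttered phoneme sequence. The *ASR* scorer models an automated speech
recognizer operating on the patient's audio: each uttered phoneme is
transcribed faithfully except with a per-phoneme error probability that
depends on whether the repetition of that phoneme was itself correct
(recognizers are measurably better on clean, correct repetitions than on
distorted ones). Error probabilities are calibrated from pre-validation
accuracies of a clinical phoneme-level recognizer: on the quiet-test
material, phoneme accuracy 0.979 on correctly repeated samples and phoneme
error rate 0.174 on incorrectly repeated samples; on the noise-test
logatoms, 0.964 and 0.161.

A transcription is a token sequence over the phoneme inventory plus two
reserved tokens: ``UNKNOWN`` (the recognizer cannot identify the phoneme;
it never matches any target phoneme) and ``BLANK`` (no phoneme detected;
stripped before alignment).

Target and transcription are aligned by global minimum-edit-distance
(Needleman-Wunsch with unit costs). Ties in the traceback are broken in a
fixed order - match > substitution > deletion > insertion - so alignments
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Literal, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .listener import Utterance
    from .materials import PhonemeInventory

__all__ = [
    "UNKNOWN",
    "BLANK",
    "Transcription",
    "AlignmentResult",
    "ScorerConfig",
    "ScoredSample",
    "UndefinedMetricError",
    "align_phonemes",
    "phoneme_score",
    "word_correct",
    "corpus_metrics",
    "oracle_scorer",
    "asr_scorer",
    "OracleScorer",
    "ASRScorer",
]

#: Reserved scorer tokens (not part of any phoneme inventory).
UNKNOWN = "<unk>"
BLANK = "<blank>"

#: Pre-validation rates of the reference clinical recognizer, by material.
PREVALIDATION = {
    "quiet": {"phoneme_accuracy": 0.979, "phoneme_error_rate": 0.174},
    "noise": {"phoneme_accuracy": 0.964, "phoneme_error_rate": 0.161},
}


class UndefinedMetricError(ValueError):
    """A corpus metric was requested on an empty stratum."""


@dataclass(frozen=True)
class Transcription:
    """Scorer output: a token sequence over inventory + {UNKNOWN, BLANK}."""

    tokens: tuple[str, ...]

    def without_blanks(self) -> tuple[str, ...]:
        return tuple(t for t in self.tokens if t != BLANK)


@dataclass(frozen=True)
class AlignmentResult:
    """Counts and aligned index pairs of one target/transcription alignment.

    ``pairs`` lists ``(target_index, transcription_index)`` with ``None``
    marking a gap; indices refer to the blank-stripped transcription.
    """

    n_match: int
    n_substitution: int
    n_insertion: int
    n_deletion: int
    pairs: tuple[tuple[int | None, int | None], ...]

    @property
    def edit_distance(self) -> int:
        return self.n_substitution + self.n_insertion + self.n_deletion


def _tokens_of(transcription: "Transcription | Sequence[str]") -> tuple[str, ...]:
    if isinstance(transcription, Transcription):
        return transcription.without_blanks()
    return tuple(t for t in transcription if t != BLANK)


def _phonemes_of(word) -> tuple[str, ...]:
    return tuple(getattr(word, "phonemes", word))


def align_phonemes(
    target: Sequence[str], transcription: "Transcription | Sequence[str]"
) -> AlignmentResult:
    """Globally align ``transcription`` against ``target`` with unit costs.

    UNKNOWN tokens can never match a target phoneme (they always count as
    substitutions or insertions). BLANK tokens are stripped first.
    """
    t = _phonemes_of(target)
    if len(t) == 0:
        raise ValueError("target must be non-empty")
    s = _tokens_of(transcription)
    m, n = len(t), len(s)

    dist = np.empty((m + 1, n + 1), dtype=np.int64)
    dist[:, 0] = np.arange(m + 1)
    dist[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        ti = t[i - 1]
        row = dist[i]
        prev = dist[i - 1]
        for j in range(1, n + 1):
            sub = 0 if (s[j - 1] == ti and s[j - 1] != UNKNOWN) else 1
            row[j] = min(prev[j - 1] + sub, prev[j] + 1, row[j - 1] + 1)

    # traceback, preferring match > substitution > deletion > insertion
    pairs: list[tuple[int | None, int | None]] = []
    n_match = n_sub = n_ins = n_del = 0
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            is_match = t[i - 1] == s[j - 1] and s[j - 1] != UNKNOWN
            diag_ok = dist[i, j] == dist[i - 1, j - 1] + (0 if is_match else 1)
            if diag_ok and is_match:
                pairs.append((i - 1, j - 1))
                n_match += 1
                i, j = i - 1, j - 1
                continue
            if diag_ok:
                pairs.append((i - 1, j - 1))
                n_sub += 1
                i, j = i - 1, j - 1
                continue
        if i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            pairs.append((i - 1, None))
            n_del += 1
            i -= 1
            continue
        pairs.append((None, j - 1))
        n_ins += 1
        j -= 1
    pairs.reverse()
    return AlignmentResult(n_match, n_sub, n_ins, n_del, tuple(pairs))


def phoneme_score(
    target: Sequence[str], transcription: "Transcription | Sequence[str]"
) -> tuple[int, int, float]:
    """Correct-phoneme count, target length and percent score for one word."""
    t = _phonemes_of(target)
    aln = align_phonemes(t, transcription)
    n_total = len(t)
    return aln.n_match, n_total, 100.0 * aln.n_match / n_total


def word_correct(
    target, transcription: "Transcription | Sequence[str]"
) -> bool:
    """True iff every target phoneme matches and nothing extra was inserted."""
    t = _phonemes_of(target)
    aln = align_phonemes(t, transcription)
    return aln.n_match == len(t) and aln.n_insertion == 0


@dataclass(frozen=True)
class ScoredSample:
    """One scored word: target, uttered ground truth, transcription, stratum.

    ``correct_repetition`` flags whether the patient repeated the word
    correctly (in which case ``uttered`` equals ``target``); accuracy
    metrics are computed on the correct stratum and error-rate metrics,
    which are relative to the *uttered* ground truth, on the incorrect one.
    """

    target: tuple[str, ...]
    uttered: tuple[str, ...]
    transcription: Transcription
    correct_repetition: bool


def corpus_metrics(
    samples: Sequence[ScoredSample], strict: bool = True
) -> dict[str, float | None]:
    """Word/phoneme accuracy and error-rate metrics over a scored corpus.

    Over correct repetitions: ``word_accuracy`` is the fraction of words
    transcribed fully correctly and ``phoneme_accuracy`` the pooled
    fraction of target phonemes matched. Over incorrect repetitions:
    ``word_error_rate`` is the fraction of wrongly repeated words that the
    scorer nevertheless transcribes as a fully correct repetition of the
    *target* (the scorer wrongly credits the patient), and
    ``phoneme_error_rate`` the pooled fraction of *uttered* phonemes
    transcribed wrongly.

    With ``strict`` (default) an empty stratum raises
    :class:`UndefinedMetricError`; otherwise its metrics are ``None``.
    """
    if len(samples) == 0:
        raise UndefinedMetricError("empty corpus")
    correct = [s for s in samples if s.correct_repetition]
    incorrect = [s for s in samples if not s.correct_repetition]
    out: dict[str, float | None] = {
        "word_accuracy": None,
        "phoneme_accuracy": None,
        "word_error_rate": None,
        "phoneme_error_rate": None,
    }
    if correct:
        n_word_ok = sum(word_correct(s.target, s.transcription) for s in correct)
        n_match = n_total = 0
        for s in correct:
            m, t, _ = phoneme_score(s.target, s.transcription)
            n_match += m
            n_total += t
        out["word_accuracy"] = n_word_ok / len(correct)
        out["phoneme_accuracy"] = n_match / n_total
    elif strict:
        raise UndefinedMetricError("no correctly repeated samples in corpus")
    if incorrect:
        n_credited = sum(word_correct(s.target, s.transcription) for s in incorrect)
        n_match_u = n_total_u = 0
        for s in incorrect:
            if len(s.uttered) == 0:
                continue
            m, t, _ = phoneme_score(s.uttered, s.transcription)
            n_match_u += m
            n_total_u += t
        out["word_error_rate"] = n_credited / len(incorrect)
        if n_total_u == 0:
            if strict:
                raise UndefinedMetricError(
                    "incorrect stratum contains no uttered phonemes"
                )
        else:
            out["phoneme_error_rate"] = 1.0 - n_match_u / n_total_u
    elif strict:
        raise UndefinedMetricError("no incorrectly repeated samples in corpus")
    return out


def oracle_scorer(utterance: "Utterance") -> Transcription:
    """Perfect manual scorer: transcribes the uttered phonemes verbatim."""
    return Transcription(tuple(utterance.phonemes))


@dataclass(frozen=True)
class ScorerConfig:
    """Noise model of the ASR-emulating scorer.

    ``p_err_given_correct`` / ``p_err_given_incorrect`` are per-phoneme
    transcription error probabilities conditioned on whether the uttered
    phoneme was a correct repetition of the target. On error the phoneme is
    replaced according to ``error_token_policy``: ``to_unknown`` emits the
    UNKNOWN token, ``to_random_phoneme`` a uniformly random *different*
    inventory phoneme, and ``mixed`` emits UNKNOWN with probability
    ``mixed_weight`` and a random phoneme otherwise.
    """

    p_err_given_correct: float
    p_err_given_incorrect: float
    error_token_policy: Literal["to_unknown", "to_random_phoneme", "mixed"] = (
        "to_unknown"
    )
    mixed_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_err_given_correct", "p_err_given_incorrect", "mixed_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.error_token_policy not in ("to_unknown", "to_random_phoneme", "mixed"):
            raise ValueError(f"unknown error_token_policy {self.error_token_policy!r}")

    @classmethod
    def from_prevalidation(cls, material_kind: str, **kwargs) -> "ScorerConfig":
        """Config calibrated to the reference recognizer's pre-validation rates."""
        rates = PREVALIDATION[material_kind]
        return cls(
            p_err_given_correct=1.0 - rates["phoneme_accuracy"],
            p_err_given_incorrect=rates["phoneme_error_rate"],
            **kwargs,
        )


def _uttered_correct_flags(utterance: "Utterance") -> tuple[bool, ...]:
    # substitution-mode utterances keep 1:1 alignment with the target; with
    # omission only correctly repeated phonemes survive in the utterance
    if len(utterance.phonemes) == len(utterance.per_phoneme_correct):
        return tuple(utterance.per_phoneme_correct)
    return tuple(True for _ in utterance.phonemes)


def _error_token(
    phoneme: str,
    cfg: ScorerConfig,
    rng: np.random.Generator,
    inventory: "PhonemeInventory | None",
) -> str:
    policy = cfg.error_token_policy
    if policy == "mixed":
        policy = "to_unknown" if rng.random() < cfg.mixed_weight else "to_random_phoneme"
    if policy == "to_unknown":
        return UNKNOWN
    if inventory is None:
        raise ValueError("error_token_policy to_random_phoneme requires an inventory")
    others = [s for s in inventory.symbols if s != phoneme]
    if not others:
        return UNKNOWN
    return others[int(rng.integers(len(others)))]


def asr_scorer(
    utterance: "Utterance",
    cfg: ScorerConfig,
    rng: np.random.Generator,
    inventory: "PhonemeInventory | None" = None,
) -> Transcription:
    """Noisy automated scorer; deterministic given the generator state."""
    flags = _uttered_correct_flags(utterance)
    tokens = []
    for phoneme, was_correct in zip(utterance.phonemes, flags):
        p_err = cfg.p_err_given_correct if was_correct else cfg.p_err_given_incorrect
        if rng.random() < p_err:
            tokens.append(_error_token(phoneme, cfg, rng, inventory))
        else:
            tokens.append(phoneme)
    return Transcription(tuple(tokens))


class OracleScorer:
    """Callable wrapper for the perfect manual-equivalent scorer."""

    name = "oracle"

    def transcribe(
        self, utterance: "Utterance", rng: np.random.Generator
    ) -> Transcription:
        return oracle_scorer(utterance)


class ASRScorer:
    """Callable wrapper binding an ASR noise model to an inventory."""

    name = "asr"

    def __init__(
        self, cfg: ScorerConfig, inventory: "PhonemeInventory | None" = None
    ) -> None:
        self.cfg = cfg
        self.inventory = inventory

    def transcribe(
        self, utterance: "Utterance", rng: np.random.Generator
    ) -> Transcription:
        return asr_scorer(utterance, self.cfg, rng, self.inventory)
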