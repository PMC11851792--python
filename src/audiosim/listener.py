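"""Virtual listener: the simulated patient of the speech audiometry tests.

A listener is described by an audiogram (air-conduction thresholds) and a
four-parameter logistic psychometric function on the test axis
(presentation level in dB HL for speech in quiet; SNR in dB for speech in
noise):

    p(x) = floor + (ceiling - floor) / (1 + exp(-k * (x - x0)))   [percent]

The curve is parameterized clinically by its speech reception threshold
``srt`` (the x at which intelligibility is 50%) and ``slope50`` (the
derivative, in % per dB, at that point); the internal steepness ``k`` and
midpoint ``x0`` are derived from them. ``floor`` and ``ceiling`` bound the
curve; a ceiling below 100% models the reduced maximum intelligibility
(rollover) seen with cochlear hearing loss.

Responses are generated per phoneme: each phoneme of the presented word is
repeated correctly with probability p(x), independently; wrong phonemes are
replaced (or omitted) according to a confusion policy. This mirrors
phoneme-level clinical scoring, which records each phoneme as correct or
not without modelling which confusion occurred.

For cohort simulation the SRT is linked to the pure-tone average (PTA) by
``srt = a * PTA + b + N(0, sigma)``; speech and tonal thresholds correlate
strongly in clinical data, and the defaults here are plausible placeholders
for that link, not clinical estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .scoring import UNKNOWN

__all__ = [
    "PTA_FREQUENCIES",
    "Audiogram",
    "ConfusionPolicy",
    "ListenerProfile",
    "Utterance",
    "InvalidProfileError",
    "intelligibility_probability",
    "respond",
    "profile_from_audiogram",
    "flat_audiogram",
    "make_cohort",
    "SRT_LINK_DEFAULTS",
    "K_MAX",
]

#: Frequencies (Hz) entering the pure-tone average.
PTA_FREQUENCIES = (500.0, 1000.0, 2000.0, 4000.0)

#: Cap on the internal logistic steepness (per dB); bounds attainable slopes.
K_MAX = 10.0

#: Default PTA -> SRT link (a, b, sigma) per test axis.
SRT_LINK_DEFAULTS = {
    "level_dB_HL": (1.0, 5.0, 5.0),
    "snr_dB": (0.15, -9.0, 2.0),
}


class InvalidProfileError(ValueError):
    """The psychometric parameters do not define a valid 50% crossing."""


@dataclass(frozen=True)
class Audiogram:
    """Air-conduction thresholds (dB HL) by frequency (Hz)."""

    thresholds: Mapping[float, float]

    def __post_init__(self) -> None:
        freqs = {float(f) for f in self.thresholds}
        missing = [f for f in PTA_FREQUENCIES if f not in freqs]
        if missing:
            raise ValueError(f"audiogram misses PTA frequencies: {missing}")
        for f, t in self.thresholds.items():
            if not -10.0 <= t <= 120.0:
                raise ValueError(f"threshold {t} dB HL at {f} Hz outside [-10, 120]")

    def to_dict(self) -> dict:
        return {str(float(f)): float(t) for f, t in sorted(self.thresholds.items())}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Audiogram":
        return cls({float(f): float(t) for f, t in d.items()})


@dataclass(frozen=True)
class ConfusionPolicy:
    """What a wrong phoneme repetition sounds like.

    ``substitute_uniform`` replaces it with a uniformly random different
    inventory phoneme, ``substitute_matrix`` draws from a per-phoneme
    confusion distribution (rows exclude the identity and sum to 1), and
    ``omit`` drops it from the utterance.
    """

    mode: Literal["substitute_uniform", "substitute_matrix", "omit"] = (
        "substitute_uniform"
    )
    matrix: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("substitute_uniform", "substitute_matrix", "omit"):
            raise ValueError(f"unknown confusion mode {self.mode!r}")
        if self.mode == "substitute_matrix":
            if self.matrix is None:
                raise ValueError("substitute_matrix requires a confusion matrix")
            for src, row in self.matrix.items():
                if src in row:
                    raise ValueError(f"confusion row {src!r} contains the identity")
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"confusion row {src!r} does not sum to 1")


@dataclass(frozen=True)
class ListenerProfile:
    """Virtual patient parameters; see the module docstring for the model."""

    audiogram: Audiogram
    axis: Literal["level_dB_HL", "snr_dB"]
    srt: float
    slope50: float
    floor: float = 0.0
    ceiling: float = 100.0
    confusion: ConfusionPolicy = field(default_factory=ConfusionPolicy)
    listener_id: str = "listener"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < self.ceiling <= 100.0:
            raise InvalidProfileError(
                f"need 0 <= floor < ceiling <= 100, got {self.floor}, {self.ceiling}"
            )
        if self.slope50 <= 0:
            raise InvalidProfileError("slope50 must be positive")
        if not self.floor < 50.0 < self.ceiling:
            raise InvalidProfileError(
                "50% must lie strictly between floor and ceiling for an SRT to exist"
            )
        if self.slope50 > (self.ceiling - self.floor) * K_MAX / 4.0:
            raise InvalidProfileError(
                f"slope50={self.slope50} not attainable with k <= {K_MAX}"
            )

    def logistic_parameters(self) -> tuple[float, float]:
        """Internal ``(k, x0)`` implied by (srt, slope50, floor, ceiling)."""
        span = self.ceiling - self.floor
        c = (50.0 - self.floor) / span
        k = self.slope50 / (span * c * (1.0 - c))
        x0 = self.srt + math.log((1.0 - c) / c) / k
        return k, x0

    def to_dict(self) -> dict:
        return {
            "listener_id": self.listener_id,
            "audiogram": self.audiogram.to_dict(),
            "axis": self.axis,
            "srt": self.srt,
            "slope50": self.slope50,
            "floor": self.floor,
            "ceiling": self.ceiling,
            "confusion": {"mode": self.confusion.mode, "matrix": self.confusion.matrix},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ListenerProfile":
        conf = d.get("confusion", {})
        return cls(
            audiogram=Audiogram.from_dict(d["audiogram"]),
            axis=d["axis"],
            srt=float(d["srt"]),
            slope50=float(d["slope50"]),
            floor=float(d.get("floor", 0.0)),
            ceiling=float(d.get("ceiling", 100.0)),
            confusion=ConfusionPolicy(
                conf.get("mode", "substitute_uniform"), conf.get("matrix")
            ),
            listener_id=d.get("listener_id", "listener"),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class Utterance:
    """What the listener said: phonemes plus per-target-phoneme correctness."""

    phonemes: tuple[str, ...]
    per_phoneme_correct: tuple[bool, ...]


def intelligibility_probability(profile: ListenerProfile, x: float) -> float:
    """Per-phoneme correctness probability at ``x`` on the profile's axis."""
    k, x0 = profile.logistic_parameters()
    if math.isinf(x):
        pct = profile.ceiling if x > 0 else profile.floor
    else:
        pct = profile.floor + (profile.ceiling - profile.floor) / (
            1.0 + math.exp(-k * (x - x0))
        )
    return pct / 100.0


def _confuse(
    phoneme: str,
    policy: ConfusionPolicy,
    rng: np.random.Generator,
    inventory,
) -> str | None:
    """The wrong phoneme actually uttered, or None if omitted."""
    if policy.mode == "omit":
        return None
    if policy.mode == "substitute_matrix":
        row = policy.matrix.get(phoneme)
        if row is None:
            raise ValueError(f"confusion matrix has no row for {phoneme!r}")
        symbols = list(row)
        probs = np.array([row[s] for s in symbols], dtype=float)
        return symbols[int(rng.choice(len(symbols), p=probs / probs.sum()))]
    if inventory is None:
        raise ValueError("substitute_uniform requires the phoneme inventory")
    others = [s for s in inventory.symbols if s != phoneme]
    if not others:
        return UNKNOWN
    return others[int(rng.integers(len(others)))]


def respond(
    profile: ListenerProfile,
    word,
    x: float,
    rng: np.random.Generator,
    inventory=None,
) -> Utterance:
    """Simulate the listener repeating ``word`` presented at ``x``.

    Each target phoneme is repeated correctly with probability
    ``intelligibility_probability(profile, x)`` independently; wrong
    phonemes are handled by the profile's confusion policy. Reproducible
    for a fixed generator state.
    """
    target = tuple(getattr(word, "phonemes", word))
    p = intelligibility_probability(profile, x)
    flags = tuple(bool(v) for v in rng.random(len(target)) < p)
    uttered: list[str] = []
    for phoneme, ok in zip(target, flags):
        if ok:
            uttered.append(phoneme)
        else:
            wrong = _confuse(phoneme, profile.confusion, rng, inventory)
            if wrong is not None:
                uttered.append(wrong)
    return Utterance(tuple(uttered), flags)


def flat_audiogram(pta: float, jitter: float = 0.0, rng=None) -> Audiogram:
    """A flat audiogram at ``pta`` dB HL, optionally jittered per frequency.

    Thresholds are redistributed so their mean stays exactly ``pta``.
    """
    values = np.full(len(PTA_FREQUENCIES), float(pta))
    if jitter > 0.0:
        if rng is None:
            raise ValueError("jitter requires a random generator")
        noise = rng.normal(0.0, jitter, len(values))
        values = values + noise - noise.mean()
    values = np.clip(values, -10.0, 120.0)
    return Audiogram(dict(zip(PTA_FREQUENCIES, (float(v) for v in values))))


def profile_from_audiogram(
    audiogram: Audiogram,
    axis: str,
    rng: np.random.Generator,
    slope50: float = 5.0,
    link: tuple[float, float, float] | None = None,
    floor: float = 0.0,
    ceiling: float = 100.0,
    confusion: ConfusionPolicy | None = None,
    listener_id: str = "listener",
    seed: int = 0,
) -> ListenerProfile:
    """Derive a listener profile from an audiogram via the PTA -> SRT link."""
    a, b, sigma = link if link is not None else SRT_LINK_DEFAULTS[axis]
    pta = float(np.mean([audiogram.thresholds[f] for f in PTA_FREQUENCIES]))
    srt = a * pta + b + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    return ListenerProfile(
        audiogram=audiogram,
        axis=axis,
        srt=float(srt),
        slope50=slope50,
        floor=floor,
        ceiling=ceiling,
        confusion=confusion or ConfusionPolicy(),
        listener_id=listener_id,
        seed=seed,
    )


def make_cohort(
    n: int,
    axis: str,
    seed: int = 0,
    pta_range: tuple[float, float] = (0.0, 80.0),
    slope50_range: tuple[float, float] = (3.0, 8.0),
    link: tuple[float, float, float] | None = None,
    audiogram_jitter: float = 5.0,
    ceiling_rolloff: float = 0.4,
    confusion: ConfusionPolicy | None = None,
) -> list[ListenerProfile]:
    """Sample ``n`` virtual listeners spanning a range of hearing losses.

    PTAs are uniform over ``pta_range``; the ceiling decreases by
    ``ceiling_rolloff`` % per dB of PTA beyond 40 dB HL (floored at 55%),
    emulating the reduced maximum intelligibility of stronger cochlear
    losses.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        pta = float(rng.uniform(*pta_range))
        audiogram = flat_audiogram(pta, jitter=audiogram_jitter, rng=rng)
        ceiling = max(55.0, 100.0 - ceiling_rolloff * max(0.0, pta - 40.0))
        slope = float(rng.uniform(*slope50_range))
        cohort.append(
            profile_from_audiogram(
                audiogram,
                axis,
                rng,
                slope50=slope,
                link=link,
                ceiling=ceiling,
                confusion=confusion,
                listener_id=f"L{i + 1:03d}",
                seed=int(rng.integers(2**31)),
            )
        )
    return cohort
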