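"""Automated adaptive speech-audiometry procedures.

Speech in quiet: one word list is presented per presentation level (PL, dB
HL). The first PL sits 20 dB above the pure-tone average (PTA) for PTA <
60 dB, 10 dB above for PTA 60-80 dB and 5 dB above beyond 80 dB, clamped
to the tested range 0-90 dB HL. The procedure descends in 10 dB steps
until a 0% point exists: if the cumulative phoneme score after the first 7
words of a list falls below 15%, the list stops early, its partial score is
kept, and the next-lower PL is imputed as 0% without testing. It then
ascends from the first PL in 10 dB steps (5 dB once the level exceeds 80
dB HL, to limit loudness discomfort) until 100% intelligibility is reached
or the newest score drops below the running maximum (a reversal of the
psychometric function's derivative, i.e. a speech maximum). Finally,
grid midpoints are added until at least 3 measured levels lie strictly
between the extremes (at most 5 added), filling in the psychometric
function.

Speech in noise: the speech level is fixed at 60 dB SPL (conversational
level) and the masking noise varies, so the x axis is the SNR in dB
(noise level = 60 - SNR). After one familiarization list in quiet,
normal-hearing listeners are tested at 0, -5, -10, -15, -20, +5, +10 dB
SNR in that order; hearing-impaired listeners skip -15 and -20. The same
7-word/15% early-stop rule applies, imputing the next 5-dB-worse SNR as 0%
and skipping any remaining worse conditions.

Every scorer transcribes the very same responses, so manual-vs-automated
comparisons are paired by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .listener import PTA_FREQUENCIES, Audiogram, ListenerProfile, respond
from .materials import SpeechList, SpeechMaterial
from .scoring import Transcription, phoneme_score
from .seeding import child_rng

__all__ = [
    "ProcedureConfig",
    "TrialRecord",
    "IntelligibilityPoint",
    "Session",
    "ProcedureError",
    "compute_pta",
    "classify_hearing",
    "initial_presentation_level",
    "snr_to_noise_level",
    "ascending_step",
    "run_list_at_level",
    "run_quiet_procedure",
    "run_noise_procedure",
]

HearingStatus = Literal["NH", "mild", "moderate", "severe"]


class ProcedureError(RuntimeError):
    """The adaptive procedure could not be completed."""


def compute_pta(audiogram: Audiogram) -> float:
    """Pure-tone average: mean threshold at 500/1000/2000/4000 Hz."""
    try:
        values = [audiogram.thresholds[f] for f in PTA_FREQUENCIES]
    except KeyError as exc:  # pragma: no cover - Audiogram validates too
        raise ValueError(f"audiogram misses PTA frequency {exc}") from exc
    return float(np.mean(values))


def classify_hearing(pta: float) -> HearingStatus:
    """Hearing status from the PTA: NH <=20 < mild <=40 < moderate <=70 < severe <=90."""
    if pta <= 20.0:
        return "NH"
    if pta <= 40.0:
        return "mild"
    if pta <= 70.0:
        return "moderate"
    if pta <= 90.0:
        return "severe"
    raise ValueError(f"PTA {pta} dB HL is beyond the classification table (> 90)")


def initial_presentation_level(
    pta: float, pl_min: float = 0.0, pl_max: float = 90.0
) -> float:
    """First presentation level: PTA + 20 / + 10 / + 5 by PTA band, clamped."""
    if pta < 0:
        raise ValueError("PTA must be non-negative")
    if pta < 60.0:
        pl = pta + 20.0
    elif pta <= 80.0:
        pl = pta + 10.0
    else:
        pl = pta + 5.0
    return float(min(max(pl, pl_min), pl_max))


def snr_to_noise_level(snr: float, stimulus_level: float = 60.0) -> float:
    """Masking-noise level (dB SPL) realizing ``snr`` at a fixed speech level."""
    return float(stimulus_level - snr)


def ascending_step(pl: float, cutoff: float = 80.0, high_step: float = 5.0,
                   low_step: float = 10.0) -> float:
    """Ascending step size from ``pl``: 5 dB above the 80 dB HL cutoff, else 10."""
    return high_step if pl > cutoff else low_step


@dataclass(frozen=True)
class ProcedureConfig:
    """Constants of the adaptive procedures (defaults as used clinically)."""

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
    nh_snr_order: tuple[float, ...] = (0.0, -5.0, -10.0, -15.0, -20.0, 5.0, 10.0)
    hi_snr_order: tuple[float, ...] = (0.0, -5.0, -10.0, 5.0, 10.0)
    snr_impute_step: float = 5.0
    reuse_lists: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nh_snr_order"] = list(self.nh_snr_order)
        d["hi_snr_order"] = list(self.hi_snr_order)
        return d


@dataclass(frozen=True)
class TrialRecord:
    """One presented word with every scorer's transcription of the response."""

    list_id: str
    word_index: int  # 1-based within the list
    x: float | None  # PL (dB HL) or SNR (dB); None for familiarization
    phase: str
    target: tuple[str, ...]
    uttered: tuple[str, ...]
    transcriptions: Mapping[str, Transcription]
    per_scorer_correct: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "list_id": self.list_id,
            "word_index": self.word_index,
            "x": self.x,
            "phase": self.phase,
            "target": list(self.target),
            "uttered": list(self.uttered),
            "transcriptions": {
                k: list(v.tokens) for k, v in self.transcriptions.items()
            },
            "per_scorer_correct": dict(self.per_scorer_correct),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialRecord":
        return cls(
            list_id=d["list_id"],
            word_index=int(d["word_index"]),
            x=None if d["x"] is None else float(d["x"]),
            phase=d["phase"],
            target=tuple(d["target"]),
            uttered=tuple(d["uttered"]),
            transcriptions={
                k: Transcription(tuple(v)) for k, v in d["transcriptions"].items()
            },
            per_scorer_correct={k: int(v) for k, v in d["per_scorer_correct"].items()},
        )


Provenance = Literal["measured", "imputed_zero", "early_stopped"]


@dataclass(frozen=True)
class IntelligibilityPoint:
    """One point of the measured psychometric function."""

    x: float
    pct: float
    n_phonemes: int
    provenance: Provenance

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "pct": self.pct,
            "n_phonemes": self.n_phonemes,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntelligibilityPoint":
        return cls(float(d["x"]), float(d["pct"]), int(d["n_phonemes"]), d["provenance"])


@dataclass
class Session:
    """Full record of one automated speech-audiometry test."""

    mode: Literal["quiet", "noise"]
    listener_id: str
    scorer_names: tuple[str, ...]
    trials: list[TrialRecord]
    points: dict[str, list[IntelligibilityPoint]]
    config: dict
    seed: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "listener_id": self.listener_id,
            "scorer_names": list(self.scorer_names),
            "trials": [t.to_dict() for t in self.trials],
            "points": {
                k: [p.to_dict() for p in v] for k, v in self.points.items()
            },
            "config": self.config,
            "seed": self.seed,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Session":
        return cls(
            mode=d["mode"],
            listener_id=d["listener_id"],
            scorer_names=tuple(d["scorer_names"]),
            trials=[TrialRecord.from_dict(t) for t in d["trials"]],
            points={
                k: [IntelligibilityPoint.from_dict(p) for p in v]
                for k, v in d["points"].items()
            },
            config=dict(d["config"]),
            seed=int(d["seed"]),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "Session":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class _ListDispenser:
    """Hands out lists without replacement, rotating once exhausted."""

    def __init__(self, lists: Sequence[SpeechList], rng: np.random.Generator,
                 reuse: bool) -> None:
        order = list(rng.permutation(len(lists)))
        self._cycle = [lists[i] for i in order]
        self._pos = 0
        self._reuse = reuse

    def next(self) -> SpeechList:
        if self._pos >= len(self._cycle):
            if not self._reuse:
                raise ProcedureError("speech lists exhausted and reuse is disabled")
            self._pos = 0
        sl = self._cycle[self._pos]
        self._pos += 1
        return sl


def run_list_at_level(
    speech_list: SpeechList,
    x: float,
    profile: ListenerProfile,
    scorers: Mapping[str, object],
    config: ProcedureConfig,
    listener_rng: np.random.Generator,
    scorer_rngs: Mapping[str, np.random.Generator],
    inventory,
    phase: str = "measure",
    record_x: float | None = "__same__",  # type: ignore[assignment]
) -> tuple[list[TrialRecord], dict[str, IntelligibilityPoint]]:
    """Present one list at level/SNR ``x``, scoring each response with every scorer.

    Applies the early-stop rule: if the reference scorer's cumulative
    phoneme score after the first ``early_stop_after_words`` words is below
    ``early_stop_threshold_pct`` %, the list stops there and the point is
    flagged ``early_stopped``.
    """
    if len(speech_list.words) == 0:
        raise ValueError("speech list is empty")
    ref = config.reference_scorer
    if ref not in scorers:
        raise ValueError(f"reference scorer {ref!r} not among scorers")
    x_rec = x if record_x == "__same__" else record_x
    trials: list[TrialRecord] = []
    n_correct = {name: 0 for name in scorers}
    n_total = 0
    stopped = False
    for wi, word in enumerate(speech_list.words, start=1):
        utterance = respond(profile, word, x, listener_rng, inventory)
        transcriptions: dict[str, Transcription] = {}
        per_correct: dict[str, int] = {}
        for name, scorer in scorers.items():
            tr = scorer.transcribe(utterance, scorer_rngs[name])
            m, _, _ = phoneme_score(word.phonemes, tr)
            transcriptions[name] = tr
            per_correct[name] = m
            n_correct[name] += m
        n_total += len(word.phonemes)
        trials.append(
            TrialRecord(
                list_id=speech_list.list_id,
                word_index=wi,
                x=x_rec,
                phase=phase,
                target=word.phonemes,
                uttered=utterance.phonemes,
                transcriptions=transcriptions,
                per_scorer_correct=per_correct,
            )
        )
        if wi == config.early_stop_after_words and wi < len(speech_list.words):
            ref_pct = 100.0 * n_correct[ref] / n_total
            if ref_pct < config.early_stop_threshold_pct:
                stopped = True
                break
    provenance: Provenance = "early_stopped" if stopped else "measured"
    points = {
        name: IntelligibilityPoint(
            x=x_rec if x_rec is not None else float("nan"),
            pct=100.0 * n_correct[name] / n_total,
            n_phonemes=n_total,
            provenance=provenance,
        )
        for name in scorers
    }
    return trials, points


def _session_rngs(seed: int, scorers: Mapping[str, object]):
    listener_rng = child_rng(seed, "listener")
    lists_rng = child_rng(seed, "lists")
    scorer_rngs = {name: child_rng(seed, f"scorer:{name}") for name in scorers}
    return listener_rng, lists_rng, scorer_rngs


def _snap_to_grid(value: float, grid: float = 5.0) -> float:
    return round(value / grid) * grid


def run_quiet_procedure(
    material: SpeechMaterial,
    profile: ListenerProfile,
    scorers: Mapping[str, object],
    config: ProcedureConfig | None = None,
    seed: int = 0,
) -> Session:
    """Run the adaptive speech-in-quiet test for one listener (one ear)."""
    if material.kind != "quiet":
        raise ValueError("quiet procedure requires a quiet-kind material")
    if profile.axis != "level_dB_HL":
        raise ValueError("quiet procedure requires a level_dB_HL listener axis")
    config = config or ProcedureConfig()
    listener_rng, lists_rng, scorer_rngs = _session_rngs(seed, scorers)
    dispenser = _ListDispenser(material.lists, lists_rng, config.reuse_lists)
    inventory = material.inventory
    pta = compute_pta(profile.audiogram)
    ref = config.reference_scorer

    trials: list[TrialRecord] = []
    points: dict[str, list[IntelligibilityPoint]] = {name: [] for name in scorers}
    tested_x: set[float] = set()

    def test_at(pl: float, phase: str) -> dict[str, IntelligibilityPoint]:
        trs, pts = run_list_at_level(
            dispenser.next(), pl, profile, scorers, config,
            listener_rng, scorer_rngs, inventory, phase=phase,
        )
        trials.extend(trs)
        for name, pt in pts.items():
            points[name].append(pt)
        tested_x.add(pl)
        return pts

    # hook: contralateral masking would be computed here when the
    # non-test ear could participate; deliberately not modelled.

    # --- descent: from the initial PL down until a 0% point exists
    pl0 = initial_presentation_level(pta, config.pl_min, config.pl_max)
    pl = pl0
    while True:
        pts = test_at(pl, "descent")
        ref_pt = pts[ref]
        lower = pl - config.descend_step
        if ref_pt.provenance == "early_stopped":
            if lower >= config.pl_min:
                for name in scorers:
                    points[name].append(
                        IntelligibilityPoint(lower, 0.0, 0, "imputed_zero")
                    )
                tested_x.add(lower)
            break
        if ref_pt.pct == 0.0 or lower < config.pl_min:
            break
        pl = lower

    # --- ascent: from the first PL up until 100% or derivative reversal
    first_pct = points[ref][0].pct
    running_max = first_pct
    if first_pct < 100.0:
        pl = pl0
        while True:
            nxt = pl + ascending_step(
                pl, config.high_level_cutoff, config.high_level_step, config.ascend_step
            )
            nxt = min(nxt, config.pl_max)
            if nxt <= pl or nxt in tested_x:
                break
            pts = test_at(nxt, "ascent")
            score = pts[ref].pct
            pl = nxt
            if score >= 100.0:
                break
            if score < running_max - config.reversal_tolerance:
                break  # derivative reversal: past the speech maximum
            running_max = max(running_max, score)

    # --- fill: ensure enough measured points strictly inside the range
    added = 0
    while added < config.max_added_points:
        xs_all = sorted(x for x in tested_x)
        lo, hi = xs_all[0], xs_all[-1]
        measured_x = {
            p.x for p in points[ref] if p.provenance != "imputed_zero"
        }
        interior = [x for x in measured_x if lo < x < hi]
        if len(interior) >= config.min_interior_points:
            break
        gaps = sorted(
            zip(xs_all[:-1], xs_all[1:]),
            key=lambda ab: ab[1] - ab[0],
            reverse=True,
        )
        candidate = None
        for a, b in gaps:
            mid = _snap_to_grid((a + b) / 2.0)
            if a < mid < b and mid not in tested_x:
                candidate = mid
                break
        if candidate is None:
            break
        test_at(candidate, "fill")
        added += 1

    for name in points:
        points[name].sort(key=lambda p: p.x)
    return Session(
        mode="quiet",
        listener_id=profile.listener_id,
        scorer_names=tuple(scorers),
        trials=trials,
        points=points,
        config=config.to_dict(),
        seed=seed,
        metadata={
            "pta": pta,
            "hearing_status": classify_hearing(pta) if pta <= 90 else None,
            "listener": profile.to_dict(),
        },
    )


def run_noise_procedure(
    material: SpeechMaterial,
    profile: ListenerProfile,
    scorers: Mapping[str, object],
    config: ProcedureConfig | None = None,
    seed: int = 0,
) -> Session:
    """Run the adaptive speech-in-noise test for one listener (binaural)."""
    if material.kind != "noise":
        raise ValueError("noise procedure requires a noise-kind material")
    if profile.axis != "snr_dB":
        raise ValueError("noise procedure requires an snr_dB listener axis")
    config = config or ProcedureConfig()
    listener_rng, lists_rng, scorer_rngs = _session_rngs(seed, scorers)
    dispenser = _ListDispenser(material.lists, lists_rng, config.reuse_lists)
    inventory = material.inventory
    pta = compute_pta(profile.audiogram)
    status = classify_hearing(pta) if pta <= 90 else "severe"
    order = config.nh_snr_order if status == "NH" else config.hi_snr_order
    ref = config.reference_scorer

    trials: list[TrialRecord] = []
    points: dict[str, list[IntelligibilityPoint]] = {name: [] for name in scorers}

    # familiarization: one list at the fixed speech level, no masking noise;
    # scored and recorded but excluded from the psychometric points
    fam_trials, _ = run_list_at_level(
        dispenser.next(), float("inf"), profile, scorers, config,
        listener_rng, scorer_rngs, inventory,
        phase="familiarization", record_x=None,
    )
    trials.extend(fam_trials)

    imputed: set[float] = set()
    skipped: set[float] = set()
    present_xs: set[float] = set()
    for snr in order:
        if snr in skipped or snr in imputed or snr in present_xs:
            continue
        trs, pts = run_list_at_level(
            dispenser.next(), snr, profile, scorers, config,
            listener_rng, scorer_rngs, inventory, phase="measure",
        )
        trials.extend(trs)
        present_xs.add(snr)
        for name, pt in pts.items():
            points[name].append(pt)
        if pts[ref].provenance == "early_stopped":
            worse = snr - config.snr_impute_step
            if worse not in present_xs:
                for name in scorers:
                    points[name].append(
                        IntelligibilityPoint(worse, 0.0, 0, "imputed_zero")
                    )
                imputed.add(worse)
                present_xs.add(worse)
            skipped.update(c for c in order if c < worse)

    for name in points:
        points[name].sort(key=lambda p: p.x)
    return Session(
        mode="noise",
        listener_id=profile.listener_id,
        scorer_names=tuple(scorers),
        trials=trials,
        points=points,
        config=config.to_dict(),
        seed=seed,
        metadata={
            "pta": pta,
            "hearing_status": status,
            "stimulus_level_spl": config.stimulus_level_spl,
            "noise_levels_spl": {
                str(snr): snr_to_noise_level(snr, config.stimulus_level_spl)
                for snr in order
            },
            "listener": profile.to_dict(),
        },
    )
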