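"""Comparison, convergence and test-retest analyses over sessions.

Automated-vs-manual agreement is quantified by the *raw* difference
(automated score minus manual score, signed) and the *absolute* difference
(its absolute value). Raw differences cancel across a cohort when the
automated scorer over- and under-estimates symmetrically; absolute
differences do not, so both are always reported as mean +/- sd.

The word-by-word convergence analysis asks how many of a list's 17 words
are really needed at each level: for every fully presented list the
cumulative phoneme score after word k (S_k) is compared to the final score
after the last word, and |S_k - S_17| is averaged per subject or per list.

Test-retest reliability compares two administrations of the same test on
the same listener: for each pair the chosen metric (overall percent score,
SRT, or maximum intelligibility) is differenced (retest minus test) and
aggregated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .procedures import Session
from .psychometrics import max_intelligibility, srt50

__all__ = [
    "ScoreComparison",
    "ConvergenceProfile",
    "RetestSummary",
    "compare_scores",
    "convergence_profile",
    "test_retest",
    "cohort_report",
    "list_scores",
    "session_metric",
]

Grouping = Literal["per_subject", "per_list"]
Metric = Literal["all_words_pct", "srt50", "max_intelligibility"]


@dataclass(frozen=True)
class ScoreComparison:
    raw_diff: float
    abs_diff: float
    unit: str


def compare_scores(automated: float, manual: float, unit: str = "%",
                   manual_unit: str | None = None) -> ScoreComparison:
    """Raw (automated - manual) and absolute difference of two scores."""
    if manual_unit is not None and manual_unit != unit:
        raise ValueError(f"unit mismatch: {unit!r} vs {manual_unit!r}")
    raw = float(automated) - float(manual)
    return ScoreComparison(raw_diff=raw, abs_diff=abs(raw), unit=unit)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def list_scores(session: Session) -> pd.DataFrame:
    """Per list-occurrence percent scores of every scorer, from the trials.

    One row per (list occurrence, scorer); familiarization trials are
    excluded. ``complete`` flags occurrences where the whole list was
    presented.
    """
    rows = []
    occ: dict[tuple[str, float], list] = {}
    for t in session.trials:
        if t.x is None:
            continue
        occ.setdefault((t.list_id, t.x), []).append(t)
    for (list_id, x), trials in occ.items():
        n_words = len(trials)
        n_phonemes = sum(len(t.target) for t in trials)
        for name in session.scorer_names:
            n_correct = sum(t.per_scorer_correct[name] for t in trials)
            rows.append(
                {
                    "listener_id": session.listener_id,
                    "mode": session.mode,
                    "list_id": list_id,
                    "x": x,
                    "scorer": name,
                    "n_words": n_words,
                    "n_phonemes": n_phonemes,
                    "pct": 100.0 * n_correct / n_phonemes,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        esw = session.config.get("early_stop_after_words")
        if esw is not None:
            df["complete"] = df["n_words"] > esw
        else:
            df["complete"] = df["n_words"] == df["n_words"].max()
    return df


@dataclass(frozen=True)
class ConvergenceProfile:
    """Mean +/- sd of |S_k - S_final| per word index k, for one grouping."""

    per_word_abs_diff: Mapping[int, float]
    per_word_sd: Mapping[int, float]
    grouping: Grouping
    n_groups: int

    def to_frame(self) -> pd.DataFrame:
        words = sorted(self.per_word_abs_diff)
        return pd.DataFrame(
            {
                "word": words,
                "abs_diff_mean": [self.per_word_abs_diff[w] for w in words],
                "abs_diff_sd": [self.per_word_sd[w] for w in words],
            }
        )


def _occurrence_curves(
    session: Session, scorer: str
) -> list[tuple[str, np.ndarray]]:
    """|S_k - S_final| arrays for every fully presented list occurrence."""
    occ: dict[tuple[str, float], list] = {}
    for t in session.trials:
        if t.x is None:
            continue
        occ.setdefault((t.list_id, t.x), []).append(t)
    if not occ:
        return []
    full_len = max(len(ts) for ts in occ.values())
    esw = session.config.get("early_stop_after_words")
    out = []
    for (list_id, _), trials in occ.items():
        # early-stopped lists have no final-word score to converge to
        complete = len(trials) > esw if esw is not None else len(trials) == full_len
        if not complete or len(trials) < full_len:
            continue
        trials = sorted(trials, key=lambda t: t.word_index)
        correct = np.array([t.per_scorer_correct[scorer] for t in trials], float)
        totals = np.array([len(t.target) for t in trials], float)
        s_k = 100.0 * np.cumsum(correct) / np.cumsum(totals)
        out.append((list_id, np.abs(s_k - s_k[-1])))
    return out


def convergence_profile(
    sessions: Sequence[Session],
    grouping: Grouping = "per_subject",
    scorer: str = "oracle",
) -> ConvergenceProfile:
    """Word-by-word convergence of cumulative scores to the final list score."""
    groups: dict[str, list[np.ndarray]] = {}
    for session in sessions:
        for list_id, curve in _occurrence_curves(session, scorer):
            key = session.listener_id if grouping == "per_subject" else list_id
            groups.setdefault(key, []).append(curve)
    if not groups:
        raise ValueError("no fully presented lists in the given sessions")
    lengths = {len(c) for curves in groups.values() for c in curves}
    if len(lengths) != 1:
        raise ValueError("sessions mix different list lengths")
    (n_words,) = lengths
    per_group = np.vstack(
        [np.mean(np.vstack(curves), axis=0) for curves in groups.values()]
    )
    mean = per_group.mean(axis=0)
    sd = per_group.std(axis=0, ddof=1) if per_group.shape[0] > 1 else np.zeros(n_words)
    return ConvergenceProfile(
        per_word_abs_diff={k + 1: float(mean[k]) for k in range(n_words)},
        per_word_sd={k + 1: float(sd[k]) for k in range(n_words)},
        grouping=grouping,
        n_groups=len(groups),
    )


def session_metric(
    session: Session,
    metric: Metric,
    scorer: str,
    method: str = "interpolation",
) -> float | None:
    """Extract one scalar metric of a session for one scorer (None if undefined)."""
    if metric == "all_words_pct":
        n_correct = n_total = 0
        for t in session.trials:
            if t.x is None:
                continue
            n_correct += t.per_scorer_correct[scorer]
            n_total += len(t.target)
        if n_total == 0:
            return None
        return 100.0 * n_correct / n_total
    points = session.points[scorer]
    if metric == "srt50":
        return srt50(points, method) if len(points) >= 2 else None
    if metric == "max_intelligibility":
        return max_intelligibility(points) if points else None
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class RetestSummary:
    metric: Metric
    n_pairs: int
    n_dropped: int
    raw_mean: float
    raw_sd: float
    abs_mean: float
    abs_sd: float


def test_retest(
    session_pairs: Sequence[tuple[Session, Session]],
    metric: Metric = "all_words_pct",
    scorer: str = "oracle",
    method: str = "interpolation",
) -> RetestSummary:
    """Aggregate retest-minus-test differences of ``metric`` over pairs.

    Pairs where the metric is undefined in either session are dropped and
    counted in ``n_dropped``.
    """
    raws, dropped = [], 0
    for test, retest in session_pairs:
        if test.listener_id != retest.listener_id or test.mode != retest.mode:
            raise ValueError("test-retest pairs must share listener and mode")
        a = session_metric(test, metric, scorer, method)
        b = session_metric(retest, metric, scorer, method)
        if a is None or b is None:
            dropped += 1
            continue
        raws.append(compare_scores(b, a).raw_diff)  # orientation: retest - test
    raw_mean, raw_sd = _mean_sd(raws)
    abs_mean, abs_sd = _mean_sd([abs(r) for r in raws])
    return RetestSummary(
        metric=metric,
        n_pairs=len(raws),
        n_dropped=dropped,
        raw_mean=raw_mean,
        raw_sd=raw_sd,
        abs_mean=abs_mean,
        abs_sd=abs_sd,
    )


def _diff_table(rows: Mapping[str, tuple[list[float], int]]) -> pd.DataFrame:
    out = []
    for group, (raws, n) in rows.items():
        raw_mean, raw_sd = _mean_sd(raws)
        abs_mean, abs_sd = _mean_sd([abs(r) for r in raws])
        out.append(
            {
                "group": group,
                "n": n,
                "raw_mean": raw_mean,
                "raw_sd": raw_sd,
                "abs_mean": abs_mean,
                "abs_sd": abs_sd,
            }
        )
    return pd.DataFrame(out)


def cohort_report(
    sessions: Sequence[Session],
    scorers: tuple[str, str] = ("oracle", "asr"),
    method: str = "interpolation",
) -> dict[str, pd.DataFrame]:
    """Descriptive automated-vs-manual difference tables over a cohort.

    ``scorers`` is (manual-equivalent, automated). Returns per-list and
    per-hearing-status tables of list-level percent-score differences, and
    a psychometric table of per-session SRT and maximum-intelligibility
    differences. Columns: group, n, raw_mean, raw_sd, abs_mean, abs_sd.
    """
    manual, automated = scorers
    per_list: dict[str, list[float]] = {}
    per_status: dict[str, list[float]] = {}
    all_raws: list[float] = []
    for session in sessions:
        if manual not in session.scorer_names or automated not in session.scorer_names:
            raise ValueError("every session must be scored by both scorers")
        df = list_scores(session)
        if df.empty:
            continue
        wide = df.pivot_table(
            index=["list_id", "x"], columns="scorer", values="pct"
        )
        status = session.metadata.get("hearing_status") or "unknown"
        for (list_id, _), row in wide.iterrows():
            raw = compare_scores(row[automated], row[manual]).raw_diff
            per_list.setdefault(list_id, []).append(raw)
            per_status.setdefault(status, []).append(raw)
            all_raws.append(raw)

    per_list_rows = {
        k: (v, len(v)) for k, v in sorted(per_list.items())
    }
    per_list_rows["all"] = (all_raws, len(all_raws))
    per_status_rows = {k: (v, len(v)) for k, v in sorted(per_status.items())}

    psy: dict[str, list[float]] = {"srt50": [], "max_intelligibility": []}
    for session in sessions:
        for metric in psy:
            a = session_metric(session, metric, automated, method)
            m = session_metric(session, metric, manual, method)
            if a is None or m is None:
                continue
            psy[metric].append(compare_scores(a, m).raw_diff)
    psy_rows = {k: (v, len(v)) for k, v in psy.items()}

    return {
        "per_list": _diff_table(per_list_rows),
        "per_status": _diff_table(per_status_rows),
        "psychometrics": _diff_table(psy_rows),
    }
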