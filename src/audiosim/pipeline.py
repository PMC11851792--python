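"""End-to-end reproducible runs: generate -> simulate -> analyze.

``run_pipeline`` takes a validated :class:`~audiosim.config.RunConfig` and
an output directory and writes:

* ``material.json`` - the generated speech material
* ``listeners.json`` - the sampled virtual-listener cohort
* ``sessions/*.json`` - one session per listener (two with ``retest``)
* ``tables/*.csv`` - per-list, per-status, psychometric and convergence
  tables (plus ``retest.csv`` when retest is enabled)
* ``run.log`` - seeds, versions and output counts

Identical configuration and seed produce byte-identical session files; the
master seed is split into named child seeds (material, cohort, one per
session) so every downstream draw is pinned.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import cohort_report, convergence_profile, test_retest
from .config import RunConfig
from .listener import ConfusionPolicy, make_cohort
from .materials import generate_material, make_default_inventory
from .procedures import Session, run_noise_procedure, run_quiet_procedure
from .scoring import ASRScorer, OracleScorer
from .seeding import child_seed

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_CSV_KW = dict(index=False, float_format="%.6g")  # fixed dialect: utf-8, '.', comma


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, encoding="utf-8", **_CSV_KW)


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> Path:
    """Run one full simulation + analysis; returns the artifact directory."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(parents=True, exist_ok=True)

    mode = config.mode
    axis = "level_dB_HL" if mode == "quiet" else "snr_dB"
    seed = config.seed

    material = generate_material(
        kind=mode,
        n_lists=config.material.resolved_n_lists(mode),
        words_per_list=config.material.words_per_list,
        phonemes_per_word=config.material.phonemes_per_word,
        inventory=make_default_inventory(
            config.material.n_vowels, config.material.n_consonants
        ),
        seed=child_seed(seed, "material"),
    )
    material.save(out / "material.json")

    cohort = make_cohort(
        n=config.cohort.n,
        axis=axis,
        seed=child_seed(seed, "cohort"),
        pta_range=(config.cohort.pta_min, config.cohort.resolved_pta_max(mode)),
        slope50_range=(config.cohort.slope50_min, config.cohort.slope50_max),
        link=config.cohort.resolved_link(axis),
        audiogram_jitter=config.cohort.audiogram_jitter,
        ceiling_rolloff=config.cohort.ceiling_rolloff,
        confusion=ConfusionPolicy(config.cohort.confusion_mode),
    )
    with open(out / "listeners.json", "w", encoding="utf-8") as fh:
        json.dump(
            [p.to_dict() for p in cohort], fh,
            ensure_ascii=False, indent=2, sort_keys=True,
        )
        fh.write("\n")

    scorers = {
        "oracle": OracleScorer(),
        "asr": ASRScorer(config.scorer.resolved(mode), material.inventory),
    }
    proc_config = config.procedure.resolved()
    run_proc = run_quiet_procedure if mode == "quiet" else run_noise_procedure

    sessions: list[Session] = []
    pairs: list[tuple[Session, Session]] = []
    for profile in cohort:
        tags = ("test", "retest") if config.retest else ("test",)
        per_listener = []
        for tag in tags:
            session = run_proc(
                material, profile, scorers, proc_config,
                seed=child_seed(seed, f"session:{profile.listener_id}:{tag}"),
            )
            session.save(out / "sessions" / f"{profile.listener_id}_{tag}.json")
            per_listener.append(session)
        sessions.append(per_listener[0])
        if config.retest:
            pairs.append((per_listener[0], per_listener[1]))

    method = config.analysis.method
    if sessions:
        report = cohort_report(sessions, scorers=("oracle", "asr"), method=method)
        try:
            conv = convergence_profile(
                sessions, grouping=config.analysis.convergence_grouping
            ).to_frame()
        except ValueError:
            conv = pd.DataFrame(columns=["word", "abs_diff_mean", "abs_diff_sd"])
    else:
        logger.warning("empty cohort: writing empty tables")
        cols = ["group", "n", "raw_mean", "raw_sd", "abs_mean", "abs_sd"]
        report = {k: pd.DataFrame(columns=cols)
                  for k in ("per_list", "per_status", "psychometrics")}
        conv = pd.DataFrame(columns=["word", "abs_diff_mean", "abs_diff_sd"])

    _write_csv(report["per_list"], out / "tables" / "per_list.csv")
    _write_csv(report["per_status"], out / "tables" / "per_status.csv")
    _write_csv(report["psychometrics"], out / "tables" / "psychometrics.csv")
    _write_csv(conv, out / "tables" / "convergence.csv")

    if config.retest:
        rows = []
        for metric in ("all_words_pct", "srt50", "max_intelligibility"):
            for scorer in ("oracle", "asr"):
                s = test_retest(pairs, metric=metric, scorer=scorer, method=method)
                rows.append(
                    {
                        "scorer": scorer,
                        "metric": metric,
                        "n": s.n_pairs,
                        "n_dropped": s.n_dropped,
                        "raw_mean": s.raw_mean,
                        "raw_sd": s.raw_sd,
                        "abs_mean": s.abs_mean,
                        "abs_sd": s.abs_sd,
                    }
                )
        _write_csv(pd.DataFrame(rows), out / "tables" / "retest.csv")

    log_lines = [
        f"audiosim {__version__}",
        f"numpy {np.__version__}",
        f"mode {mode}",
        f"seed {seed}",
        f"n_listeners {len(cohort)}",
        f"n_sessions {len(cohort) * (2 if config.retest else 1)}",
        f"config {config.model_dump_json()}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
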