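"""Adaptive procedures: PTA, hearing status, quiet and noise test logic."""

import numpy as np
import pytest

import audiosim as a
from audiosim.listener import flat_audiogram
from audiosim.procedures import (
    ProcedureConfig,
    ProcedureError,
    Session,
    ascending_step,
)
from audiosim.seeding import child_rng
from tests.conftest import make_profile


class TestPTAAndClassification:
    def test_pta_is_the_four_frequency_mean(self):
        ag = a.Audiogram({500.0: 20, 1000.0: 30, 2000.0: 40, 4000.0: 50})
        assert a.compute_pta(ag) == 35.0
        assert a.compute_pta(flat_audiogram(10.0)) == 10.0
        assert a.compute_pta(flat_audiogram(0.0)) == 0.0

    @pytest.mark.parametrize(
        "pta,status",
        [
            (0, "NH"), (20, "NH"), (21, "mild"), (40, "mild"),
            (41, "moderate"), (70, "moderate"), (71, "severe"), (90, "severe"),
        ],
    )
    def test_classification_bands(self, pta, status):
        assert a.classify_hearing(pta) == status

    def test_classification_beyond_table_raises(self):
        with pytest.raises(ValueError):
            a.classify_hearing(95.0)


class TestLevelRules:
    @pytest.mark.parametrize(
        "pta,pl",
        [
            (0, 20), (40, 60), (59, 79),   # +20 below 60
            (60, 70), (70, 80), (80, 90),  # +10 for 60-80
            (85, 90), (82, 87),            # +5 above 80, clamped to 90
        ],
    )
    def test_initial_presentation_level(self, pta, pl):
        assert a.initial_presentation_level(pta) == pl

    @pytest.mark.parametrize("snr,noise", [(10, 50), (5, 55), (0, 60), (-5, 65),
                                           (-10, 70), (-15, 75), (-20, 80)])
    def test_snr_to_noise_level_at_fixed_speech_level(self, snr, noise):
        assert a.snr_to_noise_level(snr, 60.0) == noise

    def test_ascending_step_reduces_above_80(self):
        assert ascending_step(70.0) == 10.0
        assert ascending_step(80.0) == 10.0
        assert ascending_step(85.0) == 5.0


def _run_list(speech_list, x, profile, scorers, inventory, config=None, seed=0):
    config = config or ProcedureConfig()
    scorer_rngs = {name: child_rng(seed, f"s:{name}") for name in scorers}
    return a.run_list_at_level(
        speech_list, x, profile, scorers, config,
        child_rng(seed, "listener"), scorer_rngs, inventory,
    )


class TestRunList:
    def test_deaf_listener_stops_after_seven_words(
        self, quiet_material, deaf_listener, oracle_only
    ):
        trials, pts = _run_list(
            quiet_material.lists[0], 30.0, deaf_listener, oracle_only,
            quiet_material.inventory,
        )
        assert len(trials) == 7
        assert pts["oracle"].provenance == "early_stopped"
        assert pts["oracle"].n_phonemes == 21

    def test_perfect_listener_hears_all_seventeen_words(
        self, quiet_material, perfect_listener, oracle_only
    ):
        trials, pts = _run_list(
            quiet_material.lists[0], 60.0, perfect_listener, oracle_only,
            quiet_material.inventory,
        )
        assert len(trials) == 17
        assert pts["oracle"].pct == 100.0
        assert pts["oracle"].n_phonemes == 51  # 17 words x 3 phonemes

    def test_early_stop_threshold_is_strict(
        self, quiet_material, oracle_only, inventory
    ):
        # 15% of 21 phonemes = 3.15: a score of exactly 3/21 (14.3%) stops,
        # 4/21 (19%) does not. Checked indirectly via threshold override.
        config = ProcedureConfig(early_stop_threshold_pct=0.0)
        trials, pts = _run_list(
            quiet_material.lists[0], 0.0, make_profile(srt=300.0), oracle_only,
            inventory, config=config,
        )
        assert len(trials) == 17  # nothing is below a 0% threshold


class TestQuietProcedure:
    def test_deaf_listener_gets_imputed_zero_below_first_level(
        self, quiet_material, deaf_listener, oracle_only
    ):
        s = a.run_quiet_procedure(
            quiet_material, deaf_listener, oracle_only, seed=1
        )
        pts = {p.x: p for p in s.points["oracle"]}
        first_pl = a.initial_presentation_level(80.0)  # PTA 80 -> 90
        assert pts[first_pl].provenance == "early_stopped"
        assert pts[first_pl - 10.0].provenance == "imputed_zero"
        assert pts[first_pl - 10.0].pct == 0.0
        assert pts[first_pl - 10.0].n_phonemes == 0

    def test_perfect_listener_scores_100_first_and_never_ascends(
        self, quiet_material, perfect_listener, oracle_only
    ):
        s = a.run_quiet_procedure(
            quiet_material, perfect_listener, oracle_only, seed=1
        )
        first_pl = a.initial_presentation_level(0.0)
        assert not any(t.phase == "ascent" for t in s.trials)
        pts = {p.x: p for p in s.points["oracle"]}
        assert pts[first_pl].pct == 100.0

    def test_logistic_listener_brackets_srt_with_interior_points(
        self, quiet_material, oracle_only
    ):
        profile = make_profile(pta=40.0, srt=50.0, slope50=5.0, listener_id="mid")
        s = a.run_quiet_procedure(quiet_material, profile, oracle_only, seed=5)
        pts = s.points["oracle"]
        xs = [p.x for p in pts]
        assert all(x == round(x) and x % 5 == 0 for x in xs)
        assert len(xs) == len(set(xs))
        below = [p for p in pts if p.pct < 50.0]
        above = [p for p in pts if p.pct >= 50.0]
        assert below and above
        measured = [p.x for p in pts if p.provenance != "imputed_zero"]
        interior = [x for x in measured if min(xs) < x < max(xs)]
        assert len(interior) >= 3

    def test_levels_stay_within_0_90(self, quiet_material, both_scorers):
        for seed, pta in [(1, 0.0), (2, 55.0), (3, 80.0), (4, 88.0)]:
            profile = make_profile(pta=pta, srt=pta + 5.0, listener_id=f"p{pta}")
            s = a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=seed)
            for t in s.trials:
                assert 0.0 <= t.x <= 90.0

    def test_both_scorers_share_the_same_trials(self, quiet_material, both_scorers):
        profile = make_profile(srt=50.0)
        s = a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=2)
        assert set(s.scorer_names) == {"oracle", "asr"}
        for t in s.trials:
            assert set(t.transcriptions) == {"oracle", "asr"}
        assert [p.x for p in s.points["oracle"]] == [p.x for p in s.points["asr"]]
        ns = {
            name: [p.n_phonemes for p in pts] for name, pts in s.points.items()
        }
        assert ns["oracle"] == ns["asr"]

    def test_session_reproducible_bit_for_bit(
        self, quiet_material, both_scorers, tmp_path
    ):
        profile = make_profile(srt=45.0)
        s1 = a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=9)
        s2 = a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=9)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        s1.save(p1)
        s2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_list_exhaustion_without_reuse_fails(self, inventory, oracle_only):
        small = a.generate_material("quiet", 1, 17, 3, inventory, seed=1)
        profile = make_profile(pta=40.0, srt=50.0)
        config = ProcedureConfig(reuse_lists=False)
        with pytest.raises(ProcedureError):
            a.run_quiet_procedure(small, profile, oracle_only, config, seed=1)

    def test_session_json_round_trip(self, quiet_material, both_scorers, tmp_path):
        profile = make_profile(srt=50.0)
        s = a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=3)
        path = tmp_path / "s.json"
        s.save(path)
        loaded = Session.load(path)
        assert loaded.to_dict() == s.to_dict()


class TestNoiseProcedure:
    def test_nh_listener_tested_in_the_nh_order(self, noise_material, oracle_only):
        profile = make_profile(
            pta=5.0, axis="snr_dB", srt=-30.0, slope50=5.0, listener_id="nh"
        )
        s = a.run_noise_procedure(noise_material, profile, oracle_only, seed=1)
        measured = [
            t.x for t in s.trials
            if t.phase == "measure" and t.word_index == 1
        ]
        assert measured == [0.0, -5.0, -10.0, -15.0, -20.0, 5.0, 10.0]

    def test_hi_listener_skips_minus15_and_minus20(self, noise_material, oracle_only):
        profile = make_profile(
            pta=50.0, axis="snr_dB", srt=-20.0, slope50=5.0, listener_id="hi"
        )
        s = a.run_noise_procedure(noise_material, profile, oracle_only, seed=1)
        tested = {t.x for t in s.trials if t.phase == "measure"}
        assert tested == {0.0, -5.0, -10.0, 5.0, 10.0}

    def test_familiarization_list_recorded_but_not_a_point(
        self, noise_material, oracle_only
    ):
        profile = make_profile(pta=5.0, axis="snr_dB", srt=-8.0, listener_id="nh")
        s = a.run_noise_procedure(noise_material, profile, oracle_only, seed=2)
        fam = [t for t in s.trials if t.phase == "familiarization"]
        assert len(fam) == 17 and all(t.x is None for t in fam)
        assert s.trials[0].phase == "familiarization"
        assert all(not np.isnan(p.x) for p in s.points["oracle"])

    def test_deaf_at_zero_snr_imputes_minus5(self, noise_material, oracle_only):
        profile = make_profile(
            pta=60.0, axis="snr_dB", srt=300.0, slope50=5.0, listener_id="deafsnr"
        )
        s = a.run_noise_procedure(noise_material, profile, oracle_only, seed=1)
        pts = {p.x: p for p in s.points["oracle"]}
        assert pts[0.0].provenance == "early_stopped"
        assert pts[-5.0].provenance == "imputed_zero"
        assert -10.0 not in pts  # worse scheduled conditions skipped

    def test_stimulus_level_fixed_at_60_spl(self, noise_material, oracle_only):
        profile = make_profile(pta=30.0, axis="snr_dB", srt=-3.0, listener_id="x")
        s = a.run_noise_procedure(noise_material, profile, oracle_only, seed=4)
        assert s.metadata["stimulus_level_spl"] == 60.0
        assert s.config["stimulus_level_spl"] == 60.0
        # every scheduled condition maps to noise = 60 - SNR
        for snr, noise in s.metadata["noise_levels_spl"].items():
            assert noise == 60.0 - float(snr)
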