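"""Score comparisons, convergence profiles, test-retest, cohort tables."""

import numpy as np
import pytest

import audiosim as a
from audiosim.analysis import (
    RetestSummary,
    convergence_profile,
    list_scores,
    session_metric,
)
from audiosim.analysis import test_retest as retest_summary
from tests.conftest import make_profile


class TestCompareScores:
    def test_raw_and_absolute(self):
        c = a.compare_scores(80.0, 70.0, "%")
        assert (c.raw_diff, c.abs_diff) == (10.0, 10.0)
        c = a.compare_scores(60.0, 70.0, "%")
        assert (c.raw_diff, c.abs_diff) == (-10.0, 10.0)
        c = a.compare_scores(70.0, 70.0, "%")
        assert (c.raw_diff, c.abs_diff) == (0.0, 0.0)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError):
            a.compare_scores(1.0, 2.0, "%", manual_unit="dB")

    def test_raw_means_cancel_but_absolute_do_not(self):
        raws = [a.compare_scores(x, 0.0).raw_diff for x in (10.0, -10.0)]
        abss = [a.compare_scores(x, 0.0).abs_diff for x in (10.0, -10.0)]
        assert np.mean(raws) == 0.0
        assert np.mean(abss) == 10.0


@pytest.fixture
def quiet_sessions(quiet_material, oracle_only):
    sessions = []
    for i, srt in enumerate([35.0, 45.0, 55.0]):
        profile = make_profile(
            pta=srt - 10.0, srt=srt, slope50=5.0, listener_id=f"S{i}"
        )
        sessions.append(
            a.run_quiet_procedure(quiet_material, profile, oracle_only, seed=100 + i)
        )
    return sessions


class TestConvergence:
    def test_constant_scores_converge_immediately(
        self, quiet_material, perfect_listener, oracle_only
    ):
        s = a.run_quiet_procedure(
            quiet_material, perfect_listener, oracle_only, seed=1
        )
        prof = convergence_profile([s], grouping="per_subject")
        assert all(v == 0.0 for v in prof.per_word_abs_diff.values())

    def test_entry_at_final_word_is_identically_zero(self, quiet_sessions):
        for grouping in ("per_subject", "per_list"):
            prof = convergence_profile(quiet_sessions, grouping=grouping)
            assert prof.per_word_abs_diff[17] == 0.0
            assert prof.per_word_sd[17] == 0.0

    def test_hand_computed_cumulative_differences(self, quiet_sessions):
        # recompute |S_k - S_17| for one complete list occurrence by hand
        session = quiet_sessions[1]
        occ = {}
        for t in session.trials:
            if t.x is None:
                continue
            occ.setdefault((t.list_id, t.x), []).append(t)
        (key, trials) = next(
            (k, v) for k, v in occ.items() if len(v) == 17
        )
        trials.sort(key=lambda t: t.word_index)
        correct = np.cumsum([t.per_scorer_correct["oracle"] for t in trials])
        totals = np.cumsum([len(t.target) for t in trials])
        s_k = 100.0 * correct / totals
        expected = np.abs(s_k - s_k[-1])
        single = convergence_profile(
            [_single_occurrence_session(session, key)], grouping="per_subject"
        )
        got = [single.per_word_abs_diff[k] for k in range(1, 18)]
        assert np.allclose(got, expected)

    def test_last_word_contribution_bound(self, quiet_sessions):
        # one 3-phoneme word can move the cumulative mean by at most ~100/17
        prof = convergence_profile(quiet_sessions, grouping="per_subject")
        assert prof.per_word_abs_diff[16] <= 100.0 / 17.0 + 1e-9

    def test_mean_profile_declines_with_word_index(
        self, quiet_material, oracle_only
    ):
        sessions = []
        for i in range(6):
            profile = make_profile(
                pta=30.0, srt=40.0, slope50=4.0, listener_id=f"C{i}"
            )
            sessions.append(
                a.run_quiet_procedure(quiet_material, profile, oracle_only, seed=i)
            )
        prof = convergence_profile(sessions, grouping="per_subject")
        vals = [prof.per_word_abs_diff[k] for k in range(1, 18)]
        sds = [prof.per_word_sd[k] for k in range(1, 18)]
        for k in range(1, 17):
            assert vals[k] <= vals[k - 1] + sds[k - 1] + 1e-9

    def test_early_stopped_only_sessions_are_invalid(
        self, quiet_material, deaf_listener, oracle_only
    ):
        s = a.run_quiet_procedure(quiet_material, deaf_listener, oracle_only, seed=1)
        complete = [
            len(ts)
            for ts in _occurrences(s).values()
        ]
        if all(c <= 7 for c in complete):
            with pytest.raises(ValueError):
                convergence_profile([s])


def _occurrences(session):
    occ = {}
    for t in session.trials:
        if t.x is None:
            continue
        occ.setdefault((t.list_id, t.x), []).append(t)
    return occ


def _single_occurrence_session(session, key):
    """A shallow session copy containing only one list occurrence."""
    import copy

    s = copy.copy(session)
    s.trials = [t for t in session.trials if (t.list_id, t.x) == key]
    return s


class TestTestRetest:
    def test_identical_sessions_differ_by_zero(self, quiet_sessions):
        pairs = [(s, s) for s in quiet_sessions]
        for metric in ("all_words_pct", "srt50", "max_intelligibility"):
            summary = retest_summary(pairs, metric=metric, scorer="oracle")
            assert summary.raw_mean == 0.0
            assert summary.abs_mean == 0.0
            assert summary.n_dropped == 0

    def test_orientation_is_retest_minus_test(self, quiet_sessions):
        s1, s2 = quiet_sessions[0], quiet_sessions[1]
        # same listener id is required; fake it via metadata-compatible copy
        import copy

        s2 = copy.copy(s2)
        s2.listener_id = s1.listener_id
        summary = retest_summary([(s1, s2)], metric="all_words_pct", scorer="oracle")
        m1 = session_metric(s1, "all_words_pct", "oracle")
        m2 = session_metric(s2, "all_words_pct", "oracle")
        assert summary.raw_mean == pytest.approx(m2 - m1)
        assert summary.abs_mean == pytest.approx(abs(m2 - m1))

    def test_mismatched_pairs_rejected(self, quiet_sessions):
        with pytest.raises(ValueError):
            retest_summary([(quiet_sessions[0], quiet_sessions[1])])

    def test_undefined_metric_pairs_dropped_with_count(
        self, quiet_material, deaf_listener, oracle_only, quiet_sessions
    ):
        deaf = a.run_quiet_procedure(
            quiet_material, deaf_listener, oracle_only, seed=1
        )
        pairs = [(deaf, deaf)] + [(s, s) for s in quiet_sessions]
        summary = retest_summary(pairs, metric="srt50", scorer="oracle")
        assert summary.n_dropped == 1  # deaf listener: 50% never bracketed
        assert summary.n_pairs == len(quiet_sessions)

    def test_retest_differences_shrink_with_precision(
        self, inventory, oracle_only
    ):
        # more phonemes per point -> retest absolute SRT differences shrink
        spread = {}
        for wpl in (5, 40):
            material = a.generate_material("quiet", 20, wpl, 3, inventory, seed=2)
            diffs = []
            for i in range(6):
                profile = make_profile(
                    pta=30.0, srt=40.0, slope50=5.0, listener_id=f"P{i}"
                )
                s1 = a.run_quiet_procedure(
                    material, profile, oracle_only, seed=1000 + i
                )
                s2 = a.run_quiet_procedure(
                    material, profile, oracle_only, seed=2000 + i
                )
                r = retest_summary([(s1, s2)], metric="srt50", scorer="oracle")
                if r.n_pairs:
                    diffs.append(r.abs_mean)
            spread[wpl] = np.mean(diffs)
        assert spread[40] < spread[5]


class TestCohortReport:
    def test_zero_error_asr_gives_all_zero_cells(
        self, quiet_material, zero_error_scorers
    ):
        sessions = []
        for i in range(3):
            profile = make_profile(
                pta=30.0, srt=40.0, slope50=5.0, listener_id=f"Z{i}"
            )
            sessions.append(
                a.run_quiet_procedure(
                    quiet_material, profile, zero_error_scorers, seed=i
                )
            )
        report = a.cohort_report(sessions)
        for name, table in report.items():
            assert (table["raw_mean"] == 0.0).all(), name
            assert (table["raw_sd"] == 0.0).all(), name
            assert (table["abs_mean"] == 0.0).all(), name
            assert (table["abs_sd"] == 0.0).all(), name

    def test_single_session_cells_match_hand_computation(
        self, quiet_material, both_scorers
    ):
        profile = make_profile(pta=30.0, srt=40.0, slope50=5.0, listener_id="H")
        session = a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=7)
        report = a.cohort_report([session])
        df = list_scores(session)
        wide = df.pivot_table(index=["list_id", "x"], columns="scorer", values="pct")
        raws = (wide["asr"] - wide["oracle"]).to_numpy()
        all_row = report["per_list"].set_index("group").loc["all"]
        assert all_row["n"] == len(raws)
        assert all_row["raw_mean"] == pytest.approx(raws.mean())
        assert all_row["abs_mean"] == pytest.approx(np.abs(raws).mean())

    def test_triangle_inequality_in_every_cell(self, quiet_material, both_scorers):
        sessions = []
        for i, pta in enumerate([10.0, 50.0]):
            profile = make_profile(
                pta=pta, srt=pta + 10.0, slope50=5.0, listener_id=f"T{i}"
            )
            sessions.append(
                a.run_quiet_procedure(quiet_material, profile, both_scorers, seed=i)
            )
        report = a.cohort_report(sessions)
        for table in report.values():
            ok = table["abs_mean"] + 1e-12 >= table["raw_mean"].abs()
            assert ok.all()
            assert (table["raw_sd"].fillna(0) >= 0).all()
            assert (table["abs_sd"].fillna(0) >= 0).all()
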