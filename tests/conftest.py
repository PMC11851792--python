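import pytest
from hypothesis import HealthCheck, settings

import audiosim as a
from audiosim.listener import flat_audiogram

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def inventory():
    return a.make_default_inventory(6, 12)


@pytest.fixture(scope="session")
def quiet_material(inventory):
    return a.generate_material("quiet", 20, 17, 3, inventory, seed=11)


@pytest.fixture(scope="session")
def noise_material(inventory):
    return a.generate_material("noise", 5, 17, 3, inventory, seed=12)


def make_profile(
    pta=40.0,
    axis="level_dB_HL",
    srt=50.0,
    slope50=5.0,
    floor=0.0,
    ceiling=100.0,
    confusion=None,
    listener_id="T1",
):
    """Deterministic listener profile helper used across the suite."""
    return a.ListenerProfile(
        audiogram=flat_audiogram(pta),
        axis=axis,
        srt=srt,
        slope50=slope50,
        floor=floor,
        ceiling=ceiling,
        confusion=confusion or a.ConfusionPolicy(),
        listener_id=listener_id,
    )


@pytest.fixture
def perfect_listener():
    """Hears everything: p = 1 at every tested level."""
    return make_profile(pta=0.0, srt=-200.0, slope50=5.0, listener_id="perfect")


@pytest.fixture
def deaf_listener():
    """Hears nothing in the tested range: p ~ 0 everywhere."""
    return make_profile(pta=80.0, srt=300.0, slope50=5.0, listener_id="deaf")


@pytest.fixture
def oracle_only():
    return {"oracle": a.OracleScorer()}


@pytest.fixture
def both_scorers(inventory):
    return {
        "oracle": a.OracleScorer(),
        "asr": a.ASRScorer(a.ScorerConfig.from_prevalidation("quiet"), inventory),
    }


@pytest.fixture
def zero_error_scorers(inventory):
    return {
        "oracle": a.OracleScorer(),
        "asr": a.ASRScorer(a.ScorerConfig(0.0, 0.0), inventory),
    }
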