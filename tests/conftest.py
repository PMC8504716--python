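import pytest

from rctresponders import SweepConfig, TrialTable2x2


@pytest.fixture
def seed_table() -> TrialTable2x2:
    """The simplified mortality table of the seed trial: 2:1 allocation,
    194/2333 control deaths vs 269/4687 experimental deaths."""
    return TrialTable2x2(a=194, b=269, c=2139, d=4418)


@pytest.fixture
def perfect_table() -> TrialTable2x2:
    """The all-responder trial: every control dies, every treated survives."""
    return TrialTable2x2(a=60, b=0, c=0, d=121)


@pytest.fixture
def seed_sweep_config() -> SweepConfig:
    return SweepConfig()
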