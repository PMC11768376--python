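import pytest

from wneval import trial_data


@pytest.fixture(scope="session")
def table_2022():
    """Screened 2022 evaluation matrix (9 treatments x 6 indicators)."""
    return trial_data.build_indicator_table(2022)


@pytest.fixture(scope="session")
def table_2023():
    return trial_data.build_indicator_table(2023)


@pytest.fixture(scope="session")
def candidate_2022():
    """Full candidate matrix for screening (9 treatments x 9 indicators)."""
    return trial_data.build_indicator_table(
        2022, indicators=list(trial_data.CANDIDATE_INDICATORS)
    )
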