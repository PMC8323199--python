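import pytest

from taxfill import load_rank_table


@pytest.fixture(scope="session")
def table():
    return load_rank_table()
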