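import numpy as np
import pandas as pd
import pytest

import mpmap


@pytest.fixture(scope="session")
def toy_lexicon():
    return mpmap.read_dic(mpmap.toy_dictionary_path())


@pytest.fixture(scope="session")
def table7():
    return mpmap.load_table7_fixture()


@pytest.fixture(scope="session")
def scheme():
    return mpmap.ClusterScheme.default()


from mpmap.experiments import single_author_table  # noqa: E402,F401  (shared by tests)


@pytest.fixture()
def base16():
    return single_author_table(16, seed=11)
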