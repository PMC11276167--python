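import numpy as np
import pytest

import lvdlnet as lv


@pytest.fixture(scope="session")
def registry():
    return lv.default_registry()


@pytest.fixture(scope="session")
def interval_set():
    return lv.default_interval_set()


@pytest.fixture(scope="session")
def libs_axis(registry):
    return lv.make_libs_axis(registry)


@pytest.fixture(scope="session")
def vnir_axis(interval_set):
    return lv.make_vnir_axis(interval_set)


@pytest.fixture(scope="session")
def tiny_ds():
    """4 spectra per level: enough to exercise shapes and round trips."""
    return lv.generate_preset_dataset("easy", 4, seed=7)


@pytest.fixture(scope="session")
def small_ds():
    """12 spectra per level: enough for a stratified 7:1:2 split."""
    return lv.generate_preset_dataset("easy", 12, seed=11)


@pytest.fixture(scope="session")
def small_feats(small_ds):
    return lv.featurize_dataset(small_ds)


@pytest.fixture(scope="session")
def small_split(small_ds):
    return lv.split_dataset(small_ds.labels, seed=11)
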