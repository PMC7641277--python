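import dataclasses

import pytest

from sanephys import presets


@pytest.fixture(scope="session")
def wt_preset():
    return presets.pacemaker_preset("wt")


@pytest.fixture(scope="session")
def fea_preset():
    return presets.pacemaker_preset("hcn4fea")


@pytest.fixture(scope="session")
def quiet_wt(wt_preset):
    """Noiseless, permanently firing wild-type preset."""
    return dataclasses.replace(
        wt_preset, noise_sd=0.0, frac_nonfiring=0.0, episodic_cell_prob=0.0
    )
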