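import numpy as np
import pytest

import synthlge as sl


@pytest.fixture(scope="session")
def scheme():
    """The standard 4(1)3(1)2 MOLLI scheme at a 1000 ms heart period."""
    return sl.SamplingScheme(rr_interval=1000.0)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48-px phantom with one mid-ventricular scar wedge, noiseless."""
    cfg = sl.PhantomConfig(
        image_size=48,
        scar_specs=(sl.ScarSpec(slice_index=2, start_deg=30.0, span_deg=60.0,
                                transmurality=0.6),),
        seed=11,
    )
    maps, truth = sl.make_lv_phantom(cfg)
    return cfg, maps, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
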