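import numpy as np
import pytest

from asymrepro.effects import EffectRecord


def make_record(
    dataset_id="ds1",
    measure_id="m",
    n=50,
    d=0.3,
    var_d=None,
    p=0.05,
):
    """Effect record with consistent derived fields for fixture building."""
    var_d = var_d if var_d is not None else 1.0 / n + d * d / (2 * n)
    return EffectRecord(
        dataset_id=dataset_id,
        measure_id=measure_id,
        n=n,
        t=d * np.sqrt(n),
        d=d,
        var_d=var_d,
        p=p,
        df=n - 1,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
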