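import numpy as np
import pandas as pd
import pytest

from ctbmd import GenerativeParams, ReferenceModel, generate_reference_population


@pytest.fixture(scope="session")
def toy_ref() -> ReferenceModel:
    """Hand-built reference: young 160/35 HU (f), 170/35 (m); decade bins.

    Stratum means fall 10 HU per decade from the young mean; SD 30.
    """
    edges = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    mean = {}
    sd = {}
    for s, young in (("female", 160.0), ("male", 170.0)):
        for b in range(len(edges) - 1):
            mean[(s, b)] = young - 10.0 * b
            sd[(s, b)] = 30.0
    return ReferenceModel(
        young_mean_by_sex={"female": 160.0, "male": 170.0},
        young_sd_by_sex={"female": 35.0, "male": 35.0},
        agematched_mean=mean,
        agematched_sd=sd,
        age_bin_edges=edges,
    )


@pytest.fixture(scope="session")
def gen_ref():
    """Reference model sampled by the synthetic generator (seeded)."""
    params = GenerativeParams(seed=11)
    model, young = generate_reference_population(params, seed=11)
    return model


def measurements_frame(rows) -> pd.DataFrame:
    """Measurement rows (patient_id, phase, level, hu) -> full schema frame."""
    out = []
    for pid, phase, level, hu in rows:
        out.append(dict(patient_id=pid, phase=phase, level=level,
                        mean_hu=hu, median_hu=hu, voxel_count=1000,
                        roi_volume_ml=1.0))
    return pd.DataFrame(out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
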