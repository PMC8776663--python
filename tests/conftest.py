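import numpy as np
import pytest
from scipy.special import expit

from mrdsurvey.survey_data import (
    ClusterObservation,
    StratumSpec,
    SurveyDataset,
    TransectRecord,
)
from mrdsurvey import kane_basin as kb


@pytest.fixture(scope="session")
def kb_fixture() -> SurveyDataset:
    """Bin-midpoint reconstruction of the 28 retained Kane Basin clusters."""
    return kb.sightings_fixture()


def simulate_capture_histories(
    rng: np.random.Generator,
    n: int,
    b0f: float,
    b0r: float,
    b1_per_km: float,
    ice_beta: float = 0.0,
    w_m: float = 1400.0,
) -> SurveyDataset:
    """Detected clusters drawn directly from the double-observer logistic model.

    Distances are uniform on [0, w]; front/rear detections are independent
    Bernoulli draws from the logistic model (optionally with an ice-structure
    effect); only clusters detected by at least one team are kept, exactly
    mirroring the conditional likelihood's sampling frame.
    """
    transect = TransectRecord(id="T1", stratum_id="s", length_km=100.0, design_order=0)
    stratum = StratumSpec(id="s", area_km2=1000.0, truncation_m=w_m)
    observations: list[ClusterObservation] = []
    while len(observations) < n:
        m = 2 * (n - len(observations)) + 20
        y = rng.uniform(0.0, w_m, m)
        ice = rng.binomial(1, 0.5, m)
        pf = expit(b0f + b1_per_km * y / 1000.0 + ice_beta * ice)
        pr = expit(b0r + b1_per_km * y / 1000.0 + ice_beta * ice)
        sf = rng.uniform(size=m) < pf
        sr = rng.uniform(size=m) < pr
        for i in np.where(sf | sr)[0]:
            if len(observations) >= n:
                break
            observations.append(
                ClusterObservation(
                    id=f"o{len(observations)}",
                    transect_id="T1",
                    stratum_id="s",
                    distance_m=float(y[i]),
                    seen_front=int(sf[i]),
                    seen_rear=int(sr[i]),
                    cluster_size=int(rng.integers(1, 4)),
                    activity=int(rng.binomial(1, 0.3)),
                    ice_rough=int(ice[i]),
                    visibility_bad=int(rng.binomial(1, 0.2)),
                    cloud_quartile=int(rng.integers(0, 5)),
                )
            )
    return SurveyDataset(tuple(observations), (transect,), (stratum,))
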