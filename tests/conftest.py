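import numpy as np
import pytest

from fjordflux.watermass import EnvelopeTable, TSRecord, WaterMassEnvelope


@pytest.fixture
def toy_envelopes() -> EnvelopeTable:
    """Small four-class envelope table used throughout the tests.

    AW {T>=3, S>=34.9, sigma<27.92}; TAW {1<=T<3, S>=34.7, sigma<27.92};
    ArW {T<1, 34.3<=S<=34.8}; LW {0.5<=T<1, S>=34.3}.
    """
    return EnvelopeTable(
        envelopes=[
            WaterMassEnvelope("AW", t_min=3.0, s_min=34.9, sigma_max=27.92),
            WaterMassEnvelope("TAW", t_min=1.0, t_max=3.0, s_min=34.7,
                              sigma_max=27.92),
            WaterMassEnvelope("ArW", t_max=1.0, s_min=34.3, s_max=34.8,
                              closed={"s_max": True}),
            WaterMassEnvelope("LW", t_min=0.5, t_max=1.0, s_min=34.3),
        ],
    )


def make_record(t, s, sigma=None, depth=10.0):
    return TSRecord(station_id="st", region="toy", year=2016, depth=depth,
                    temperature=t, salinity=s, sigma_theta=sigma)


@pytest.fixture
def rng():
    return np.random.default_rng(20170811)
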