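import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

from nirsload.montage import default_montage
from nirsload.preprocessing import (build_sample_set, channel_qc,
                                    intensity_to_od, lowpass_filter,
                                    mbll_convert)
from nirsload.synthetic import ForwardModelConfig, generate_design, generate_fnirs


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def default_design():
    return generate_design(seed=0)


def preprocess_recording(rec, lowpass=True, drop_incorrect=True):
    """Standard chain: QC -> OD -> Beer-Lambert -> filter -> sample set."""
    qc = channel_qc(rec.raw_intensity)
    od = intensity_to_od(rec.raw_intensity)
    hemo = mbll_convert(od, rec.config.constants, rec.sampling_rate,
                        montage=rec.config.montage)
    if lowpass:
        hemo.hbr = lowpass_filter(hemo.hbr, sampling_rate=rec.sampling_rate)
    hemo.channel_mask = qc.mask
    return build_sample_set(hemo, rec.design, drop_incorrect=drop_incorrect)


def simulate_samples(seed=0, design_kwargs=None, **fwd_kwargs):
    """Generate a session and run the preprocessing chain."""
    design = generate_design(seed=seed, **(design_kwargs or {}))
    cfg = ForwardModelConfig(seed=seed, **fwd_kwargs)
    rec = generate_fnirs(design, cfg)
    return preprocess_recording(rec), rec
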