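import numpy as np
import pytest

from fetaltdi.core import ROISpec
from fetaltdi.events import AnalysisConfig, _canonical_base
from fetaltdi.preprocess import acceleration, moving_average
from fetaltdi.synthetic import HeartGeometry, HeartModelParams, generate_trace


TINY_ROI = ROISpec.at_av_plane(1e-6, 2.0)


@pytest.fixture(scope="session")
def default_params():
    return HeartModelParams()


@pytest.fixture(scope="session")
def geometry_ga3():
    return HeartGeometry.for_ga(38.0)


@pytest.fixture(scope="session")
def clean_trace(default_params, geometry_ga3):
    """Noise-free 7-cycle trace sampled with a 2x2 mm ROI, plus ground truth."""
    return generate_trace(default_params, geometry_ga3, ROISpec.at_av_plane(2.0, 2.0), seed=1)


@pytest.fixture(scope="session")
def clean_pipeline(clean_trace):
    """(smoothed trace, setting-1 filtered trace, acceleration) for the clean fixture."""
    trace, _ = clean_trace
    cfg = AnalysisConfig()
    base = _canonical_base(trace, cfg)
    filt = moving_average(base, cfg.filter_windows[0])
    return base, filt, acceleration(filt)
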