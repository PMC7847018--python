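import numpy as np
import pytest

from crrtpk.core import (
    Analyte,
    CircuitConfig,
    ConcentrationSeries,
    ExperimentRecord,
    Filter,
    Mode,
    Site,
)

BENCH_TIMES_MIN = np.array([0.0, 10.0, 20.0, 30.0, 45.0, 60.0])


def mono_exponential_series(
    c0=100.0, k_per_h=0.9, times_min=BENCH_TIMES_MIN, site=Site.pre_filter
):
    conc = c0 * np.exp(-k_per_h * times_min / 60.0)
    return ConcentrationSeries(site, Analyte.apixaban, times_min, conc)


@pytest.fixture
def cvvh_config():
    return CircuitConfig(
        mode=Mode.CVVH, filter=Filter.HF1400, effluent_flow=2.0, dilution_split=0.0
    )


@pytest.fixture
def cvvhd_config():
    return CircuitConfig(mode=Mode.CVVHD, filter=Filter.M150, effluent_flow=4.0)


def bolus_record(config, dose_mg, c0, k_per_h, times_min=BENCH_TIMES_MIN):
    """Noiseless bolus experiment with consistent paired samples."""
    pre = mono_exponential_series(c0, k_per_h, times_min)
    paired_t = np.array([10.0, 30.0])
    c_pre_paired = c0 * np.exp(-k_per_h * paired_t / 60.0)
    # single-pass extraction consistent with CL = k*V where V = dose/c0 (L)
    V = 1000.0 * dose_mg / c0
    cl = k_per_h * V
    extraction = cl / config.plasma_flow
    c_post = c_pre_paired * (1 - extraction)
    if config.mode is Mode.CVVH:
        c_eff = 0.6 * c_pre_paired
    else:
        c_eff = 0.6 * (c_pre_paired + c_post) / 2
    series = [
        pre,
        ConcentrationSeries(Site.post_filter, Analyte.apixaban, paired_t, c_post),
        ConcentrationSeries(Site.effluent, Analyte.apixaban, paired_t, c_eff),
    ]
    return ExperimentRecord(config=config, series=series, dose_mg=dose_mg)
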