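import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from pgtrange.spectra import BinningSpec, EventList, SpotMeta, Spectrum2D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_binning():
    """A coarse grid: 20 time bins of 0.25 ns, energy 0.1-8.0 MeV in 0.5 MeV."""
    return BinningSpec(
        time_bin_width_ns=0.25,
        n_time_bins=20,
        energy_bin_width_MeV=0.5,
        energy_min_MeV=0.1,
        energy_max_MeV=8.1,
    )


@pytest.fixture
def segment_binning():
    """Smallest grid admitting the five 230-bin time segments."""
    return BinningSpec(
        time_bin_width_ns=1.06 / 230,
        n_time_bins=1150,
        energy_bin_width_MeV=0.25,
        energy_min_MeV=0.1,
        energy_max_MeV=8.1,
    )


def make_meta(spot_id="s0", cavity=0.0, **kw) -> SpotMeta:
    kw.setdefault("beam_energy", 162.0)
    kw.setdefault("mode", "static")
    return SpotMeta(spot_id=spot_id, cavity_mm=cavity, **kw)


def make_events(energies, times, t_rf=None, **meta_kw) -> EventList:
    kw = {}
    if t_rf is not None:
        kw["t_rf_ns"] = t_rf
    return EventList(
        meta=make_meta(**meta_kw),
        energy_MeV=np.asarray(energies, dtype=float),
        time_ns=np.asarray(times, dtype=float),
        **kw,
    )


def make_spectrum(counts, binning, **meta_kw) -> Spectrum2D:
    return Spectrum2D(meta=make_meta(**meta_kw), counts=counts, binning=binning)


@pytest.fixture
def random_spectrum(rng, small_binning):
    counts = rng.poisson(3.0, size=(small_binning.n_time_bins, small_binning.n_energy_bins))
    return make_spectrum(counts.astype(float), small_binning)
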