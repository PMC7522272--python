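import pytest

from opwf.synthetic import PulseTemplateSpec, StudyConfig, make_pulse_template
from opwf.waveform import CardiacCycleWaveform


def make_cycle(spec: PulseTemplateSpec, f: float = 1.0) -> CardiacCycleWaveform:
    return CardiacCycleWaveform(samples=make_pulse_template(spec), f=f)


@pytest.fixture
def tri_spec_1000() -> PulseTemplateSpec:
    """Reference triangular template with known closed-form PWF values."""
    return PulseTemplateSpec(dc=35.0, ac=10.0, rise_fraction=0.5, n_frames=1000)


@pytest.fixture
def tri_cycle_1000(tri_spec_1000) -> CardiacCycleWaveform:
    return make_cycle(tri_spec_1000, f=1.0)


@pytest.fixture
def recovery_config() -> StudyConfig:
    """Acquisition config with an integer number of frames per cycle (30)."""
    return StudyConfig(frame_rate_hz=120.0, heart_rate_bpm=240.0, noise_sd=0.0, seed=0)


@pytest.fixture
def aligned_vessel_spec() -> PulseTemplateSpec:
    """Vessel template whose peak phase lands on the 30-frame cycle grid."""
    return PulseTemplateSpec(dc=45.0, ac=12.0, rise_fraction=0.4, n_frames=240)


@pytest.fixture
def aligned_tissue_spec() -> PulseTemplateSpec:
    return PulseTemplateSpec(dc=25.0, ac=6.0, rise_fraction=0.4, n_frames=240)
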