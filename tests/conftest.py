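import pytest

from cchm.holo_sim import NoiseModel, VirtualMicroscope
from cchm.signal_model import MisalignmentState, OpticsConfig, SourceModel


@pytest.fixture(scope="session")
def src_rect() -> SourceModel:
    """Narrowband rectangular spectrum: sinc temporal envelope with side lobes."""
    return SourceModel(spectral_shape="rectangular")


@pytest.fixture(scope="session")
def src_gauss() -> SourceModel:
    """Gaussian spectrum: smooth, lobe-free temporal envelope."""
    return SourceModel(spectral_shape="gaussian")


@pytest.fixture(scope="session")
def optics_small() -> OpticsConfig:
    """128 px detector, 0.6 um object sampling, bin-aligned diagonal carrier."""
    return OpticsConfig.bin_aligned(n=128, dx_object_um=0.6)


@pytest.fixture(scope="session")
def optics_wide() -> OpticsConfig:
    """256 px detector with 1 um sampling: field wide enough for 100 um offsets."""
    return OpticsConfig.bin_aligned(n=256, dx_object_um=1.0)


@pytest.fixture
def make_mic(optics_small, src_rect):
    """Factory for quiet (noise-free unless asked) small microscopes."""

    def factory(
        state=None,
        source=src_rect,
        optics=optics_small,
        noise_frac=0.0,
        seed=0,
        phase_object=None,
        **kw,
    ) -> VirtualMicroscope:
        return VirtualMicroscope(
            source,
            optics,
            state or MisalignmentState(),
            phase_object=phase_object,
            noise=NoiseModel(read_noise_frac=noise_frac),
            seed=seed,
            **kw,
        )

    return factory
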