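import numpy as np
import pytest

from uraman.core import (
    Group,
    Sex,
    SpectraSet,
    Spectrum,
    SpectrumMeta,
    WavenumberAxis,
    default_grid,
)
from uraman.pipeline import RunConfig, run_pipeline
from uraman.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def grid() -> WavenumberAxis:
    return default_grid()


@pytest.fixture
def smooth_spectrum(grid) -> Spectrum:
    """Broad smooth profile with no narrow features (despike no-op input)."""
    x = grid.values
    y = 100.0 + 50.0 * np.exp(-0.5 * ((x - 1100.0) / 300.0) ** 2)
    return Spectrum(grid, y, SpectrumMeta("smooth"))


def make_set(grid, intensities, groups=None) -> SpectraSet:
    groups = groups or [Group.CT] * len(intensities)
    spectra = [
        Spectrum(
            grid,
            y,
            SpectrumMeta(
                spectrum_id=f"s{i + 1}",
                sample_id=f"sample{i + 1}",
                group=g,
                sex=Sex.M,
                replicate_index=1,
            ),
        )
        for i, (y, g) in enumerate(zip(intensities, groups))
    ]
    return SpectraSet(grid, spectra)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort (40 samples x 6 replicates)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run on the default cohort, shared across tests."""
    return run_pipeline(RunConfig(simulate=CohortConfig(seed=1), seed=1))
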