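import numpy as np
import pytest

from qhtsdiff import ConcentrationSeries, LibrarySpec, generate_library, generate_screen


@pytest.fixture(scope="session")
def series() -> ConcentrationSeries:
    return ConcentrationSeries.default()


def small_spec(seed: int = 11, **kwargs) -> LibrarySpec:
    """120-compound, 6-class library with one planted selective class."""
    defaults = dict(
        n_compounds=120,
        class_sizes={"MTOR": 20, "TOP2A": 20, "EGFR": 20, "BRD4": 20,
                     "HDAC1": 20, "SRC": 20},
        fraction_active=0.5,
        selective_classes={"MTOR": -1.5},
        seed=seed,
    )
    defaults.update(kwargs)
    return LibrarySpec(**defaults)


@pytest.fixture(scope="session")
def small_screen(series):
    """Annotations, truth and a low-noise raw screen for the small library."""
    spec = small_spec()
    annotations, truth = generate_library(spec, series)
    records = generate_screen(annotations, truth, series, noise_sd=2.0, seed=12)
    return annotations, truth, records
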