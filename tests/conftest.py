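import numpy as np
import pandas as pd
import pytest

from ftirnet.spectra import SpectralDataset, WavenumberGrid
from ftirnet.synth import preset, generate
from ftirnet.spectra import average_replicates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """12 spectra (2 classes x 3 samples x 2 replicates) on a 10-point grid."""
    grid = WavenumberGrid(start=700, stop=736, step=4)
    rows, spectra = [], []
    for ci, cname in enumerate(["AS", "HC"]):
        for si in range(3):
            base = rng.random(grid.n_points) + ci
            for ri in range(2):
                rows.append(
                    {"sample_id": f"{cname}{si}", "replicate_id": ri, "class_label": cname}
                )
                spectra.append(base + 0.01 * ri)
    return SpectralDataset(
        grid=grid,
        absorbance=np.vstack(spectra),
        meta=pd.DataFrame(rows),
        class_names=("AS", "HC"),
    )


@pytest.fixture(scope="session")
def tiny_easy_dataset():
    """Replicate-averaged easy-preset dataset, 6 samples/class: fast training."""
    cfg = preset("easy", n_samples_per_class=6, n_replicates=2, seed=7)
    return average_replicates(generate(cfg))
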