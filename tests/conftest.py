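import numpy as np
import pandas as pd
import pytest

from ketox import curves, io, synthetic


@pytest.fixture(scope="session")
def grid():
    return curves.build_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    return curves.build_grid(points_per_decade=2)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact deterministic dataset exercising every reader."""
    return synthetic.generate(
        synthetic.GeneratorConfig(n_chemicals=30, n_assays=10, n_kes=4, seed=42)
    )


@pytest.fixture()
def bundle_dir(tmp_path, small_bundle):
    return small_bundle.write(tmp_path / "bundle")


def make_labels_frame(records):
    """Hand-build a labels frame from (chem_id, tox, hc, hb) tuples."""
    return io.labels_frame(
        [io.HepatotoxLabel(chem_id=c, hepatotoxic=t, hepatocellular=hc, hepatobiliary=hb) for c, t, hc, hb in records]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
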