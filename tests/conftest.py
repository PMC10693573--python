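import numpy as np
import pandas as pd
import pytest

from vped.config import RenderConfig
from vped.synthetic import TrajectoryTable, render_image, sample_features


@pytest.fixture(scope="session")
def trajectories() -> TrajectoryTable:
    return TrajectoryTable()


@pytest.fixture(scope="session")
def benchmark_scene():
    """One default synthetic scene: 50 non-overlapping pores, 10 vessels."""
    fs = sample_features(20, 50, seed=11)
    pores = fs[fs["kind"] == "pore"]
    vessels = fs[fs["kind"] == "vessel"].head(10)
    sample = pd.concat([pores, vessels], ignore_index=True)
    image, truth = render_image(sample, seed=12)
    return image, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def circle_polygon(radius: float, n: int = 64, centre=(0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([centre[0] + radius * np.cos(t),
                            centre[1] + radius * np.sin(t)])
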