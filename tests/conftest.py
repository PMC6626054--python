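import numpy as np
import pytest

from wormscreen import PlateLayout, PopulationSpec, SimConfig, simulate_population


@pytest.fixture(scope="session")
def layout() -> PlateLayout:
    return PlateLayout()


@pytest.fixture(scope="session")
def small_layout() -> PlateLayout:
    """Single-region plate small enough to render quickly in tests."""
    return PlateLayout(width_mm=20.0, height_mm=16.0, n_cols=1, n_rows=1, border_mm=1.0)


@pytest.fixture(scope="session")
def disease_tracks(layout):
    """Default disease-model population, full-length recording."""
    spec = PopulationSpec(n_animals=200, median_speed_mm_s=0.043)
    return simulate_population(spec, layout, SimConfig(seed=11))


def make_track(x, y, t=None, animal_id=0, region=-1):
    """Small helper to build a track from coordinate lists."""
    from wormscreen import Track

    x = np.asarray(x, dtype=float)
    t = np.arange(len(x), dtype=float) if t is None else np.asarray(t, dtype=float)
    return Track(
        animal_id=animal_id,
        frames=np.arange(len(x)),
        t_s=t,
        x_mm=x,
        y_mm=np.asarray(y, dtype=float),
        region=region,
    )
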