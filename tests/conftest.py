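import numpy as np
import pytest

from enmstack.climate import ClimateStack, ScenarioTag, VirtualSpecies, generate_climate


@pytest.fixture
def base_stack() -> ClimateStack:
    """Small two-layer baseline climate used across unit tests."""
    return generate_climate((20, 20), ["temp", "precip"], autocorr_length_km=20,
                            seed=42, cell_size_km=10.0)


@pytest.fixture
def narrow_species() -> VirtualSpecies:
    return VirtualSpecies("spA", {"temp": 0.5, "precip": -0.5},
                          {"temp": 0.6, "precip": 0.6}, occupancy_threshold=0.3)


def make_stack(layers: dict, cell_size_km: float = 10.0,
               tag: ScenarioTag | None = None) -> ClimateStack:
    """Build a ClimateStack straight from arrays (test helper)."""
    arrs = {k: np.asarray(v, dtype=float) for k, v in layers.items()}
    shape = next(iter(arrs.values())).shape
    return ClimateStack(grid_shape=shape, cell_size_km=cell_size_km, layers=arrs,
                        tag=tag or ScenarioTag("baseline"))
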