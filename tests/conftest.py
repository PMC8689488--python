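import numpy as np
import pandas as pd
import pytest

from rosquant import ZStack, default_phantom, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """A tiny 3-channel, 4-slice stack of random 12-bit intensities."""
    vox = rng.integers(0, 4096, size=(3, 4, 8, 8), dtype=np.uint16)
    return ZStack(vox, channels=("ch1", "ch2", "ch3"), pixel_size_um=2.5)


@pytest.fixture
def clean_phantom():
    """Noise-free 256-square phantom with a 25% true ROS fraction."""
    return render_phantom(default_phantom((256, 256), ros_fraction=0.25, noise_sd=0.0, seed=7))


def balanced_table(
    rng,
    n_treatments=3,
    n_containers=2,
    n_individuals=5,
    treatment_effects=None,
    container_sd=1.0,
    residual_sd=1.0,
    response="y",
):
    """A balanced nested layout with Gaussian effects, as a tidy table."""
    effects = treatment_effects or [0.0] * n_treatments
    rows = []
    for ti in range(n_treatments):
        for ci in range(n_containers):
            c_eff = rng.normal(0, container_sd)
            for ii in range(n_individuals):
                rows.append(
                    {
                        "treatment": f"T{ti}",
                        "container": f"T{ti}-c{ci}",
                        "individual_id": f"T{ti}-c{ci}-i{ii}",
                        response: effects[ti] + c_eff + rng.normal(0, residual_sd),
                    }
                )
    return pd.DataFrame(rows)
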