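import numpy as np
import pandas as pd
import pytest

from irakit import (
    AnnualMatrix,
    SeriesVector,
    aegean_like_preset,
    fit_pca,
    generate_scenario,
    orient_components,
)


def make_series(values, start=2000, label="x") -> SeriesVector:
    values = np.asarray(values, dtype=float)
    years = np.arange(start, start + len(values))
    return SeriesVector.from_arrays(years, values, label)


def make_matrix(values, start=2000, names=None) -> AnnualMatrix:
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"v{i}" for i in range(values.shape[1])]
    years = np.arange(start, start + values.shape[0])
    return AnnualMatrix.from_arrays(years, values, names)


@pytest.fixture(scope="session")
def noise_free_scenario():
    cfg = aegean_like_preset(seed=0, noise_sd_latent=0.0,
                             noise_sd_idiosyncratic=0.0)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def noise_free_scores(noise_free_scenario):
    stressors, system, truth = noise_free_scenario
    pc1sys = orient_components(fit_pca(system, scale=True)).score_series(1)
    pc1str = orient_components(fit_pca(stressors, scale=True)).score_series(1)
    return pc1sys, pc1str, truth


@pytest.fixture(scope="session")
def noisy_scenario():
    # a draw whose sequential-TGAM thresholds land exactly on truth, so the
    # geometry tests exercise a well-formed three-basin landscape
    cfg = aegean_like_preset(seed=3)
    return generate_scenario(cfg)
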