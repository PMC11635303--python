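import warnings

import numpy as np
import pytest

from canopylai.pipeline import RunConfig, stage_select, stage_train
from canopylai.spectra import build_spectral_features, plot_mean_spectrum
from canopylai.synth import (STAGES, make_layout, simulate_cube,
                             simulate_lai)
from canopylai.textures import pca_first_component, texture_feature_table

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings(
    "ignore", module="sklearn")


@pytest.fixture(scope="session")
def default_layout():
    return make_layout(0)


@pytest.fixture(scope="session")
def default_truth(default_layout):
    truth = []
    for stage in STAGES:
        truth.extend(simulate_lai(default_layout, stage, 0))
    return truth


@pytest.fixture(scope="session")
def default_cubes(default_layout, default_truth):
    return {stage: simulate_cube(default_layout, default_truth, stage, 0)
            for stage in STAGES}


@pytest.fixture(scope="session")
def default_features(default_layout, default_truth, default_cubes):
    """The full 144 x 308 combined feature table at seed 0."""
    import pandas as pd

    from canopylai.containers import FeatureTable
    tables = []
    for stage in STAGES:
        cube = default_cubes[stage]
        recs = plot_mean_spectrum(cube, default_layout, stage)
        spec = build_spectral_features(recs)
        pc1 = pca_first_component(cube)
        tex = texture_feature_table(pc1, default_layout, stage)
        tables.append(spec.join(tex))
    data = pd.concat([t.data for t in tables]).sort_index()
    return FeatureTable(data, tables[0].families)


@pytest.fixture(scope="session")
def default_experiment(default_features, default_truth, tmp_path_factory):
    """SPA selections + the full 5 x 3 x 2 evaluation grid at seed 0."""
    cfg = RunConfig(seed=0,
                    out_dir=str(tmp_path_factory.mktemp("experiment")))
    screen, selections = stage_select(cfg, default_features, default_truth)
    result = stage_train(cfg, default_features, default_truth,
                         {fs: r.chosen_columns
                          for fs, r in selections.items()})
    return {"screen": screen, "selections": selections, "result": result}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
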