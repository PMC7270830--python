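import numpy as np
import pandas as pd
import pytest

from phenorow.pipeline import RunConfig, run_pipeline, simulate
from phenorow.synthetic import TrialLayout, generate_layout, render_ortho


@pytest.fixture(scope="session")
def small_layout():
    """4 entries x 3 blocks: 36 rows, 1,152 plants — fast but non-trivial."""
    return TrialLayout(n_entries=4, n_reps=3, n_blocks=3, rng_seed=7)


@pytest.fixture(scope="session")
def small_truth(small_layout):
    plants, rows, plots = generate_layout(small_layout)
    return plants, rows, plots


@pytest.fixture(scope="session")
def small_render(small_layout, small_truth):
    plants, _, _ = small_truth
    raster, ndvi_truth, panels, gcps = render_ortho(
        plants, small_layout, bands=("red", "nir")
    )
    return raster, ndvi_truth, panels, gcps


@pytest.fixture(scope="session")
def field_run(tmp_path_factory):
    """Full synthetic dataset plus a complete pipeline run on disk."""
    out = tmp_path_factory.mktemp("field_run")
    cfg = RunConfig(
        out_dir=str(out), n_entries=4, n_reps=3, n_blocks=3, seed=7,
        harvest_noise_sd=5.0,
    )
    simulate(cfg)
    cfg.raster = str(out / "ortho.tif")
    cfg.gcps = str(out / "gcps.csv")
    cfg.panels = str(out / "panels.csv")
    cfg.track = str(out / "track.csv")
    cfg.harvest = str(out / "harvest_plots.csv")
    manifest = run_pipeline(cfg)
    return cfg, out, manifest


@pytest.fixture(scope="session")
def field_truth(field_run):
    _, out, _ = field_run
    return pd.read_csv(out / "plants.csv")
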