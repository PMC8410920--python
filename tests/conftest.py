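"""Shared fixtures: a small seeded synthetic domain, generated once."""

from __future__ import annotations

import pytest

from thermidx.pipeline import run_pipeline
from thermidx.synth import SynthConfig, generate_forcing, generate_stations


@pytest.fixture(scope="session")
def synth_cfg():
    """2-day, ~20x20-cell synthetic July domain, noise-free stations."""
    return SynthConfig(bbox=(110.0, 112.0, 29.0, 31.0), start="2018-07-01",
                       n_days=2, seed=1234, n_stations=10)


@pytest.fixture(scope="session")
def synth_domain(tmp_path_factory, synth_cfg):
    """Forcing NetCDF paths + noise-free station CSV for the session."""
    d = tmp_path_factory.mktemp("domain")
    paths = generate_forcing(synth_cfg, d)
    csv = generate_stations(synth_cfg, paths["fine"], d / "stations.csv")
    return {"cfg": synth_cfg, "fine": paths["fine"], "fdir": paths["fdir"],
            "stations": csv, "dir": d}


@pytest.fixture(scope="session")
def pipeline_output(tmp_path_factory, synth_domain):
    """Daily NetCDF files produced by one full pipeline run."""
    out = tmp_path_factory.mktemp("daily")
    paths = run_pipeline({"fine_forcing": str(synth_domain["fine"]),
                          "fdir_forcing": str(synth_domain["fdir"]),
                          "output_dir": str(out)})
    return {"paths": paths, "dir": out, "clips": run_pipeline.last_clips}
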