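from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dtims.calibration import SingleFieldCalibration
from dtims.synthetic import SimulationConfig, simulate_campaign


@pytest.fixture(scope="session")
def campaign100():
    """A 100-chemical campaign under default study conditions (pinned seed)."""
    return simulate_campaign(SimulationConfig(n_chemicals=100, seed=11))


@pytest.fixture(scope="session")
def noiseless_campaign():
    """A noise- and artifact-free 60-chemical campaign: curation should be lossless."""
    cfg = SimulationConfig(
        n_chemicals=60, seed=21,
        ccs_scatter_sigma=0.03, drift_noise_sigma_ms=0.0, mz_noise_sigma_ppm=0.0,
        isotope_noise_rel=0.0, multimer_rate=0.0, degraded_rate=0.0,
    )
    return simulate_campaign(cfg)


@pytest.fixture(scope="session")
def calibration_fit(campaign100):
    return SingleFieldCalibration(
        campaign100["calibrant_arrivals"], campaign100["calibrants"]
    ).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_synthetic_library(entries: list[dict]):
    """Build a Library from minimal entry dicts, filling schema defaults."""
    from dtims.library_io import LIBRARY_COLUMNS, Library

    rows = []
    for i, e in enumerate(entries):
        row = {
            "chemical_id": e.get("chemical_id", f"DTXCHK{i:05d}"),
            "name": e.get("name", f"chem-{i}"),
            "formula": e.get("formula", "C10H10O2"),
            "class": e.get("class", "Pesticide"),
            "ion_type": e.get("ion_type", "[M+H]+"),
            "mode": e.get("mode", "ESI+"),
            "mz_theoretical": e.get("mz_theoretical", e.get("mz", 200.0)),
            "mz_measured_mean": e.get("mz", 200.0),
            "mass_error_ppm": e.get("mass_error_ppm", 0.0),
            "ccs_mean_A2": e.get("ccs", 150.0),
            "replicate_pct_diff": e.get("replicate_pct_diff", 0.1),
            "n_replicates": e.get("n_replicates", 2),
            "trend_pct_dev": e.get("trend_pct_dev", 1.0),
        }
        rows.append(row)
    return Library(entries=pd.DataFrame(rows, columns=LIBRARY_COLUMNS))
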