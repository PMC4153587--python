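import numpy as np
import pandas as pd
import pytest

import aphidlag as al


@pytest.fixture
def flat_temps() -> al.TemperatureSeries:
    """One year of constant 7 °C days."""
    days = pd.date_range("2000-01-01", periods=366)
    return al.TemperatureSeries(days, np.full(len(days), 7.0))


@pytest.fixture
def toy_panel() -> pd.DataFrame:
    """Two years, one plot, weekly counts with known TSM."""
    rows = []
    for year, counts in [(2001, [0, 10, 40, 120, 30]), (2002, [0, 0, 20, 80, 200, 50])]:
        dates = pd.date_range(f"{year}-05-10", periods=len(counts), freq="7D")
        for d, a in zip(dates, counts):
            rows.append({"year": year, "plot": "A", "date": d, "aphids": a,
                         "tillers": 100})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def paper_scale_config() -> al.SyntheticConfig:
    """The study conditions: 24 years × 6 plots, truth (β₁, δ, γ) = (−15, −20, 0)."""
    return al.SyntheticConfig(plots_min=6, plots_max=6)


@pytest.fixture(scope="session")
def paper_scale_fit(paper_scale_config):
    """One simulated study and its model-1 and model-3 fits (shared, read-only)."""
    temps, rec = al.simulate_records(paper_scale_config, seed=42)
    f1 = al.fit_model(rec, temps, al.DesignSpec(model_id=1, depth_L=123))
    f3 = al.fit_model(rec, temps, al.DesignSpec(model_id=3, depth_L=123))
    return temps, rec, f1, f3
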