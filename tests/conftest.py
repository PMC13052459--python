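import numpy as np
import pandas as pd
import pytest


def make_detections(rows):
    """Detection frame from (tag, receiver, iso_time) tuples."""
    df = pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_deployments(tags, river="Shin", year=2019,
                     release="2019-04-15T12:00:00"):
    return pd.DataFrame({
        "tag_id": list(tags), "river": river, "year": year,
        "release_time": pd.Timestamp(release),
        "fork_length_mm": 140.0, "mass_g": 25.0,
        "delay_min_s": 18.0, "delay_max_s": 35.0,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced synthetic study (three rivers) shared by integration tests."""
    from postsmolt import reference, simulate
    config = simulate.SimulationConfig()
    config.cohorts = reference.COHORTS[
        reference.COHORTS["river"].isin(["Shin", "Oykel", "Spey"])].copy()
    return simulate.scenario_moray(seed=42, config=config)
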