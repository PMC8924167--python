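import numpy as np
import pandas as pd
import pytest

from lobsterresp import (
    AnimalRecord,
    ChamberSpec,
    SimulationTruth,
    simulate_mo2_trajectory,
    synthesize_trace,
)
from lobsterresp.mo2_extraction import MO2Series, extract_mo2
from lobsterresp.trace_io import BackgroundRecord


@pytest.fixture
def default_truth():
    return SimulationTruth(seed=42)


@pytest.fixture
def default_chamber():
    return ChamberSpec()


@pytest.fixture
def default_animal():
    return AnimalRecord(
        animal_id="a1",
        species="J. edwardsii",
        sex="m",
        body_mass_kg=1.12,
        carapace_length_cm=12.0,
        acclimation_temp_c=14.0,
        experimental_temp_c=14.0,
        body_volume_l=1.0,
    )


@pytest.fixture(scope="session")
def synthetic_series():
    """One full study-like trial run through simulation and extraction."""
    truth = SimulationTruth(seed=42)
    chamber = ChamberSpec()
    traj = simulate_mo2_trajectory(
        truth, chamber.trial_duration_h, chamber.sample_interval_s / 3600.0
    )
    trace = synthesize_trace(traj, chamber, truth)
    animal = AnimalRecord(
        animal_id="a1",
        species="J. edwardsii",
        sex="m",
        body_mass_kg=chamber.body_mass_kg,
        carapace_length_cm=12.0,
        acclimation_temp_c=14.0,
        experimental_temp_c=14.0,
        body_volume_l=chamber.body_volume_l,
    )
    bg_rate = truth.background_rate(chamber.body_mass_kg)
    series = extract_mo2(
        trace,
        chamber_volume_l=chamber.chamber_volume_l,
        animal=animal,
        background=BackgroundRecord(bg_rate, bg_rate),
        saturation_concentration_mg_l=chamber.saturation_concentration_mg_l,
    )
    return truth, chamber, series


def series_from_values(times_h, mo2_values) -> MO2Series:
    """Build a minimal accepted-only MO2Series from explicit values."""
    times_h = np.asarray(times_h, dtype=float)
    mo2_values = np.asarray(mo2_values, dtype=float)
    data = pd.DataFrame(
        {
            "cycle_index": np.arange(len(times_h)),
            "cycle_time_h": times_h,
            "slope_mg_l_h": np.nan,
            "r2": 1.0,
            "n_samples": 36,
            "min_saturation_pct": 100.0,
            "background_rate_mg_h": 0.0,
            "mo2": mo2_values,
            "flags": "",
            "accepted": True,
        }
    )
    return MO2Series(data=data, effective_volume_l=9.0, body_mass_kg=1.0)
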