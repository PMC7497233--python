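import numpy as np
import pytest

from isocue.isotope import IsotopeValue, WaterPool
from isocue.kinetics import EquilibrationModel
from isocue.synthetic import SyntheticTruth, TwoPoolSystem, simulate_birch_experiment


@pytest.fixture
def reference_model() -> EquilibrationModel:
    """A mid-range equilibration curve: 0.2 → 20 atom% at b = 0.3 h⁻¹."""
    return EquilibrationModel(at_in=0.2, at_24=20.0, b=0.3, horizon_h=24.0)


@pytest.fixture
def equal_pool_system() -> TwoPoolSystem:
    """Two equal 0.01 mol pools exchanging at F = 0.0015 mol h⁻¹ (b = 0.3 h⁻¹)."""
    return TwoPoolSystem(
        soil_pool=WaterPool(0.01, IsotopeValue(0.2)),
        external_pool=WaterPool(0.01, IsotopeValue(39.8)),
        exchange_rate_f=0.0015,
    )


@pytest.fixture(scope="session")
def noiseless_simulation():
    """A full noiseless Birch experiment with default multipliers."""
    truth = SyntheticTruth(
        noise_sd_at=0.0, noise_sd_at_dna=0.0, noise_sd_ppm=0.0, seed=7
    )
    return truth, simulate_birch_experiment(truth)


def pipeline_cue(sim, excess_mode: bool = False):
    """Run the full fit → lookup → fluxes pipeline on a simulation bundle."""
    from isocue.cue import compute_fluxes
    from isocue.io import soil_water_lookup_from_report
    from isocue.kinetics import fit_kinetics_dataset

    soil = sim.kinetics[sim.kinetics["pool"] == "soil"]
    report = fit_kinetics_dataset(
        soil, group_cols=("soil_id", "moisture", "treatment")
    )
    lookup = soil_water_lookup_from_report(report)
    return compute_fluxes(
        sim.endpoints, sim.soils, soil_water_at=lookup, excess_mode=excess_mode
    )
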