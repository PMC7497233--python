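"""A full synthetic vapor-vs-liquid experiment and its method comparison.

Generates a three-soil, dry/moist, vapor/liquid/control experiment with a
known rewetting (Birch) stimulation, runs the complete pipeline on the
generated tables and compares the two labeling methods: on dry soil, direct
liquid addition inflates respiration and growth and depresses apparent CUE.
"""

from isocue import SyntheticTruth, compare_methods, compute_fluxes, simulate_birch_experiment
from isocue.io import soil_water_lookup_from_report
from isocue.kinetics import fit_kinetics_dataset

truth = SyntheticTruth(rewet_resp_mult=4.5, rewet_growth_mult=2.8, seed=42)
sim = simulate_birch_experiment(truth)
print(f"true CUE (unstimulated): {truth.true_cue:.3f}")
print(f"{len(sim.endpoints)} endpoint vials, {len(sim.kinetics)} kinetics observations")

# 1) fit vapor-arm equilibration kinetics per soil x moisture
report = fit_kinetics_dataset(
    sim.kinetics[sim.kinetics["pool"] == "soil"],
    group_cols=("soil_id", "moisture", "treatment"),
    liquid_addition_at=truth.target_label_at,
)
print("\nfitted kinetics (vapor arms):")
print(report[["soil_id", "moisture", "b", "at_24", "time_average"]].to_string(index=False))

# 2) endpoint calculus for every vial
fluxes = compute_fluxes(
    sim.endpoints, sim.soils, soil_water_at=soil_water_lookup_from_report(report)
)

# 3) method comparison on the dry soils
for soil_id in ("fast", "medium", "slow"):
    dry = fluxes[(fluxes["moisture"] == "dry") & (fluxes["soil_id"] == soil_id)]
    table = compare_methods(
        dry[dry["treatment"] == "liquid_high"],
        dry[dry["treatment"] == "vapor"],
        label_a="liquid",
        label_b="vapor",
    ).set_index("variable")
    print(
        f"\n{soil_id} soil, dry — liquid addition vs vapor equilibration:\n"
        f"  respiration {table.loc['respiration', 'pct_difference']:+.0f}%, "
        f"growth {table.loc['growth', 'pct_difference']:+.0f}%, "
        f"CUE {table.loc['cue', 'pct_difference']:+.1f}%"
    )
# The rewetting burst inflates respiration more than growth, so the
# liquid-addition method systematically underestimates CUE on dry soil.
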