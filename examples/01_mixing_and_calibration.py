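"""Mix labeled and unlabeled water pools, and correct extraction fractionation.

Builds the mole-balance mixture of a dry soil's native water with an ¹⁸O
label addition, then fits a linear calibration from cryodistillation
standards and corrects a measured value with it.
"""

from isocue import (
    IsotopeValue,
    WaterPool,
    apply_calibration,
    fit_calibration,
    mix_pools,
    volume_to_o_moles,
)

# a dry soil holds ~19 mg water at natural abundance; we add 95 µl of
# 24 atom% label — what enrichment does the combined soil water reach?
soil_o = volume_to_o_moles(19.0, IsotopeValue(0.2005), temperature_c=25.0)
label_o = volume_to_o_moles(95.0, IsotopeValue(24.0), temperature_c=25.0)
mixed = mix_pools(
    [WaterPool(soil_o, IsotopeValue(0.2005)), WaterPool(label_o, IsotopeValue(24.0))]
)
print(f"soil water: {soil_o * 1e3:.3f} mmol O, label: {label_o * 1e3:.3f} mmol O")
print(f"mixed soil-water enrichment: {mixed.atom_percent:.3f} atom% 18O")
# -> ~19.9 atom%: the label dominates because the dry soil holds little water

# five waters of known enrichment carried through the same cryodistillation
# as the samples reveal the extraction fractionation
known = [1.0, 5.0, 10.0, 20.0, 40.0]
measured = [1.35, 5.28, 10.15, 19.95, 39.50]  # slight damping + offset
curve = fit_calibration(known, measured)
print(
    f"calibration: measured = {curve.slope:.4f} x known + {curve.intercept:.3f} "
    f"(residual sd {curve.residual_sd:.3f} atom%)"
)
corrected = apply_calibration(curve, 10.00)
print(f"a sample measured at 10.000 atom% corrects to {corrected.atom_percent:.3f} atom%")
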