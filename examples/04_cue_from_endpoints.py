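"""Respiration, growth and CUE for a single vial from endpoint measurements.

Walks the full endpoint calculus: headspace CO2 -> respired C, DNA 18O
excess -> DNA produced -> biomass C produced, then uptake and CUE.
"""

from isocue import (
    EndpointMeasurement,
    SoilBiomassInfo,
    VialConfig,
    cue,
    dna_produced,
    growth_c,
    respiration_from_headspace,
)

vial = VialConfig(headspace_ml=25.8, soil_fresh_g=0.4, gwc=0.05)
m = EndpointMeasurement(
    co2_ppm_t0=420.0,
    co2_ppm_t24=660.0,          # 240 ppm CO2 accumulated over 24 h
    o_dna_extr=2.68,            # µg O in the DNA extract
    at_dna_label=0.435,         # labeled DNA, atom% 18O
    at_dna_na=0.2005,           # unlabeled control DNA
    at_soil_water=17.25,        # time-averaged soil water (vapor method)
)
soil = SoilBiomassInfo(mbc_ug_per_g=450.0, dna_ug_per_g=22.5)  # f_DNA = 20

resp, resp_flags = respiration_from_headspace(m, vial)
dna_ug, dna_flags = dna_produced(m)
growth = growth_c(dna_ug, soil, vial.dry_mass_g)
result = cue(growth, resp, resp_flags + dna_flags)

print(f"dry soil mass: {vial.dry_mass_g:.4f} g, headspace: {vial.headspace_moles * 1e3:.3f} mmol gas")
print(f"respiration: {result.respiration:.2f} ug C/g dry soil per 24 h")
print(f"DNA produced: {dna_ug:.4f} ug  ->  growth: {result.growth:.2f} ug C/g (x f_DNA={soil.f_dna:.0f})")
print(f"uptake: {result.uptake:.2f} ug C/g, CUE: {result.cue:.3f}")
# CUE is the fraction of assimilated C retained in biomass; ~0.2-0.6 is the
# usual soil range, higher under dry (respiration-suppressing) conditions.
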