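"""Endpoint calculus: respiration, ¹⁸O-DNA growth, uptake and CUE.

Respiration comes from the headspace CO₂ accumulation over the incubation
(ideal-gas conversion of the ppm change). Growth comes from the ¹⁸O excess
in genomic DNA: the amount of DNA produced during the incubation is

    DNA_produced = O_DNAextr · (at%_DNA,L − at%_DNA,n.a.) / at%_soilwater · 100/31.21

where 31.21% is the average oxygen content of DNA by mass; DNA produced is
converted to biomass carbon with the soil-specific biomass-C : DNA ratio
f_DNA. Carbon uptake is growth + respiration and CUE = growth / uptake.

For the vapor-equilibration method ``at%_soilwater`` must be the
*time-averaged* soil-water enrichment from the kinetics module, because the
soil water is only gradually labeled; for direct liquid addition it is the
constant mixing enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from isocue.isotope import NATURAL_ABUNDANCE_AT

__all__ = [
    "DNA_OXYGEN_CONTENT_PCT",
    "R_GAS",
    "VialConfig",
    "EndpointMeasurement",
    "SoilBiomassInfo",
    "FluxResult",
    "respiration_from_headspace",
    "dna_produced",
    "growth_c",
    "cue",
    "compare_methods",
    "compute_fluxes",
]

#: Average oxygen content of DNA, percent by mass.
DNA_OXYGEN_CONTENT_PCT: float = 31.21

#: Molar gas constant, J mol⁻¹ K⁻¹.
R_GAS: float = 8.31446

#: Atomic mass of carbon, g/mol.
_M_C: float = 12.011


@dataclass(frozen=True)
class VialConfig:
    """Physical setup of one incubation vial.

    Defaults mirror a 400 mg soil aliquot in a 1.2 ml inner vial inside a
    27 ml glass headspace vial (effective gas volume 27 − 1.2 = 25.8 ml; the
    ~0.15 ml soil solid volume is neglected).
    """

    headspace_ml: float = 25.8
    soil_fresh_g: float = 0.4
    gwc: float = 0.05  # g water / g dry soil (dry-mass basis)
    label_volume_ul: float = 107.0
    label_at: float = 20.0
    temperature_c: float = 25.0
    pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        if self.headspace_ml <= 0:
            raise ValueError("headspace volume must be positive")
        if self.soil_fresh_g <= 0:
            raise ValueError("soil mass must be positive")
        if self.gwc < 0:
            raise ValueError("gravimetric water content cannot be negative")

    @property
    def dry_mass_g(self) -> float:
        """Dry soil mass, g: fresh/(1 + gwc) with gwc on a dry-mass basis."""
        return self.soil_fresh_g / (1.0 + self.gwc)

    @property
    def headspace_moles(self) -> float:
        """Total moles of gas in the headspace (ideal gas at T, P)."""
        p_pa = self.pressure_kpa * 1e3
        v_m3 = self.headspace_ml * 1e-6
        return p_pa * v_m3 / (R_GAS * (self.temperature_c + 273.15))


@dataclass(frozen=True)
class EndpointMeasurement:
    """Per-vial endpoint observations feeding the growth/respiration calculus."""

    co2_ppm_t0: float
    co2_ppm_t24: float
    o_dna_extr: float  # µg O in the DNA extract
    at_dna_label: float  # atom% ¹⁸O of labeled DNA
    at_dna_na: float  # atom% ¹⁸O of natural-abundance DNA
    at_soil_water: float  # atom% ¹⁸O of soil water (time-averaged for vapor)
    incubation_h: float = 24.0

    def __post_init__(self) -> None:
        if self.co2_ppm_t0 < 0 or self.co2_ppm_t24 < 0:
            raise ValueError("CO2 concentrations cannot be negative")
        if self.o_dna_extr < 0:
            raise ValueError("DNA-extract oxygen cannot be negative")
        if self.incubation_h <= 0:
            raise ValueError("incubation time must be positive")


@dataclass(frozen=True)
class SoilBiomassInfo:
    """Soil microbial biomass C and DNA stocks, and their ratio f_DNA.

    f_DNA = MBC / DNA converts DNA produced (µg) into biomass C produced
    (µg C). Both stocks are per g dry soil; MBC comes from chloroform
    fumigation extraction, DNA from fluorimetric quantification.
    """

    mbc_ug_per_g: float
    dna_ug_per_g: float

    def __post_init__(self) -> None:
        if self.mbc_ug_per_g <= 0 or self.dna_ug_per_g <= 0:
            raise ValueError("biomass C and DNA stocks must be positive")

    @property
    def f_dna(self) -> float:
        return self.mbc_ug_per_g / self.dna_ug_per_g


@dataclass(frozen=True)
class FluxResult:
    """Per-vial C fluxes over the incubation (µg C g⁻¹ dry soil) and CUE."""

    respiration: float
    growth: float
    uptake: float
    cue: float | None
    flags: tuple[str, ...] = ()


def respiration_from_headspace(m: EndpointMeasurement, v: VialConfig) -> tuple[float, tuple[str, ...]]:
    """Respired C over the incubation, µg C per g dry soil.

    Δppm(CO₂) × headspace moles × 12.011 g/mol C, per g dry soil. A negative
    Δppm is allowed (it can arise from measurement noise) but flagged.
    """
    flags: tuple[str, ...] = ()
    delta_ppm = m.co2_ppm_t24 - m.co2_ppm_t0
    if delta_ppm < 0:
        flags = ("negative_co2_accumulation",)
    co2_mol = delta_ppm * 1e-6 * v.headspace_moles
    ug_c = co2_mol * _M_C * 1e6
    return ug_c / v.dry_mass_g, flags


def dna_produced(
    m: EndpointMeasurement, excess_mode: bool = False,
    natural_abundance: float = NATURAL_ABUNDANCE_AT,
) -> tuple[float, tuple[str, ...]]:
    """DNA produced during the incubation, µg.

    O_DNAextr × (label excess / soil-water atom%) × 100/31.21. The
    soil-water term is used as raw atom% by default, exactly as the growth
    calculus is conventionally written; ``excess_mode=True`` subtracts the
    natural-abundance baseline from it for sensitivity analysis.

    A negative label excess (labeled below unlabeled DNA) is clipped to zero
    and flagged — negative growth is unphysical but the event must stay
    visible for QC.
    """
    at_sw = m.at_soil_water - (natural_abundance if excess_mode else 0.0)
    if at_sw <= 0:
        raise ValueError(f"soil-water enrichment must be positive, got {at_sw}")
    excess = m.at_dna_label - m.at_dna_na
    if excess < 0:
        return 0.0, ("negative_dna_enrichment",)
    return (
        m.o_dna_extr * (excess / at_sw) * 100.0 / DNA_OXYGEN_CONTENT_PCT,
        (),
    )


def growth_c(dna_ug: float, info: SoilBiomassInfo, dry_mass_g: float) -> float:
    """Biomass C produced, µg C per g dry soil: DNA produced × f_DNA / dry mass."""
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    return dna_ug * info.f_dna / dry_mass_g


def cue(
    growth: float, respiration: float, flags: Sequence[str] = ()
) -> FluxResult:
    """Carbon uptake and use efficiency from growth and respiration fluxes.

    uptake = growth + respiration; CUE = growth/uptake. When both fluxes are
    zero CUE is undefined and reported as missing with a flag.
    """
    if growth < 0 or respiration < 0:
        raise ValueError("growth and respiration must be non-negative")
    all_flags = tuple(flags)
    uptake = growth + respiration
    if uptake == 0:
        return FluxResult(respiration, growth, uptake, None, all_flags + ("undefined_cue",))
    return FluxResult(respiration, growth, uptake, growth / uptake, all_flags)


_COMPARE_VARS = ("respiration", "growth", "uptake", "cue")


def compare_methods(
    results_a: Sequence[FluxResult] | pd.DataFrame,
    results_b: Sequence[FluxResult] | pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
) -> pd.DataFrame:
    """Group-mean comparison of two sets of flux results (a relative to b).

    Returns one row per variable with both group means, the ratio
    mean_a/mean_b and the percent difference 100·(mean_a − mean_b)/mean_b.
    No inferential statistics are computed.
    """

    def _frame(res) -> pd.DataFrame:
        if isinstance(res, pd.DataFrame):
            return res
        return pd.DataFrame(
            [
                {
                    "respiration": r.respiration,
                    "growth": r.growth,
                    "uptake": r.uptake,
                    "cue": r.cue,
                }
                for r in res
            ]
        )

    fa, fb = _frame(results_a), _frame(results_b)
    if fa.empty or fb.empty:
        raise ValueError("both groups must be non-empty")
    rows = []
    for var in _COMPARE_VARS:
        mean_a = float(fa[var].dropna().mean())
        mean_b = float(fb[var].dropna().mean())
        if mean_b == 0:
            raise ValueError(f"zero denominator mean for {var}")
        rows.append(
            {
                "variable": var,
                f"mean_{label_a}": mean_a,
                f"mean_{label_b}": mean_b,
                "ratio": mean_a / mean_b,
                "pct_difference": 100.0 * (mean_a - mean_b) / mean_b,
            }
        )
    return pd.DataFrame(rows)


def compute_fluxes(
    endpoints: pd.DataFrame,
    soils: pd.DataFrame,
    soil_water_at: dict | None = None,
    vial: VialConfig | None = None,
    excess_mode: bool = False,
    natural_abundance: float = NATURAL_ABUNDANCE_AT,
) -> pd.DataFrame:
    """Per-vial flux table from endpoint and soil tables.

    Parameters
    ----------
    endpoints
        One row per vial; columns ``vial_id, treatment, moisture, soil_id,
        co2_ppm_t0, co2_ppm_t24, o_dna_ug, at_dna_label, at_dna_na,
        incubation_h`` and optionally ``at_soil_water`` (liquid arms).
    soils
        Per-soil table with ``soil_id, mbc_ug_per_g, dna_ug_per_g, gwc``.
    soil_water_at
        Mapping ``(soil_id, moisture) -> atom%`` supplying the time-averaged
        soil-water enrichment for vapor-arm vials (from the kinetics fit
        report). Rows whose enrichment cannot be resolved are flagged, not
        dropped.
    vial
        Common vial geometry; per-row ``gwc`` from the soils table overrides
        the default water content.

    Returns
    -------
    pandas.DataFrame
        One row per input vial: respiration, growth, uptake, cue (per
        incubation and per hour) plus semicolon-joined QC flags.
    """
    vial = vial or VialConfig()
    soil_map = soils.set_index("soil_id").to_dict(orient="index")
    rows = []
    for _, r in endpoints.iterrows():
        flags: list[str] = []
        soil = soil_map.get(r["soil_id"])
        if soil is None:
            raise ValueError(f"vial {r['vial_id']}: unknown soil_id {r['soil_id']}")
        gwc = float(soil.get("gwc", vial.gwc))
        if str(r.get("moisture", "")) == "moist" and "gwc_moist" in soil:
            gwc = float(soil["gwc_moist"])
        vconf = VialConfig(
            headspace_ml=vial.headspace_ml,
            soil_fresh_g=vial.soil_fresh_g,
            gwc=gwc,
            label_volume_ul=vial.label_volume_ul,
            label_at=vial.label_at,
            temperature_c=vial.temperature_c,
            pressure_kpa=vial.pressure_kpa,
        )
        treatment = str(r["treatment"])

        at_sw = r.get("at_soil_water")
        if at_sw is None or (isinstance(at_sw, float) and np.isnan(at_sw)):
            key = (r["soil_id"], r.get("moisture"))
            at_sw = (soil_water_at or {}).get(key)

        is_control = treatment == "control"
        has_dna = not is_control and np.isfinite(float(r.get("o_dna_ug", np.nan)))

        m = EndpointMeasurement(
            co2_ppm_t0=float(r["co2_ppm_t0"]),
            co2_ppm_t24=float(r["co2_ppm_t24"]),
            o_dna_extr=float(r["o_dna_ug"]) if has_dna else 0.0,
            at_dna_label=float(r["at_dna_label"]) if has_dna else 0.0,
            at_dna_na=float(r["at_dna_na"]) if has_dna else 0.0,
            at_soil_water=float(at_sw) if at_sw is not None and np.isfinite(float(at_sw)) else np.nan,
            incubation_h=float(r.get("incubation_h", 24.0)),
        )
        resp, resp_flags = respiration_from_headspace(m, vconf)
        flags.extend(resp_flags)

        growth = np.nan
        cue_val: float | None = None
        uptake = np.nan
        if is_control or not has_dna:
            flags.append("no_dna_data" if not is_control else "control_respiration_only")
        elif not np.isfinite(m.at_soil_water):
            flags.append("missing_soil_water_enrichment")
        else:
            dna_ug, dna_flags = dna_produced(
                m, excess_mode=excess_mode, natural_abundance=natural_abundance
            )
            flags.extend(dna_flags)
            info = SoilBiomassInfo(
                mbc_ug_per_g=float(soil["mbc_ug_per_g"]),
                dna_ug_per_g=float(soil["dna_ug_per_g"]),
            )
            growth = growth_c(dna_ug, info, vconf.dry_mass_g)
            res = cue(growth, max(resp, 0.0), flags)
            uptake, cue_val, flags = res.uptake, res.cue, list(res.flags)

        rows.append(
            {
                "vial_id": r["vial_id"],
                "treatment": treatment,
                "moisture": r.get("moisture"),
                "soil_id": r["soil_id"],
                "respiration": resp,
                "growth": growth,
                "uptake": uptake,
                "cue": cue_val if cue_val is not None else np.nan,
                "respiration_per_h": resp / m.incubation_h,
                "growth_per_h": growth / m.incubation_h,
                "at_soil_water_used": m.at_soil_water,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
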