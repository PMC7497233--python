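"""Ground-truth generator: two-pool isotope exchange and a Birch-effect experiment.

Physical picture
----------------
A sealed headspace vial holds two liquid water pools that never touch: the
soil water and an external ¹⁸O-labeled droplet at the bottom of the vial.
Oxygen isotopes redistribute between them through the vapor phase
(evaporation/condensation). Treating the vapor as a massless conduit, the
atom fractions obey first-order exchange

    dx_s/dt = (F/m_s)·(x_e − x_s),   dx_e/dt = (F/m_e)·(x_s − x_e)

with F the exchange flux (mol O h⁻¹) and m_s, m_e the pool sizes (mol O).
Both pools relax exponentially toward the mole-weighted equilibrium
x_eq = (m_s·x_s0 + m_e·x_e0)/(m_s + m_e) with the shared rate

    b = F·(1/m_s + 1/m_e),

which is exactly the soil-specific coefficient of the equilibration model
in :mod:`isocue.kinetics`. Total O and total ¹⁸O are conserved.

Experiment emulator
-------------------
:func:`simulate_birch_experiment` produces every table the pipeline
consumes (kinetics, endpoints, soils) plus a ground-truth record, for a
soils × moisture × treatment × replicates design. Liquid-addition arms on
dry soil get their respiration and growth inflated by configurable
rewetting multipliers (the Birch effect); vapor arms do not. DNA label
enrichments are synthesized by inverting the growth calculus with the exact
time-averaged soil-water enrichment, so noiseless data round-trip through
the pipeline to the true fluxes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from isocue.cue import DNA_OXYGEN_CONTENT_PCT, VialConfig
from isocue.isotope import NATURAL_ABUNDANCE_AT, IsotopeValue, WaterPool, water_density_g_per_ml

__all__ = [
    "TwoPoolSystem",
    "SyntheticTruth",
    "SoilPreset",
    "SOIL_PRESETS",
    "simulate_two_pool",
    "two_pool_numeric",
    "simulate_birch_experiment",
    "write_simulation",
]


@dataclass(frozen=True)
class TwoPoolSystem:
    """A closed pair of liquid water pools exchanging oxygen via vapor."""

    soil_pool: WaterPool
    external_pool: WaterPool
    exchange_rate_f: float  # mol O h⁻¹

    def __post_init__(self) -> None:
        if not (np.isfinite(self.exchange_rate_f) and self.exchange_rate_f >= 0):
            raise ValueError("exchange flux F must be non-negative and finite")

    @property
    def b(self) -> float:
        """Shared relaxation rate, h⁻¹: F·(1/m_s + 1/m_e)."""
        return self.exchange_rate_f * (
            1.0 / self.soil_pool.o_moles + 1.0 / self.external_pool.o_moles
        )

    @property
    def x_eq(self) -> float:
        """Mole-weighted equilibrium ¹⁸O atom fraction of both pools."""
        m_s, m_e = self.soil_pool.o_moles, self.external_pool.o_moles
        return (
            m_s * self.soil_pool.enrichment.atom_fraction
            + m_e * self.external_pool.enrichment.atom_fraction
        ) / (m_s + m_e)

    def analytic(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Exact atom fractions (x_soil, x_external) at times ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        decay = np.exp(-self.b * t)
        x_s0 = self.soil_pool.enrichment.atom_fraction
        x_e0 = self.external_pool.enrichment.atom_fraction
        return (
            self.x_eq + (x_s0 - self.x_eq) * decay,
            self.x_eq + (x_e0 - self.x_eq) * decay,
        )


def two_pool_numeric(system: TwoPoolSystem, times: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Numerically integrated atom fractions, for cross-checking the analytic form.

    Stiff-safe adaptive integration at tight tolerances; agrees with
    :meth:`TwoPoolSystem.analytic` to ≲1e−10 relative.
    """
    times = np.asarray(times, dtype=float)
    m_s, m_e = system.soil_pool.o_moles, system.external_pool.o_moles
    f = system.exchange_rate_f

    def rhs(_t, x):
        d = x[1] - x[0]
        return [f / m_s * d, -f / m_e * d]

    x0 = [
        system.soil_pool.enrichment.atom_fraction,
        system.external_pool.enrichment.atom_fraction,
    ]
    t_span = (0.0, max(float(times.max()), 1e-9))
    sol = solve_ivp(
        rhs, t_span, x0, t_eval=np.clip(times, 0, None),
        method="LSODA", rtol=1e-12, atol=1e-15,
    )
    if not sol.success:
        raise RuntimeError(f"two-pool integration failed: {sol.message}")
    return sol.y[0], sol.y[1]


def simulate_two_pool(
    system: TwoPoolSystem,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    replicates: int = 1,
) -> pd.DataFrame:
    """Noisy observations of both pools of a closed two-pool exchange.

    Returns a long-format kinetics table with columns ``pool`` (soil |
    external), ``time_h``, ``replicate``, ``atom_pct`` (observed) and
    ``atom_pct_true`` (analytic solution). Gaussian noise with the given sd
    (atom%) is added independently per observation and clipped to [0, 100].
    """
    times = np.asarray(times, dtype=float)
    if times.size < 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a non-empty sorted sequence")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_s, x_e = system.analytic(times)
    frames = []
    for pool, x in (("soil", x_s), ("external", x_e)):
        for rep in range(1, replicates + 1):
            obs = x * 100.0
            if noise_sd > 0:
                obs = np.clip(obs + rng.normal(0.0, noise_sd, size=obs.shape), 0.0, 100.0)
            frames.append(
                pd.DataFrame(
                    {
                        "pool": pool,
                        "time_h": times,
                        "replicate": rep,
                        "atom_pct": obs,
                        "atom_pct_true": x * 100.0,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SoilPreset:
    """One synthetic soil: exchange kinetics and biomass stocks."""

    b: float  # h⁻¹, vapor-equilibration rate coefficient
    whc: float  # g water / g dry soil at water holding capacity
    mbc_ug_per_g: float  # microbial biomass C, µg C / g dry soil
    dna_ug_per_g: float  # DNA stock, µg / g dry soil


#: Three default soils ("fast", "medium", "slow" equilibration) spanning the
#: range of rate coefficients seen across contrasting soil types.
SOIL_PRESETS: dict[str, SoilPreset] = {
    "fast": SoilPreset(b=0.6, whc=0.55, mbc_ug_per_g=625.0, dna_ug_per_g=25.0),
    "medium": SoilPreset(b=0.3, whc=0.50, mbc_ug_per_g=450.0, dna_ug_per_g=22.5),
    "slow": SoilPreset(b=0.12, whc=0.45, mbc_ug_per_g=300.0, dna_ug_per_g=20.0),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a synthetic Birch-effect experiment.

    ``true_growth`` and ``true_respiration`` are the *unstimulated dry-soil*
    fluxes (µg C g⁻¹ dry soil per 24 h incubation); moist soils scale both
    by ``moist_activity_mult`` (leaving CUE unchanged). Liquid-addition arms
    on dry soil are inflated by the rewetting multipliers — the Birch
    effect; the low-volume liquid arm receives a damped stimulation
    (``low_addition_frac`` of the full multiplier excess).

    Water atom% observations carry ``noise_sd_at``; DNA ¹⁸O measurements
    carry the much smaller ``noise_sd_at_dna`` (TC/EA-IRMS precision);
    headspace CO₂ readings carry ``noise_sd_ppm``.
    """

    b_true: float | None = None  # None -> per-soil preset values
    true_growth: float = 6.0
    true_respiration: float = 8.0
    rewet_resp_mult: float = 4.5
    rewet_growth_mult: float = 2.8
    moist_activity_mult: float = 2.5
    low_addition_frac: float = 0.6
    noise_sd_at: float = 0.3
    noise_sd_at_dna: float = 0.01
    noise_sd_ppm: float = 5.0
    seed: int = 0
    target_label_at: float = 20.0
    ambient_co2_ppm: float = 420.0
    growth_mode: str = "uniform"  # or "late_burst"
    burst_window_h: float = 6.0

    def __post_init__(self) -> None:
        if self.true_growth < 0 or self.true_respiration < 0:
            raise ValueError("true fluxes must be non-negative")
        if self.rewet_resp_mult < 1 or self.rewet_growth_mult < 1:
            raise ValueError("rewetting multipliers must be ≥ 1")
        if min(self.noise_sd_at, self.noise_sd_at_dna, self.noise_sd_ppm) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.growth_mode not in ("uniform", "late_burst"):
            raise ValueError(f"unknown growth_mode {self.growth_mode!r}")

    @property
    def true_cue(self) -> float:
        return self.true_growth / (self.true_growth + self.true_respiration)


_M_H2O_16O = 18.015


def _o_moles_from_mass(mass_g: float, atom_fraction: float) -> float:
    return mass_g / (_M_H2O_16O + 2.0 * atom_fraction)


def _label_for_target(m_soil: float, x_soil: float, add_mass_g: float, x_target: float) -> tuple[float, float]:
    """Label atom fraction (and its O moles) so the mixture hits ``x_target``.

    The label's molar mass depends on its own enrichment, so solve the
    mixing balance by fixed-point iteration (converges in a few steps).
    """
    x_l = x_target
    for _ in range(25):
        m_l = _o_moles_from_mass(add_mass_g, x_l)
        x_new = (x_target * (m_soil + m_l) - m_soil * x_soil) / m_l
        if abs(x_new - x_l) < 1e-15:
            x_l = x_new
            break
        x_l = x_new
    if not 0.0 < x_l <= 1.0:
        raise ValueError(
            f"no physical label enrichment reaches {x_target:.3f} atom fraction "
            "with this water addition"
        )
    return x_l, _o_moles_from_mass(add_mass_g, x_l)


def _windowed_average_at(at_in, at_24, b, t0, t1):
    """Mean of the equilibration curve (atom%) over [t0, t1]."""
    span = t1 - t0
    factor = (np.exp(-b * t0) - np.exp(-b * t1)) / (b * span)
    return at_24 + (at_in - at_24) * factor


def _delta_ppm_for_respiration(resp_ug_per_g: float, vial: VialConfig) -> float:
    """Headspace ppm rise that the stated respiration produces (ideal gas)."""
    ug_c = resp_ug_per_g * vial.dry_mass_g
    mol_co2 = ug_c * 1e-6 / 12.011
    return mol_co2 / vial.headspace_moles * 1e6


@dataclass
class BirchSimulation:
    """Output bundle of :func:`simulate_birch_experiment`."""

    kinetics: pd.DataFrame
    endpoints: pd.DataFrame
    soils: pd.DataFrame
    truth: dict


def simulate_birch_experiment(
    truth: SyntheticTruth,
    soils: Mapping[str, SoilPreset] | Sequence[str] = ("fast", "medium", "slow"),
    moistures: Sequence[str] = ("dry", "moist"),
    treatments: Sequence[str] = ("vapor", "liquid_high", "liquid_low", "control"),
    replicates: int = 3,
    soil_timepoints: Sequence[float] = (2.0, 4.0, 8.0, 16.0, 24.0),
    external_timepoints: Sequence[float] = (2.0, 4.0, 8.0, 24.0),
    incubation_h: float = 24.0,
    vial: VialConfig | None = None,
) -> BirchSimulation:
    """Emulate a full vapor-vs-liquid ¹⁸O labeling experiment with known truth.

    For every soil × moisture combination the soil water and the external
    label droplet form a closed two-pool system whose equilibrium is the
    target labeling enrichment (~20 atom%); vapor arms observe its kinetics
    and their DNA integrates the *time-averaged* enrichment, while liquid
    arms are labeled instantly at the mixing enrichment. On dry soils the
    liquid arms' respiration and growth are inflated by the rewetting
    multipliers. A no-water control arm contributes respiration only.

    Returns
    -------
    BirchSimulation
        ``kinetics`` (vapor-arm soil and external pool series),
        ``endpoints`` (one row per vial), ``soils`` (per-soil stocks) and a
        ``truth`` record with the global parameters and per-vial true fluxes.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    known = set(SOIL_PRESETS)
    if not isinstance(soils, Mapping):
        bad = [s for s in soils if s not in known]
        if bad:
            raise ValueError(f"unknown soil preset(s) {bad}; choose from {sorted(known)}")
        soils = {name: SOIL_PRESETS[name] for name in soils}
    allowed_treat = {"vapor", "liquid_high", "liquid_low", "control"}
    if not set(treatments) <= allowed_treat:
        raise ValueError(f"unknown treatment(s) {set(treatments) - allowed_treat}")
    if not set(moistures) <= {"dry", "moist"}:
        raise ValueError("moisture levels must be 'dry' and/or 'moist'")

    rng = np.random.default_rng(truth.seed)
    base_vial = vial or VialConfig()
    x_na = NATURAL_ABUNDANCE_AT / 100.0
    x_target = truth.target_label_at / 100.0

    kin_rows, end_rows, soil_rows, vial_truth = [], [], [], []
    soils_meta = {}

    for soil_id, preset in soils.items():
        b_soil = truth.b_true if truth.b_true is not None else preset.b
        gwc = {"dry": 0.05, "moist": round(0.35 * preset.whc, 4)}
        soil_rows.append(
            {
                "soil_id": soil_id,
                "mbc_ug_per_g": preset.mbc_ug_per_g,
                "dna_ug_per_g": preset.dna_ug_per_g,
                "gwc": gwc["dry"],
                "gwc_moist": gwc["moist"],
                "whc": preset.whc,
            }
        )
        soils_meta[soil_id] = {"b_true": b_soil, "f_dna": preset.mbc_ug_per_g / preset.dna_ug_per_g}

        for moisture in moistures:
            vconf = VialConfig(
                headspace_ml=base_vial.headspace_ml,
                soil_fresh_g=base_vial.soil_fresh_g,
                gwc=gwc[moisture],
                temperature_c=base_vial.temperature_c,
                pressure_kpa=base_vial.pressure_kpa,
            )
            dry_mass = vconf.dry_mass_g
            soil_water_g = gwc[moisture] * dry_mass
            m_s = _o_moles_from_mass(soil_water_g, x_na)
            # full addition brings the soil to 60% WHC; label enrichment is
            # chosen so the mixed (or equilibrated) soil water hits the target
            add_g = max((0.6 * preset.whc - gwc[moisture]) * dry_mass, 0.01)
            x_label, m_e = _label_for_target(m_s, x_na, add_g, x_target)
            density = water_density_g_per_ml(vconf.temperature_c)
            add_ul = add_g / density * 1e3

            system = TwoPoolSystem(
                soil_pool=WaterPool(m_s, IsotopeValue.from_fraction(x_na)),
                external_pool=WaterPool(m_e, IsotopeValue.from_fraction(x_label)),
                exchange_rate_f=b_soil / (1.0 / m_s + 1.0 / m_e),
            )
            at_in = x_na * 100.0
            at_eq = system.x_eq * 100.0

            # low-volume addition: 30 µl of more enriched water, same target
            x_label_low, m_e_low = _label_for_target(
                m_s, x_na, 30e-3 * density, x_target
            )

            # --- kinetics tables (vapor arms only; liquid labeling is instant)
            if "vapor" in treatments:
                for pool, tpts in (("soil", soil_timepoints), ("external", external_timepoints)):
                    x_s, x_e = system.analytic(np.asarray(tpts, dtype=float))
                    true_at = (x_s if pool == "soil" else x_e) * 100.0
                    for rep in range(1, replicates + 1):
                        obs = true_at.copy()
                        if truth.noise_sd_at > 0:
                            obs = np.clip(
                                obs + rng.normal(0, truth.noise_sd_at, obs.shape), 0, 100
                            )
                        for t, at_obs in zip(tpts, obs):
                            kin_rows.append(
                                {
                                    "vial_id": f"K_{soil_id}_{moisture}",
                                    "pool": pool,
                                    "time_h": t,
                                    "atom_pct": at_obs,
                                    "replicate": rep,
                                    "batch_id": soil_id,
                                    "soil_id": soil_id,
                                    "moisture": moisture,
                                    "treatment": "vapor",
                                }
                            )

            # --- true time-averaged soil-water enrichment for the vapor arm
            if truth.growth_mode == "late_burst":
                t0 = max(incubation_h - truth.burst_window_h, 0.0)
                at_sw_vapor = _windowed_average_at(at_in, at_eq, b_soil, t0, incubation_h)
            else:
                bT = b_soil * incubation_h
                at_sw_vapor = at_eq + (at_in - at_eq) * (-np.expm1(-bT)) / bT

            # --- endpoint vials
            o_dna = preset.dna_ug_per_g * dry_mass * DNA_OXYGEN_CONTENT_PCT / 100.0
            f_dna = preset.mbc_ug_per_g / preset.dna_ug_per_g
            moist_mult = truth.moist_activity_mult if moisture == "moist" else 1.0

            for treatment in treatments:
                if treatment == "liquid_low" and moisture == "moist":
                    continue  # low-volume addition is a dry-soil arm only
                resp_mult = growth_mult = 1.0
                if moisture == "dry" and treatment == "liquid_high":
                    resp_mult, growth_mult = truth.rewet_resp_mult, truth.rewet_growth_mult
                elif moisture == "dry" and treatment == "liquid_low":
                    resp_mult = 1.0 + truth.low_addition_frac * (truth.rewet_resp_mult - 1.0)
                    growth_mult = 1.0 + truth.low_addition_frac * (truth.rewet_growth_mult - 1.0)

                resp_true = truth.true_respiration * moist_mult * resp_mult
                growth_true = truth.true_growth * moist_mult * growth_mult
                at_sw_true = truth.target_label_at if treatment.startswith("liquid") else at_sw_vapor

                delta_ppm = _delta_ppm_for_respiration(resp_true, vconf)
                dna_prod_true = growth_true * dry_mass / f_dna
                at_excess_true = (
                    dna_prod_true * at_sw_true * DNA_OXYGEN_CONTENT_PCT / (100.0 * o_dna)
                )

                for rep in range(1, replicates + 1):
                    vial_id = f"{soil_id}_{moisture}_{treatment}_r{rep}"
                    e_ppm = (
                        rng.normal(0, truth.noise_sd_ppm, 2)
                        if truth.noise_sd_ppm > 0
                        else np.zeros(2)
                    )
                    row = {
                        "vial_id": vial_id,
                        "treatment": treatment,
                        "moisture": moisture,
                        "soil_id": soil_id,
                        "co2_ppm_t0": truth.ambient_co2_ppm + e_ppm[0],
                        "co2_ppm_t24": truth.ambient_co2_ppm + delta_ppm + e_ppm[1],
                        "o_dna_ug": np.nan,
                        "at_dna_label": np.nan,
                        "at_dna_na": np.nan,
                        "at_soil_water": np.nan,
                        "incubation_h": incubation_h,
                    }
                    if treatment != "control":
                        e_dna = (
                            rng.normal(0, truth.noise_sd_at_dna, 2)
                            if truth.noise_sd_at_dna > 0
                            else np.zeros(2)
                        )
                        row["o_dna_ug"] = o_dna
                        row["at_dna_label"] = NATURAL_ABUNDANCE_AT + at_excess_true + e_dna[0]
                        row["at_dna_na"] = NATURAL_ABUNDANCE_AT + e_dna[1]
                        if treatment.startswith("liquid"):
                            e_sw = (
                                rng.normal(0, truth.noise_sd_at)
                                if truth.noise_sd_at > 0
                                else 0.0
                            )
                            row["at_soil_water"] = at_sw_true + e_sw
                    end_rows.append(row)
                    vial_truth.append(
                        {
                            "vial_id": vial_id,
                            "soil_id": soil_id,
                            "moisture": moisture,
                            "treatment": treatment,
                            "b_true": b_soil,
                            "respiration_true": resp_true,
                            "growth_true": None if treatment == "control" else growth_true,
                            "cue_true": None
                            if treatment == "control"
                            else growth_true / (growth_true + resp_true),
                            "at_soil_water_true": None if treatment == "control" else at_sw_true,
                            "label_volume_ul": 30.0
                            if treatment == "liquid_low"
                            else add_ul,
                            "label_at": (x_label_low if treatment == "liquid_low" else x_label)
                            * 100.0,
                        }
                    )

    return BirchSimulation(
        kinetics=pd.DataFrame(kin_rows),
        endpoints=pd.DataFrame(end_rows),
        soils=pd.DataFrame(soil_rows),
        truth={
            "global": asdict(truth),
            "true_cue": truth.true_cue,
            "soils": soils_meta,
            "vials": vial_truth,
        },
    )


def write_simulation(sim: BirchSimulation, out_dir) -> dict:
    """Write kinetics.csv, endpoints.csv, soils.csv and truth.json to ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("kinetics", sim.kinetics),
        ("endpoints", sim.endpoints),
        ("soils", sim.soils),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = str(p)
    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(sim.truth, fh, indent=1)
    paths["truth"] = str(p)
    return paths
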