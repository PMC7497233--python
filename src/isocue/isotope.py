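"""Isotope units, water-pool mixing mass balance, and extraction calibration.

All internal arithmetic is done in ¹⁸O *atom fraction* (¹⁸O atoms per O atom,
in [0, 1]); atom percent (atom fraction × 100) appears only at the I/O
boundary. Mixing is computed on moles of oxygen, not on water mass, because
at high enrichment (20–99 atom%) the molar mass of water differs appreciably
from that of natural-abundance water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "NATURAL_ABUNDANCE_AT",
    "IsotopeValue",
    "WaterPool",
    "CalibrationCurve",
    "CalibratedValue",
    "mix_pools",
    "volume_to_o_moles",
    "water_density_g_per_ml",
    "fit_calibration",
    "apply_calibration",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
]

#: Natural ¹⁸O abundance of unlabeled water, atom percent (VSMOW-consistent).
#: Overridable wherever a baseline enters a calculation.
NATURAL_ABUNDANCE_AT: float = 0.2005

#: ¹⁸O/¹⁶O isotope ratio of the VSMOW reference water.
R_VSMOW: float = 0.0020052

#: Molar mass of water built entirely from ¹⁶O, g/mol.
_M_H2O_16O: float = 18.015


class OutOfRangeWarning(UserWarning):
    """A calibrated value fell outside the physical atom-percent range."""


@dataclass(frozen=True)
class IsotopeValue:
    """An ¹⁸O enrichment, stored as atom percent (¹⁸O atoms per 100 O atoms)."""

    atom_percent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.atom_percent):
            raise ValueError(f"atom_percent must be finite, got {self.atom_percent}")
        if not 0.0 <= self.atom_percent <= 100.0:
            raise ValueError(
                f"atom_percent must lie in [0, 100], got {self.atom_percent}"
            )

    @property
    def atom_fraction(self) -> float:
        """¹⁸O atoms per O atom, in [0, 1]."""
        return self.atom_percent / 100.0

    @classmethod
    def from_fraction(cls, atom_fraction: float) -> "IsotopeValue":
        return cls(atom_fraction * 100.0)


@dataclass(frozen=True)
class WaterPool:
    """An oxygen reservoir: moles of O plus its ¹⁸O enrichment.

    The pool is the unit of all mixing and exchange mass balance; ¹⁸O moles
    are ``o_moles × atom_fraction``.
    """

    o_moles: float
    enrichment: IsotopeValue

    def __post_init__(self) -> None:
        if not (np.isfinite(self.o_moles) and self.o_moles > 0):
            raise ValueError(f"o_moles must be positive and finite, got {self.o_moles}")

    @property
    def o18_moles(self) -> float:
        return self.o_moles * self.enrichment.atom_fraction


def mix_pools(pools: Sequence[WaterPool] | Iterable[WaterPool]) -> IsotopeValue:
    """Enrichment of the pool obtained by combining ``pools``.

    Mole-weighted mean atom fraction; total ¹⁸O is conserved exactly.

    Parameters
    ----------
    pools
        One or more water pools with positive oxygen content.

    Returns
    -------
    IsotopeValue
        Enrichment of the mixture, atom percent.
    """
    pools = list(pools)
    if not pools:
        raise ValueError("mix_pools requires at least one pool")
    total_o = sum(p.o_moles for p in pools)
    total_o18 = sum(p.o18_moles for p in pools)
    return IsotopeValue.from_fraction(total_o18 / total_o)


# Density of air-free liquid water at 101.325 kPa, g/ml (CRC handbook values).
_DENSITY_T_C = np.array([0.0, 4.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0])
_DENSITY_G_ML = np.array(
    [0.99984, 1.00000, 0.99970, 0.99910, 0.99821, 0.99705, 0.99565, 0.99403, 0.99222]
)


def water_density_g_per_ml(temperature_c: float) -> float:
    """Density of liquid water at ``temperature_c`` (°C), linearly interpolated.

    Valid for 0–40 °C; the enrichment-driven density excess of ¹⁸O water is
    not applied here (it is folded into the molar-mass correction used by
    :func:`volume_to_o_moles`).
    """
    if not 0.0 <= temperature_c <= 40.0:
        raise ValueError(f"temperature {temperature_c} °C outside tabulated 0–40 °C")
    return float(np.interp(temperature_c, _DENSITY_T_C, _DENSITY_G_ML))


def volume_to_o_moles(
    volume_ul: float, enrichment: IsotopeValue, temperature_c: float = 20.0
) -> float:
    """Moles of oxygen in ``volume_ul`` µl of water at a given enrichment.

    Uses the enrichment-dependent mean molar mass of water,
    ``18.015 + 2 × atom_fraction`` g/mol (each ¹⁸O substitution adds ~2 g/mol
    and every water molecule carries one O atom), and the density of water at
    the stated temperature.
    """
    if not (np.isfinite(volume_ul) and volume_ul > 0):
        raise ValueError(f"volume must be positive, got {volume_ul} µl")
    mass_g = volume_ul * 1e-3 * water_density_g_per_ml(temperature_c) * 1e-3
    molar_mass = _M_H2O_16O + 2.0 * enrichment.atom_fraction
    return mass_g / molar_mass * 1e3


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response of measured atom% to known atom% for one extraction batch.

    Fitted from standards of known ¹⁸O content carried through the same
    cryodistillation as the soil samples, to correct for extraction
    fractionation: ``measured = slope × known + intercept``.
    """

    slope: float
    intercept: float
    n_standards: int
    residual_sd: float = 0.0
    offset_only: bool = False

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if self.n_standards < 2:
            raise ValueError("calibration needs at least 2 standards")


class CalibratedValue(NamedTuple):
    """A fractionation-corrected atom% and whether it had to be clipped."""

    atom_percent: float
    out_of_range: bool


def fit_calibration(
    known: Sequence[float],
    measured: Sequence[float],
    offset_only: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares of measured atom% on known atom%.

    Parameters
    ----------
    known, measured
        Equal-length sequences (n ≥ 2) of standard and observed atom%.
        The known values must not all coincide.
    offset_only
        Fix the slope at 1 and fit only an additive offset (for users who
        prefer an offset-only fractionation correction).
    """
    k = np.asarray(known, dtype=float)
    m = np.asarray(measured, dtype=float)
    if k.shape != m.shape or k.ndim != 1:
        raise ValueError("known and measured must be equal-length 1-D sequences")
    if k.size < 2:
        raise ValueError("calibration needs at least 2 standards")
    if np.ptp(k) == 0:
        raise ValueError("known standards are all identical; cannot fit a line")
    if offset_only:
        slope, intercept = 1.0, float(np.mean(m - k))
    else:
        slope, intercept = (float(v) for v in np.polyfit(k, m, 1))
    resid = m - (slope * k + intercept)
    dof = k.size - (1 if offset_only else 2)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        n_standards=int(k.size),
        residual_sd=residual_sd,
        offset_only=offset_only,
    )


def apply_calibration(curve: CalibrationCurve, measured: float) -> CalibratedValue:
    """Invert the calibration: recover the true atom% from a measured one.

    Returns ``(measured − intercept)/slope``, clipped to [0, 100]; a clipped
    result carries ``out_of_range=True`` and raises an
    :class:`OutOfRangeWarning`.
    """
    raw = (measured - curve.intercept) / curve.slope
    if 0.0 <= raw <= 100.0:
        return CalibratedValue(raw, False)
    warnings.warn(
        f"calibrated value {raw:.4g} atom% outside [0, 100]; clipped",
        OutOfRangeWarning,
        stacklevel=2,
    )
    return CalibratedValue(float(np.clip(raw, 0.0, 100.0)), True)


def delta_to_atom_percent(delta_permil: float) -> float:
    """Convert δ¹⁸O (‰ vs VSMOW) to atom percent."""
    ratio = R_VSMOW * (1.0 + delta_permil / 1e3)
    return ratio / (1.0 + ratio) * 100.0


def atom_percent_to_delta(atom_percent: float) -> float:
    """Convert atom percent to δ¹⁸O (‰ vs VSMOW)."""
    x = atom_percent / 100.0
    ratio = x / (1.0 - x)
    return (ratio / R_VSMOW - 1.0) * 1e3
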