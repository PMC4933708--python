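"""Carbonate-system carbon isotope model for microbialite biosignatures.

Predicts the theoretical equilibrium |d13C| of aragonite precipitating from
lake water, given the measured |d13C| of dissolved inorganic carbon (DIC),
pH and temperature, and scores measured thrombolite carbonate against that
prediction.  A positive offset (carbonate heavier than equilibrium) records
preferential 12C drawdown by photoautotrophy; a negative offset records
addition of 12C-rich respired carbon by heterotrophy.

The calculation has three steps:

1. *Speciation*: partition DIC among CO2(aq), HCO3- and CO3(2-) from pH and
   the temperature-dependent apparent dissociation constants of carbonic
   acid (mole fractions 1 : K1/aH : K1*K2/aH**2 with aH = 10**-pH).
2. *Mass balance*: solve
   d_DIC = x_co2aq*d_co2aq + x_hco3*d_hco3 + x_co3*d_co3
   for d_hco3, tying each species delta to d_hco3 through the equilibrium
   enrichment factors at the given temperature (exact multiplicative alpha
   form, alpha = 1 + eps/1000).
3. *Mineral fractionation*: apply the aragonite-bicarbonate enrichment to
   d_hco3 to obtain the equilibrium aragonite value.

All delta values are permil VPDB; enrichment factors eps are permil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "WaterSample",
    "CarbonateSample",
    "SpeciationResult",
    "FractionationSet",
    "EquilibriumPrediction",
    "BiosignatureResult",
    "DEFAULT_FRACTIONATION",
    "carbonic_acid_constants",
    "speciate_dic",
    "hco3_delta_from_dic",
    "equilibrium_aragonite_delta",
    "max_equilibrium_prediction",
    "biosignature_offsets",
    "salinity_from_conductance",
]

T_CELSIUS_MIN = 0.0
T_CELSIUS_MAX = 50.0
PH_MIN = 2.0
PH_MAX = 12.0


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside valid range [{lo}, {hi}]")


@dataclass(frozen=True)
class WaterSample:
    """One water-chemistry measurement (lake or groundwater)."""

    id: str
    source: Literal["lake", "groundwater"]
    delta13c_dic: float
    ph: float
    temperature: float | None = None
    conductance: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("lake", "groundwater"):
            raise ValueError(f"source must be 'lake' or 'groundwater', got {self.source!r}")
        _check_range("ph", self.ph, PH_MIN, PH_MAX)
        if self.temperature is not None:
            _check_range("temperature", self.temperature, T_CELSIUS_MIN, T_CELSIUS_MAX)
        if self.conductance is not None and self.conductance <= 0:
            raise ValueError(f"conductance must be positive, got {self.conductance!r}")


@dataclass(frozen=True)
class CarbonateSample:
    """One carbonate subsample from a core depth interval."""

    id: str
    core: str
    depth_top: float
    depth_bottom: float
    delta13c_caco3: float

    def __post_init__(self) -> None:
        if self.depth_top < 0 or self.depth_bottom < 0:
            raise ValueError("depth interval must be non-negative")
        if not self.depth_top < self.depth_bottom:
            raise ValueError(
                f"depth_top ({self.depth_top}) must be < depth_bottom ({self.depth_bottom})"
            )


@dataclass(frozen=True)
class SpeciationResult:
    """DIC mole fractions and the dissociation constants that produced them."""

    x_co2aq: float
    x_hco3: float
    x_co3: float
    k1: float
    k2: float
    temperature: float
    ph: float

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.x_co2aq, self.x_hco3, self.x_co3])


def _pk1_freshwater(t_kelvin: float) -> float:
    # Plummer & Busenberg (1982) zero-ionic-strength parameterization
    return -(
        -356.3094
        - 0.06091964 * t_kelvin
        + 21834.37 / t_kelvin
        + 126.8339 * math.log10(t_kelvin)
        - 1684915.0 / t_kelvin**2
    )


def _pk2_freshwater(t_kelvin: float) -> float:
    return -(
        -107.8871
        - 0.03252849 * t_kelvin
        + 5151.79 / t_kelvin
        + 38.92561 * math.log10(t_kelvin)
        - 563713.9 / t_kelvin**2
    )


def _pk1_saline(t_kelvin: float, salinity: float = 35.0) -> float:
    # Mehrbach et al. refit by Dickson & Millero (1987); apparent (stoichiometric)
    # seawater-scale constants, default S = 35
    s = salinity
    return (
        3670.7 / t_kelvin
        - 62.008
        + 9.7944 * math.log(t_kelvin)
        - 0.0118 * s
        + 0.000116 * s**2
    )


def _pk2_saline(t_kelvin: float, salinity: float = 35.0) -> float:
    s = salinity
    return 1394.7 / t_kelvin + 4.777 - 0.0184 * s + 0.000118 * s**2


def carbonic_acid_constants(
    temperature: float, variant: str = "freshwater"
) -> tuple[float, float]:
    """Apparent first and second dissociation constants K1, K2 at ``temperature`` (degC).

    ``variant='freshwater'`` uses the zero-ionic-strength temperature
    polynomials; ``variant='saline'`` uses apparent seawater-style constants
    (activity coefficients absorbed).  The study lake is hypersaline and its
    authors do not state their choice, so both are exposed.
    """
    _check_range("temperature", temperature, T_CELSIUS_MIN, T_CELSIUS_MAX)
    tk = temperature + 273.15
    if variant == "freshwater":
        return 10.0 ** -_pk1_freshwater(tk), 10.0 ** -_pk2_freshwater(tk)
    if variant == "saline":
        return 10.0 ** -_pk1_saline(tk), 10.0 ** -_pk2_saline(tk)
    raise ValueError(f"unknown constants variant {variant!r}")


def speciate_dic(
    ph: float,
    temperature: float,
    constants_variant: str = "freshwater",
    k_override: tuple[float, float] | None = None,
) -> SpeciationResult:
    """Partition DIC into CO2(aq) / HCO3- / CO3(2-) mole fractions.

    pH is treated as hydrogen-ion activity; the mass-action ratios
    1 : K1/aH : K1*K2/aH**2 are normalized to sum to one.  ``k_override``
    substitutes explicit (K1, K2) values, mainly for testing.
    """
    _check_range("ph", ph, PH_MIN, PH_MAX)
    _check_range("temperature", temperature, T_CELSIUS_MIN, T_CELSIUS_MAX)
    if k_override is not None:
        k1, k2 = k_override
    else:
        k1, k2 = carbonic_acid_constants(temperature, constants_variant)
    a_h = 10.0**-ph
    ratios = np.array([1.0, k1 / a_h, k1 * k2 / a_h**2])
    x = ratios / ratios.sum()
    return SpeciationResult(
        x_co2aq=float(x[0]),
        x_hco3=float(x[1]),
        x_co3=float(x[2]),
        k1=k1,
        k2=k2,
        temperature=temperature,
        ph=ph,
    )


@dataclass(frozen=True)
class FractionationSet:
    """Temperature-dependent carbon isotope enrichment factors (permil).

    Each function maps temperature in degC to an enrichment eps such that
    alpha = 1 + eps/1000 converts the reference-species delta to the
    subject-species delta in the exact multiplicative form.

    The default set composes the aragonite-CO2(g) factor (linear in degC)
    with the classic bicarbonate-CO2(g) and CO2(aq)-HCO3- equations
    (hyperbolic in kelvin), plus a small carbonate-bicarbonate term.  Its
    anchor value eps(aragonite - HCO3-) at 25 degC is 2.71 permil.
    """

    eps_arag_minus_hco3: Callable[[float], float]
    eps_co2aq_minus_hco3: Callable[[float], float]
    eps_co3_minus_hco3: Callable[[float], float]
    provenance: str = "unspecified"

    def alphas(self, temperature: float) -> tuple[float, float, float]:
        """(alpha_co2aq, alpha_hco3=1, alpha_co3) relative to HCO3- at T."""
        return (
            1.0 + self.eps_co2aq_minus_hco3(temperature) / 1000.0,
            1.0,
            1.0 + self.eps_co3_minus_hco3(temperature) / 1000.0,
        )


def _eps_arag_gas(t_c: float) -> float:
    # aragonite - CO2(gas), linear in degC
    return 13.88 - 0.13 * t_c


def _eps_hco3_gas(t_c: float) -> float:
    # HCO3- - CO2(gas)
    tk = t_c + 273.15
    return 9483.0 / tk - 23.89


def _eps_arag_hco3_default(t_c: float) -> float:
    return _eps_arag_gas(t_c) - _eps_hco3_gas(t_c)


def _eps_co2aq_hco3_default(t_c: float) -> float:
    tk = t_c + 273.15
    return -9866.0 / tk + 24.12


def _eps_co3_hco3_default(t_c: float) -> float:
    tk = t_c + 273.15
    return -867.0 / tk + 2.52


DEFAULT_FRACTIONATION = FractionationSet(
    eps_arag_minus_hco3=_eps_arag_hco3_default,
    eps_co2aq_minus_hco3=_eps_co2aq_hco3_default,
    eps_co3_minus_hco3=_eps_co3_hco3_default,
    provenance="aragonite-CO2(g) linear factor minus HCO3-CO2(g) hyperbolic factor; "
    "CO2(aq)-HCO3 and CO3-HCO3 from the classic inorganic-carbon compilation",
)

# Alternate coefficient set using the textbook linear-in-degC approximations
# of the gas-reference enrichments; kept for sensitivity analysis of the
# equilibrium prediction to the coefficient-source choice.
LINEAR_FRACTIONATION = FractionationSet(
    eps_arag_minus_hco3=lambda t_c: (13.88 - 0.13 * t_c) - (10.78 - 0.1141 * t_c),
    eps_co2aq_minus_hco3=lambda t_c: (0.0049 * t_c - 1.31) - (10.78 - 0.1141 * t_c),
    eps_co3_minus_hco3=_eps_co3_hco3_default,
    provenance="linear-in-degC approximations of the gas-reference enrichments",
)

FRACTIONATION_SETS = {
    "default": DEFAULT_FRACTIONATION,
    "linear": LINEAR_FRACTIONATION,
}


def hco3_delta_from_dic(
    delta13c_dic: float,
    speciation: SpeciationResult,
    fr: FractionationSet = DEFAULT_FRACTIONATION,
    temperature: float | None = None,
) -> float:
    """Solve the species mass balance for the |d13C| of bicarbonate.

    d_DIC = sum_i x_i * d_i with d_i = alpha_i*(d_hco3 + 1000) - 1000, so
    d_hco3 = (d_DIC + 1000) / sum_i x_i*alpha_i - 1000.
    """
    if temperature is None:
        temperature = speciation.temperature
    x = speciation.fractions
    if np.all(x == 0):
        raise ValueError("degenerate speciation: all mole fractions are zero")
    alphas = np.array(fr.alphas(temperature))
    denom = float(np.dot(x, alphas))
    return (delta13c_dic + 1000.0) / denom - 1000.0


def equilibrium_aragonite_delta(
    delta13c_hco3: float,
    temperature: float,
    fr: FractionationSet = DEFAULT_FRACTIONATION,
) -> float:
    """Equilibrium aragonite |d13C| from bicarbonate |d13C| at ``temperature``."""
    _check_range("temperature", temperature, T_CELSIUS_MIN, T_CELSIUS_MAX)
    alpha = 1.0 + fr.eps_arag_minus_hco3(temperature) / 1000.0
    return alpha * (delta13c_hco3 + 1000.0) - 1000.0


@dataclass(frozen=True)
class EquilibriumPrediction:
    """Maximum theoretical equilibrium aragonite |d13C| and its provenance."""

    delta13c_hco3: float
    delta13c_arag_eq: float
    temperature: float
    ph: float
    source_sample_id: str


def max_equilibrium_prediction(
    samples: Sequence[WaterSample],
    t_range: tuple[float, float] = (10.0, 40.0),
    t_step: float = 0.1,
    fr: FractionationSet = DEFAULT_FRACTIONATION,
    constants_variant: str = "freshwater",
) -> EquilibriumPrediction:
    """Maximum possible equilibrium aragonite |d13C| across water samples.

    Water temperatures at collection are rarely reported, so for each sample
    the equilibrium value is maximized over a temperature grid (default
    10-40 degC inclusive, 0.1 degC step); a sample with a recorded
    temperature is evaluated at that temperature only.  The overall maximum
    and the sample/temperature that produced it are returned.
    """
    if not samples:
        raise ValueError("at least one water sample is required")
    t_lo, t_hi = t_range
    _check_range("t_range[0]", t_lo, T_CELSIUS_MIN, T_CELSIUS_MAX)
    _check_range("t_range[1]", t_hi, T_CELSIUS_MIN, T_CELSIUS_MAX)
    if t_hi < t_lo:
        raise ValueError("t_range must be ordered (low, high)")
    n = int(round((t_hi - t_lo) / t_step)) + 1
    grid = np.linspace(t_lo, t_hi, n)

    best: EquilibriumPrediction | None = None
    for s in samples:
        temps = [s.temperature] if s.temperature is not None else grid
        for t in temps:
            spec = speciate_dic(s.ph, float(t), constants_variant)
            d_h = hco3_delta_from_dic(s.delta13c_dic, spec, fr)
            d_a = equilibrium_aragonite_delta(d_h, float(t), fr)
            if best is None or d_a > best.delta13c_arag_eq:
                best = EquilibriumPrediction(
                    delta13c_hco3=d_h,
                    delta13c_arag_eq=d_a,
                    temperature=float(t),
                    ph=s.ph,
                    source_sample_id=s.id,
                )
    assert best is not None
    return best


@dataclass(frozen=True)
class BiosignatureResult:
    """Per-sample offsets of observed carbonate |d13C| above equilibrium."""

    sample_ids: tuple[str, ...]
    offsets: tuple[float, ...]
    classifications: tuple[str, ...]
    prediction: EquilibriumPrediction
    tolerance: float

    @property
    def min_offset(self) -> float:
        return min(self.offsets)

    @property
    def max_offset(self) -> float:
        return max(self.offsets)

    @property
    def mean_offset(self) -> float:
        return float(np.mean(self.offsets))

    @property
    def sd_offset(self) -> float:
        return float(np.std(self.offsets, ddof=1)) if len(self.offsets) > 1 else 0.0


def _classify(offset: float, tolerance: float) -> str:
    if abs(offset) <= tolerance:
        return "equilibrium"
    return "photoautotrophic" if offset > 0 else "heterotrophic"


def biosignature_offsets(
    carbonates: Sequence[CarbonateSample],
    prediction: EquilibriumPrediction,
    tolerance: float = 0.1,
) -> BiosignatureResult:
    """Offsets of measured carbonate |d13C| above the theoretical maximum.

    offset_i = d13C_CaCO3,i - prediction.delta13c_arag_eq.  Offsets above
    +tolerance are classified photoautotrophic (12C preferentially removed
    from the DIC pool by photosynthesis, leaving the carbonate enriched);
    below -tolerance heterotrophic (respired 12C-rich carbon added); within
    the tolerance, equilibrium.  The default tolerance of 0.1 permil is an
    order of magnitude above typical analytical reproducibility.
    """
    if not carbonates:
        raise ValueError("at least one carbonate sample is required")
    if not math.isfinite(prediction.delta13c_arag_eq):
        raise ValueError("equilibrium prediction is not finite")
    offsets = tuple(c.delta13c_caco3 - prediction.delta13c_arag_eq for c in carbonates)
    return BiosignatureResult(
        sample_ids=tuple(c.id for c in carbonates),
        offsets=offsets,
        classifications=tuple(_classify(o, tolerance) for o in offsets),
        prediction=prediction,
        tolerance=tolerance,
    )


# Log-log power-law regression of total dissolved solids on specific
# conductance for Australian salt lakes: TDS = a * SC**b.
SALINITY_REGRESSION = {"a": 0.4665, "b": 1.0878}


def salinity_from_conductance(sc: float) -> float:
    """Estimate salinity (TDS, g/L) from specific conductance (mS/cm at 25 degC).

    Uses the published power-law conductivity-salinity regression for
    Australian salt lakes; valid for hypersaline waters well beyond the
    oceanographic practical-salinity range.
    """
    if sc <= 0:
        raise ValueError(f"specific conductance must be positive, got {sc!r}")
    return SALINITY_REGRESSION["a"] * sc ** SALINITY_REGRESSION["b"]
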