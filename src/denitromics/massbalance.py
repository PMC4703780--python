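"""Chemostat stoichiometry: C:N ratios, nitrogen balance, growth yield,
medium recipe and batch-incubation rate estimation.

Conventions: concentrations in mM (mM-C and mM-N count carbon and nitrogen
atoms), protein in g/L, dilution rate in culture-volume changes per day,
rates in mM/h (with a convenience conversion to umol L^-1 day^-1).  Biomass
is modelled as CH1.8O0.5N0.2 (formula mass 24.6 g per C-mol, N:C = 0.2
mol/mol); the protein fraction of dry biomass defaults to 0.47, inside the
standard 45-55% range and chosen so the nitrogen balance and the growth
yield worked examples are mutually consistent (see docs/methods.md).  All
conversion constants are config-exposed via :class:`BiomassModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class BiomassModel:
    """Conversion constants between assimilated N, biomass C and protein."""

    n_to_c: float = 0.2  # mol N per mol biomass C
    formula_mass: float = 24.6  # g per C-mol biomass (CH1.8O0.5N0.2)
    protein_fraction: float = 0.47  # g protein per g dry biomass

    def validate(self) -> None:
        if not (self.n_to_c > 0 and self.formula_mass > 0 and self.protein_fraction > 0):
            raise ValueError("all BiomassModel constants must be positive")
        if self.n_to_c > 1:
            raise ValueError("n_to_c above 1 mol N per mol C is not physical")


@dataclass
class ChemostatState:
    """Observed influent/effluent chemistry of one steady-state chemostat."""

    influent_nitrite: float = 0.0  # mM
    influent_nitrate: float = 0.0  # mM
    influent_organic_carbon: float = 0.0  # mM-C
    influent_organic_n: float = 0.0  # mM-N
    effluent_ammonium: float = 0.0  # mM
    effluent_nitrite: float = 0.0  # mM
    measured_protein: float = 0.0  # g/L
    dilution_rate: float = 0.36  # volume changes / day
    temperature: float = 25.0  # degC

    def validate(self) -> None:
        for name in (
            "influent_nitrite", "influent_nitrate", "influent_organic_carbon",
            "influent_organic_n", "effluent_ammonium", "effluent_nitrite",
            "measured_protein",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dilution_rate <= 0:
            raise ValueError("dilution_rate must be positive")


@dataclass
class BatchSeries:
    """Timed concentration series from a batch incubation."""

    times: np.ndarray  # hours
    concentrations: np.ndarray  # mM
    analyte: str = "nitrite"

    def validate(self) -> None:
        t = np.asarray(self.times, float)
        if t.size < 3:
            raise ValueError("batch series needs at least 3 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MassBalanceResult:
    cn_ratio: float  # C-mol / N-mol
    assimilated_n: float  # mM-N
    predicted_protein: float  # g/L
    yield_: float | None  # C-mol assimilated / C-mol converted
    dnra_warning: bool = False


#: mM/h -> umol L^-1 day^-1
MM_PER_H_TO_UMOL_PER_L_DAY = 24_000.0


def cn_ratio(state: ChemostatState) -> float:
    """Influent carbon-to-nitrogen ratio, C-mol per N-mol of NO2- + NO3-."""
    n = state.influent_nitrite + state.influent_nitrate
    if n <= 0:
        raise ValueError("influent nitrite + nitrate must be positive")
    return state.influent_organic_carbon / n


def nitrogen_balance(state: ChemostatState) -> float:
    """Assimilated nitrogen (mM-N): influent organic N minus effluent NH4+.

    A negative balance means more ammonium left than organic N entered,
    which can result from dissimilatory nitrate reduction to ammonium
    (DNRA); it is returned as-is with a warning.
    """
    assim = state.influent_organic_n - state.effluent_ammonium
    if assim < 0:
        warnings.warn(
            "negative assimilated N: possible DNRA (dissimilatory nitrate "
            "reduction to ammonium)",
            stacklevel=2,
        )
    return assim


def protein_from_nitrogen(assimilated_n: float, model: BiomassModel | None = None) -> float:
    """Protein concentration (g/L) implied by assimilated N (mM-N).

    assimilated N / n_to_c gives biomass carbon (mmol/L); times the biomass
    formula mass and the protein fraction gives g protein per litre.
    """
    model = model or BiomassModel()
    model.validate()
    return assimilated_n / 1000.0 / model.n_to_c * model.formula_mass * model.protein_fraction


def growth_yield(
    protein: float, converted_carbon: float, model: BiomassModel | None = None
) -> float:
    """Growth yield: C-mol assimilated into biomass per C-mol converted.

    ``protein`` in g/L, ``converted_carbon`` in mM-C.  Biomass carbon is
    back-calculated from protein through the biomass model.
    """
    model = model or BiomassModel()
    model.validate()
    if converted_carbon <= 0:
        raise ValueError("converted carbon must be positive")
    biomass_c = protein / model.protein_fraction / model.formula_mass * 1000.0  # mM-C
    y = biomass_c / converted_carbon
    if y > 1.0:
        raise ValueError(f"infeasible yield {y:.3f} > 1")
    return y


#: yield reported in the literature for model denitrifiers on acetate
REFERENCE_DENITRIFIER_YIELD = 0.3


def medium_recipe(
    total_carbon: float,
    fractions: tuple[float, float, float] = (0.44, 0.08, 0.48),
) -> dict[str, float]:
    """Split total medium carbon (mM-C) into glucose/acetate/amino-acid pools.

    Default fractions are 44% glucose, 8% acetate, 48% amino acids,
    mimicking the monomer composition of decaying biomass.
    """
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    s = sum(fractions)
    if abs(s - 1.0) > 0.01:
        raise ValueError(f"fractions sum to {s}, not 1 within 0.01")
    alloc = {
        "glucose": total_carbon * fractions[0] / s,
        "acetate": total_carbon * fractions[1] / s,
        "aminoacids": total_carbon * fractions[2] / s,
    }
    return alloc


@dataclass
class RateEstimate:
    slope_mm_per_h: float
    stderr_mm_per_h: float
    slope_umol_per_l_day: float
    ci95: tuple[float, float]
    intercept: float
    n: int


def batch_rate(series: BatchSeries) -> RateEstimate:
    """Ordinary least-squares rate from a batch time series.

    Returns the slope in mM/h with its standard error and the 95% confidence
    interval (t distribution, n-2 df), plus the slope in umol L^-1 day^-1.
    """
    series.validate()
    t = np.asarray(series.times, float)
    c = np.asarray(series.concentrations, float)
    fit = stats.linregress(t, c)
    tcrit = stats.t.ppf(0.975, t.size - 2)
    half = tcrit * fit.stderr
    return RateEstimate(
        slope_mm_per_h=float(fit.slope),
        stderr_mm_per_h=float(fit.stderr),
        slope_umol_per_l_day=float(fit.slope) * MM_PER_H_TO_UMOL_PER_L_DAY,
        ci95=(float(fit.slope) - half, float(fit.slope) + half),
        intercept=float(fit.intercept),
        n=int(t.size),
    )


def mass_balance(
    state: ChemostatState,
    model: BiomassModel | None = None,
    converted_carbon: float | None = None,
) -> MassBalanceResult:
    """Full mass-balance report for one chemostat state.

    ``converted_carbon`` defaults to the entire influent organic carbon
    (complete consumption); pass a smaller value for partial conversion.
    The yield is computed from the *measured* protein when available.
    """
    state.validate()
    model = model or BiomassModel()
    cc = state.influent_organic_carbon if converted_carbon is None else converted_carbon
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        assim = nitrogen_balance(state)
    dnra = any("DNRA" in str(w.message) for w in caught)
    if dnra:
        warnings.warn("negative assimilated N: possible DNRA", stacklevel=2)
    pred = protein_from_nitrogen(assim, model)
    y = None
    if state.measured_protein > 0 and cc > 0:
        y = growth_yield(state.measured_protein, cc, model)
    return MassBalanceResult(
        cn_ratio=cn_ratio(state),
        assimilated_n=assim,
        predicted_protein=pred,
        yield_=y,
        dnra_warning=dnra,
    )
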