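"""Gamma-concept growth model for psychrotolerant lactic acid bacteria.

Secondary model: the maximal specific growth rate is the rate at optimum
multiplied by one dimensionless gamma term in [0, 1] per environmental
factor (cardinal-parameter forms for temperature and pH, a water-activity
term for water-phase salt, MIC-style terms for smoke phenols, CO2 and
nitrite).  Primary model: a logistic curve with a discrete lag, run from
the inoculum level toward the maximum population density.

The default parameter values are a calibration by qualitative anchors for
a psychrotolerant-LAB starter in lightly preserved fish: growth over the
whole 10-25 degC screening range, liquid smoke the strongest inhibitor,
water-phase salt intermediate, pH/CO2/nitrite minor over their screening
ranges, and complete suppression of growth (no threshold crossing within
the simulation horizon) only when low temperature combines with near-MIC
smoke.  They are not fitted to any strain and every value is editable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "EnvironmentalCondition",
    "GrowthModelParams",
    "SimulationConfig",
    "GrowthCurve",
    "InvalidConditionError",
    "water_activity_from_salt",
    "secondary_mu",
    "lag_from_rlt",
    "simulate_growth",
]

LN2 = math.log(2.0)


class InvalidConditionError(ValueError):
    """Raised for non-finite or physically meaningless condition values."""


@dataclass(frozen=True)
class EnvironmentalCondition:
    """One combination of the seven screening variables.

    ``rlt`` is the relative lag time (dimensionless work of adaptation; 0
    means no lag phase), ``temperature`` degC, ``nacl`` % water-phase salt,
    ``ph`` pH units, ``smoke`` ppm phenol-equivalent liquid smoke, ``co2``
    % CO2 at equilibrium in the headspace, ``nitrite`` ppm.
    """

    rlt: float
    temperature: float
    nacl: float
    ph: float
    smoke: float
    co2: float
    nitrite: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise InvalidConditionError(f"{name} must be finite, got {value}")
        if self.rlt < 0:
            raise InvalidConditionError("rlt must be >= 0")
        for name in ("nacl", "smoke", "co2", "nitrite"):
            if getattr(self, name) < 0:
                raise InvalidConditionError(f"{name} must be >= 0")
        if not 0.0 <= self.ph <= 14.0:
            raise InvalidConditionError("ph must be in [0, 14]")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "EnvironmentalCondition":
        return cls(**{k: float(mapping[k]) for k in
                      ("rlt", "temperature", "nacl", "ph", "smoke", "co2", "nitrite")})


@dataclass(frozen=True)
class GrowthModelParams:
    """Cardinal and MIC parameters of the secondary model.

    mu_ref
        Maximal specific growth rate at the optimum of every factor, 1/h.
    t_min, t_opt
        Cardinal temperatures (degC) of the square-root-type term
        ``gamma_T = ((T - t_min)/(t_opt - t_min))^2`` (suboptimal branch;
        clamped to 1 above ``t_opt``).
    ph_min, ph_opt, ph_max
        Cardinal pH values of the CPM term
        ``(pH - ph_min)(ph_max - pH) / ((ph_opt - ph_min)(ph_max - ph_opt))``.
    aw_min, aw_opt
        Water-activity bounds of the linear salt term; NaCl %WPS is first
        converted to a_w with the quadratic NaCl/a_w relation.
    phenol_mic, phenol_exponent
        Smoke term ``(1 - P/MIC)^exponent`` (ppm phenol equivalents).
    co2_max
        Equilibrium headspace CO2 (%) extinguishing growth, linear term.
    nitrite_mic
        Nitrite MIC (ppm), linear term.
    """

    mu_ref: float = 0.7
    t_min: float = 2.0
    t_opt: float = 28.0
    ph_min: float = 3.4
    ph_opt: float = 6.3
    ph_max: float = 9.2
    aw_min: float = 0.928
    aw_opt: float = 0.997
    phenol_mic: float = 55.0
    phenol_exponent: float = 2.0
    co2_max: float = 120.0
    nitrite_mic: float = 600.0

    def optimum(self, rlt: float = 0.0) -> EnvironmentalCondition:
        """Condition at which every gamma term equals 1."""
        return EnvironmentalCondition(
            rlt=rlt, temperature=self.t_opt, nacl=0.0, ph=self.ph_opt,
            smoke=0.0, co2=0.0, nitrite=0.0,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GrowthModelParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def water_activity_from_salt(wps: float) -> float:
    """Water activity of the aqueous phase at ``wps`` % water-phase NaCl
    (quadratic NaCl/a_w relation for brines)."""
    return 1.0 - 5.2471e-3 * wps - 1.2206e-4 * wps * wps


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def gamma_temperature(t: float, p: GrowthModelParams) -> float:
    if t <= p.t_min:
        return 0.0
    return _clip01((t - p.t_min) / (p.t_opt - p.t_min)) ** 2


def gamma_ph(ph: float, p: GrowthModelParams) -> float:
    if ph <= p.ph_min or ph >= p.ph_max:
        return 0.0
    num = (ph - p.ph_min) * (p.ph_max - ph)
    den = (p.ph_opt - p.ph_min) * (p.ph_max - p.ph_opt)
    return _clip01(num / den)


def gamma_salt(nacl: float, p: GrowthModelParams) -> float:
    aw = water_activity_from_salt(nacl)
    return _clip01((aw - p.aw_min) / (p.aw_opt - p.aw_min))


def gamma_smoke(smoke: float, p: GrowthModelParams) -> float:
    if smoke >= p.phenol_mic:
        return 0.0
    return (1.0 - smoke / p.phenol_mic) ** p.phenol_exponent


def gamma_co2(co2: float, p: GrowthModelParams) -> float:
    return _clip01(1.0 - co2 / p.co2_max)


def gamma_nitrite(nitrite: float, p: GrowthModelParams) -> float:
    return _clip01(1.0 - nitrite / p.nitrite_mic)


def secondary_mu(condition: EnvironmentalCondition, params: GrowthModelParams | None = None) -> float:
    """Maximal specific growth rate (1/h) under ``condition``.

    Product of the individual gamma terms times ``mu_ref``; returns exactly
    0 when any factor is at or beyond its cardinal limit (growth/no-growth
    boundary).
    """
    if params is None:
        params = GrowthModelParams()
    gammas = (
        gamma_temperature(condition.temperature, params),
        gamma_ph(condition.ph, params),
        gamma_salt(condition.nacl, params),
        gamma_smoke(condition.smoke, params),
        gamma_co2(condition.co2, params),
        gamma_nitrite(condition.nitrite, params),
    )
    mu = params.mu_ref
    for g in gammas:
        mu *= g
    return mu


def lag_from_rlt(rlt: float, mu: float) -> float:
    """Lag duration (h) from the relative lag time.

    RLT counts the adaptation work in doublings, so ``lag = rlt ln(2)/mu``.
    A population with ``rlt = 0`` has no lag phase regardless of the rate;
    with ``mu = 0`` and positive RLT the lag is infinite (no growth ever).
    """
    if rlt < 0:
        raise ValueError("rlt must be >= 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if rlt == 0:
        return 0.0
    if mu == 0:
        return math.inf
    return rlt * LN2 / mu


@dataclass(frozen=True)
class SimulationConfig:
    """Primary-model settings: inoculum ``n0``, ceiling ``nmax`` and
    critical threshold ``ncrit`` in log10 CFU/g; ``horizon`` and ``dt``
    in hours."""

    n0: float = 5.0
    nmax: float = 9.0
    ncrit: float = 8.9
    horizon: float = 2000.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if not (self.n0 < self.ncrit < self.nmax):
            raise ValueError("require n0 < ncrit < nmax")
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")

    def time_grid(self) -> np.ndarray:
        n_steps = int(math.floor(self.horizon / self.dt + 1e-9))
        return np.arange(n_steps + 1) * self.dt


@dataclass
class GrowthCurve:
    """Simulated log10 population trajectory under one condition."""

    times: np.ndarray
    log_density: np.ndarray
    mu_used: float
    lag_used: float
    condition: EnvironmentalCondition | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.log_density = np.asarray(self.log_density, dtype=float)
        if self.times.shape != self.log_density.shape:
            raise ValueError("times and log_density must have the same shape")


def logistic_log10(times: np.ndarray, mu: float, lag: float,
                   n0: float, nmax: float) -> np.ndarray:
    """Log10 density of a logistic-with-delay population at ``times``.

    Flat at ``n0`` until ``lag``, then a logistic approach (in cell
    numbers) to ``nmax`` at specific rate ``mu``.
    """
    times = np.asarray(times, dtype=float)
    if mu <= 0:
        return np.full_like(times, n0)
    ratio = 10.0 ** (nmax - n0) - 1.0  # (Nmax - N0)/N0
    t_eff = np.clip(times - lag, 0.0, None)
    return nmax - np.log10(1.0 + ratio * np.exp(-mu * t_eff))


def simulate_growth(
    condition: EnvironmentalCondition,
    params: GrowthModelParams | None = None,
    sim: SimulationConfig | None = None,
) -> GrowthCurve:
    """Deterministic growth curve for ``condition``.

    The secondary model supplies mu, the relative lag time supplies the
    lag, and the primary model is evaluated on the configured time grid.
    With mu = 0 (or an infinite lag) the curve stays at ``n0``.
    """
    if params is None:
        params = GrowthModelParams()
    if sim is None:
        sim = SimulationConfig()
    mu = secondary_mu(condition, params)
    lag = lag_from_rlt(condition.rlt, mu)
    times = sim.time_grid()
    if mu <= 0 or math.isinf(lag):
        log_density = np.full_like(times, sim.n0)
    else:
        log_density = logistic_log10(times, mu, lag, sim.n0, sim.nmax)
    return GrowthCurve(times=times, log_density=log_density,
                       mu_used=mu, lag_used=lag, condition=condition)
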