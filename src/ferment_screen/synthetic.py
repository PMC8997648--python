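"""Synthetic ground-truth generators for testing the screening pipeline.

The simulator's 243-run response table is not a public dataset, so the
test surface is built from generators with fully known structure:
quadratic response surfaces with chosen coefficients plus Gaussian noise,
a "study-like" sparse coefficient pattern whose signs and ranking mirror
the qualitative outcome of the fish-fermentation screen, and logistic
growth fixtures whose threshold-crossing times are known in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .doe import DesignTable
from .growth import GrowthCurve, SimulationConfig, logistic_log10
from .rsm import Term, model_matrix_from_codes

__all__ = [
    "GroundTruth",
    "make_synthetic_responses",
    "make_paperlike_truth",
    "make_growth_fixture",
    "logistic_crossing_time",
]


@dataclass(frozen=True)
class GroundTruth:
    """Known quadratic surface: intercept, per-term coefficients (absent
    terms are exactly 0), Gaussian noise level and generator seed."""

    intercept: float
    coefficients: dict[Term, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def active_terms(self) -> list[Term]:
        return [t for t, b in self.coefficients.items() if b != 0.0]

    def beta(self, terms: list[Term]) -> np.ndarray:
        """Coefficient vector aligned to ``[intercept] + terms``."""
        return np.array([self.intercept] + [self.coefficients.get(t, 0.0) for t in terms])


def make_synthetic_responses(design: DesignTable, truth: GroundTruth) -> np.ndarray:
    """Responses y = quadratic(coded design) + N(0, noise_sd^2) noise.

    Seeded by ``truth.seed``; with ``noise_sd = 0`` the values lie exactly
    on the generating surface.
    """
    mm = model_matrix_from_codes(design.codes, include_interactions=True,
                                 factors=design.factors)
    unknown = set(truth.coefficients) - set(mm.terms)
    if unknown:
        raise ValueError(f"truth contains terms outside the design term set: {unknown}")
    y = mm.X @ truth.beta(mm.terms)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    return y


def make_paperlike_truth(seed: int = 0, noise_sd: float = 0.01) -> GroundTruth:
    """A sparse truth with the effect structure found in the fish screen.

    For the growth-rate response the dominant effect is a negative liquid
    smoke term, followed by a positive temperature term and a negative
    water-phase salt term, with a temperature-by-smoke interaction; the
    magnitudes are free fixture choices on the 1/h scale of mu_max, only
    the signs and the ranking are pinned.  Factor indices follow the
    default design order (RLT, T, NaCl, pH, Smoke, CO2, Nitrite).
    """
    coefficients = {
        Term("linear", 4): -0.072,       # smoke: dominant, negative
        Term("linear", 1): 0.055,        # temperature: positive
        Term("linear", 2): -0.024,       # NaCl: negative
        Term("interaction", 1, 4): -0.045,  # temperature x smoke
        Term("quadratic", 4): 0.018,     # curvature near the smoke MIC
    }
    return GroundTruth(intercept=0.16, coefficients=coefficients,
                       noise_sd=noise_sd, seed=seed)


def logistic_crossing_time(
    mu: float, lag: float, sim: SimulationConfig, ncrit: float | None = None
) -> float:
    """Closed-form time at which the delayed logistic curve reaches
    ``ncrit`` (defaults to the configured critical threshold).

    Inverts N(t) = Nmax / (1 + ((Nmax - N0)/N0) exp(-mu (t - lag))) at
    N = 10^ncrit; infinite when mu = 0.
    """
    if ncrit is None:
        ncrit = sim.ncrit
    if not sim.n0 < ncrit < sim.nmax:
        raise ValueError("ncrit must lie strictly between n0 and nmax")
    if mu <= 0:
        return math.inf
    n0, nmax = 10.0 ** sim.n0, 10.0 ** sim.nmax
    ntarget = 10.0 ** ncrit
    work = math.log((nmax - n0) / n0 * ntarget / (nmax - ntarget))
    return lag + work / mu


def make_growth_fixture(
    mu: float, lag: float, sim: SimulationConfig | None = None
) -> GrowthCurve:
    """Logistic-with-delay curve with exactly known kinetics.

    Evaluates the closed-form primary model on the configured time grid;
    the crossing time of any threshold is available analytically through
    :func:`logistic_crossing_time`, which makes these curves the reference
    inputs for threshold-extraction tests.
    """
    if mu < 0 or lag < 0:
        raise ValueError("mu and lag must be >= 0")
    if sim is None:
        sim = SimulationConfig()
    times = sim.time_grid()
    log_density = logistic_log10(times, mu, lag, sim.n0, sim.nmax)
    return GrowthCurve(times=times, log_density=log_density,
                       mu_used=mu, lag_used=lag, condition=None)
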