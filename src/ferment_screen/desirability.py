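"""Piecewise-linear individual desirability and one-factor profiles.

A desirability maps a predicted response onto [0, 1]: 0 at or beyond the
most unfavorable value, 1 at or beyond the most favorable value, linear
in between.  For the screening responses, a high maximal growth rate is
favorable (larger-is-better) and a long time to the critical threshold is
unfavorable (smaller-is-better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .doe import DesignTable
from .rsm import QuadraticFit

__all__ = [
    "DesirabilitySpec",
    "individual_desirability",
    "desirability_profile",
    "overall_desirability",
    "spec_from_fit",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Anchors of one desirability transform.

    ``orientation`` is ``"larger"`` (y_fav > y_unfav) or ``"smaller"``
    (y_fav < y_unfav); the two must be consistent with the anchor order.
    """

    y_unfav: float
    y_fav: float
    orientation: str = "larger"

    def __post_init__(self) -> None:
        if self.y_unfav == self.y_fav:
            raise ValueError("y_unfav and y_fav must differ (degenerate spec)")
        if self.orientation not in ("larger", "smaller"):
            raise ValueError("orientation must be 'larger' or 'smaller'")
        larger = self.y_fav > self.y_unfav
        if larger != (self.orientation == "larger"):
            raise ValueError("anchor order inconsistent with orientation")


def individual_desirability(y, spec: DesirabilitySpec):
    """Desirability of response value(s) ``y`` under ``spec``.

    Scalar in, scalar out; array in, array out.  The linear branch
    ``(y - y_unfav) / (y_fav - y_unfav)`` handles both orientations
    through the sign of its denominator, clipped to [0, 1].
    """
    arr = np.asarray(y, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("response values must be finite")
    d = np.clip((arr - spec.y_unfav) / (spec.y_fav - spec.y_unfav), 0.0, 1.0)
    if np.isscalar(y) or arr.ndim == 0:
        return float(d)
    return d


def spec_from_fit(fit: QuadraticFit, design: DesignTable, orientation: str) -> DesirabilitySpec:
    """Default anchors: min/max of the model predictions over the design
    region, so censored simulator outputs do not distort the scale."""
    pred = fit.predict(design.codes)
    lo, hi = float(pred.min()), float(pred.max())
    if lo == hi:
        raise ValueError("model predicts a constant response; anchors are degenerate")
    if orientation == "larger":
        return DesirabilitySpec(y_unfav=lo, y_fav=hi, orientation="larger")
    return DesirabilitySpec(y_unfav=hi, y_fav=lo, orientation="smaller")


def desirability_profile(
    fit: QuadraticFit,
    factor: str,
    spec: DesirabilitySpec,
    others_at: dict[str, float] | None = None,
    resolution: int = 21,
) -> pd.DataFrame:
    """One-factor desirability curve.

    The factor sweeps a coded grid over [-1, +1] while the other factors
    stay at ``others_at`` (coded; default 0, the center of the region);
    each prediction is mapped through ``spec``.  Columns: factor, coded,
    actual, predicted, desirability.
    """
    if fit.factors is None:
        raise ValueError("fit carries no factor metadata")
    names = [f.name for f in fit.factors]
    if factor not in names:
        raise KeyError(f"unknown factor {factor!r}")
    idx = names.index(factor)
    spec_f = fit.factors[idx]
    others_at = others_at or {}
    base = np.zeros(len(names))
    for fname, code in others_at.items():
        if fname not in names:
            raise KeyError(f"unknown factor {fname!r}")
        base[names.index(fname)] = code
    grid = np.linspace(-1.0, 1.0, resolution)
    points = np.tile(base, (resolution, 1))
    points[:, idx] = grid
    predicted = fit.predict(points)
    des = individual_desirability(predicted, spec)
    return pd.DataFrame(
        {
            "factor": factor,
            "coded": grid,
            "actual": [spec_f.decode(c) for c in grid],
            "predicted": predicted,
            "desirability": des,
        }
    )


def overall_desirability(d_values: Sequence[float] | Iterable[float]) -> float:
    """Geometric mean of individual desirabilities (0 if any component is 0)."""
    values = list(d_values)
    if not values:
        raise ValueError("need at least one desirability value")
    for d in values:
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"desirability {d} outside [0, 1]")
    if any(d == 0.0 for d in values):
        return 0.0
    return float(math.exp(sum(math.log(d) for d in values) / len(values)))
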