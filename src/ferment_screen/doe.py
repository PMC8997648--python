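"""Three-level factorial designs for fermentation factor screening.

Builds regular ``3^(k-p)`` fractional factorial designs over the screening
factors of a smoked fermented fish formulation (relative lag time,
temperature, water-phase salt, pH, liquid smoke, headspace CO2, nitrite),
codes factor levels onto the standard {-1, 0, +1} scale and decodes them
back to physical units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "InvalidDesignError",
    "default_factors",
    "build_design",
    "decode",
    "encode",
    "factors_from_csv",
]

#: Default randomization seed for run order (arbitrary but fixed).
DEFAULT_SEED = 20220325


class InvalidDesignError(ValueError):
    """Raised when a requested fraction cannot be constructed."""


@dataclass(frozen=True)
class FactorSpec:
    """One designed factor with its three physical levels.

    Parameters
    ----------
    name : str
        Machine identifier (e.g. ``"temperature"``); used as a column stem.
    level_lo, level_mid, level_hi : float
        Physical values at coded levels -1, 0 and +1.  ``level_mid`` must
        lie strictly between the other two.
    label : str, optional
        Short display label for report tables (e.g. ``"T"``).
    """

    name: str
    level_lo: float
    level_mid: float
    level_hi: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.level_lo < self.level_hi):
            raise ValueError(f"{self.name}: level_lo must be < level_hi")
        if not (self.level_lo < self.level_mid < self.level_hi):
            raise ValueError(f"{self.name}: level_mid must lie strictly between level_lo and level_hi")

    @property
    def display(self) -> str:
        return self.label if self.label is not None else self.name

    def decode(self, code: float) -> float:
        """Map a coded value in [-1, +1] to physical units.

        Piecewise linear through the three anchors, so -1/0/+1 map exactly
        onto ``level_lo``/``level_mid``/``level_hi`` even for off-centre
        midpoints; fractional codes interpolate.
        """
        c = float(code)
        if c < -1.0 or c > 1.0:
            raise ValueError(f"coded value {c} outside [-1, +1]")
        if c == -1.0:
            return self.level_lo
        if c == 1.0:
            return self.level_hi
        if c <= 0.0:
            return self.level_mid + c * (self.level_mid - self.level_lo)
        return self.level_mid + c * (self.level_hi - self.level_mid)

    def encode(self, value: float) -> float:
        """Inverse of :meth:`decode`; raises if outside the factor range."""
        v = float(value)
        if v < self.level_lo or v > self.level_hi:
            raise ValueError(
                f"{self.name}: value {v} outside [{self.level_lo}, {self.level_hi}]"
            )
        if v <= self.level_mid:
            return (v - self.level_mid) / (self.level_mid - self.level_lo)
        return (v - self.level_mid) / (self.level_hi - self.level_mid)


def default_factors() -> tuple[FactorSpec, ...]:
    """The seven screening factors and their levels for the fish formulation.

    Order fixes the 1-based factor numbering used in effect tables
    ("(2) T (L)", "2L by 5L", ...).
    """
    return (
        FactorSpec("rlt", 0.0, 2.0, 4.0, label="RLT"),
        FactorSpec("temperature", 10.0, 17.5, 25.0, label="T"),
        FactorSpec("nacl", 0.0, 3.0, 6.0, label="NaCl"),
        FactorSpec("ph", 5.0, 6.0, 7.0, label="pH"),
        FactorSpec("smoke", 0.0, 20.0, 40.0, label="Smoke"),
        FactorSpec("co2", 0.0, 15.0, 30.0, label="CO2"),
        FactorSpec("nitrite", 0.0, 75.0, 150.0, label="Nitrite"),
    )


@dataclass
class DesignTable:
    """A coded 3-level design: one row per run, one column per factor.

    ``codes`` holds integers in {-1, 0, +1} with shape ``(n_runs, k)``;
    ``run_ids`` are the post-randomization labels ``"S1".."Sn"``;
    ``generators`` documents the defining relations of the fraction so the
    confounding pattern is reproducible.
    """

    factors: tuple[FactorSpec, ...]
    codes: np.ndarray
    run_ids: tuple[str, ...]
    seed: int
    generators: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.factors):
            raise ValueError("codes must be (n_runs, n_factors)")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("all codes must be in {-1, 0, +1}")
        if len(self.run_ids) != self.codes.shape[0]:
            raise ValueError("one run_id per row required")
        if len(set(self.run_ids)) != len(self.run_ids):
            raise ValueError("run_ids must be unique")

    @property
    def n_runs(self) -> int:
        return self.codes.shape[0]

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def to_frame(self) -> pd.DataFrame:
        """Design as a DataFrame with coded and decoded columns."""
        data: dict[str, object] = {"run_id": list(self.run_ids)}
        for j, f in enumerate(self.factors):
            data[f"{f.name}_coded"] = self.codes[:, j]
        actual = decode(self)
        for f in self.factors:
            data[f"{f.name}_actual"] = actual[f.name].to_numpy()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _generator_spec(n_basic: int, n_generated: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Coefficient patterns for the generated columns of a regular fraction.

    Generated column ``i`` (1-based) is built from basic columns
    ``(1, 2, 2+i)`` with GF(3) coefficients ``(1, w_i, 1)`` where ``w_i``
    alternates 1, 2, 1, 2, ...  For the default 3^(7-2) fraction this gives
    x6 = (x1 + x2 + x3) mod 3 and x7 = (x1 + 2 x2 + x4) mod 3.
    """
    if n_generated > 0 and n_basic < 2 + n_generated:
        raise InvalidDesignError(
            f"fraction needs {2 + n_generated} basic columns for {n_generated} "
            f"generators but only {n_basic} remain"
        )
    spec = []
    for i in range(1, n_generated + 1):
        cols = (0, 1, 1 + i)  # 0-based basic-column indices
        coeffs = (1, 1 if i % 2 == 1 else 2, 1)
        spec.append((cols, coeffs))
    return spec


def build_design(
    factors: Sequence[FactorSpec] | None = None,
    fraction_exponent: int = 2,
    seed: int = DEFAULT_SEED,
) -> DesignTable:
    """Construct a regular ``3^(k-p)`` fractional factorial design.

    The first ``k - p`` factors form a full 3-level factorial; each of the
    remaining ``p`` factor columns is a fixed GF(3) linear combination of
    basic columns (see :func:`_generator_spec`), which keeps every column
    balanced (each level in exactly ``n/3`` runs) and orthogonal to the
    basic columns.  Run order is shuffled with ``seed``; run labels
    ``"S1".."Sn"`` are assigned after shuffling, so the set of rows is
    seed-independent but their order is not.

    Parameters
    ----------
    factors : sequence of FactorSpec, optional
        Defaults to the seven-factor set of :func:`default_factors`.
    fraction_exponent : int
        ``p`` in ``3^(k-p)``; 0 returns the full factorial.
    seed : int
        Randomization seed for the run order.
    """
    if factors is None:
        factors = default_factors()
    factors = tuple(factors)
    k = len(factors)
    p = int(fraction_exponent)
    if not 1 <= k <= 12:
        raise InvalidDesignError(f"number of factors must be in [1, 12], got {k}")
    if p < 0 or p >= k:
        raise InvalidDesignError(f"fraction_exponent must satisfy 0 <= p < k, got p={p}, k={k}")
    b = k - p
    if p > 0 and b < 2:
        raise InvalidDesignError("fraction leaves fewer than 2 independent columns")
    gens = _generator_spec(b, p)

    base = np.array(list(itertools.product(range(3), repeat=b)), dtype=int)
    columns = [base[:, j] for j in range(b)]
    gen_strings = []
    for gi, (cols, coeffs) in enumerate(gens):
        col = np.zeros(len(base), dtype=int)
        parts = []
        for c, w in zip(cols, coeffs):
            col += w * base[:, c]
            parts.append(f"x{c + 1}" if w == 1 else f"{w}*x{c + 1}")
        columns.append(col % 3)
        gen_strings.append(f"x{b + gi + 1} = ({' + '.join(parts)}) mod 3")
    codes = np.column_stack(columns) - 1

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codes))
    codes = codes[order]
    run_ids = tuple(f"S{i + 1}" for i in range(len(codes)))
    return DesignTable(
        factors=factors,
        codes=codes,
        run_ids=run_ids,
        seed=int(seed),
        generators=tuple(gen_strings),
    )


def decode(design: DesignTable) -> pd.DataFrame:
    """Physical conditions for every run of a coded design."""
    out = {}
    for j, f in enumerate(design.factors):
        out[f.name] = np.array([f.decode(c) for c in design.codes[:, j]])
    frame = pd.DataFrame(out)
    frame.insert(0, "run_id", list(design.run_ids))
    return frame


def encode(actual_value: float, factor: FactorSpec) -> float:
    """Code a physical value onto the [-1, +1] scale of ``factor``."""
    return factor.encode(actual_value)


def factors_from_csv(path) -> tuple[FactorSpec, ...]:
    """Read factor specifications from a CSV with columns
    ``name, level_lo, level_mid, level_hi[, label]``."""
    frame = pd.read_csv(path)
    required = {"name", "level_lo", "level_mid", "level_hi"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"factor file missing columns: {sorted(missing)}")
    specs = []
    for _, row in frame.iterrows():
        specs.append(
            FactorSpec(
                name=str(row["name"]),
                level_lo=float(row["level_lo"]),
                level_mid=float(row["level_mid"]),
                level_hi=float(row["level_hi"]),
                label=str(row["label"]) if "label" in frame.columns and pd.notna(row.get("label")) else None,
            )
        )
    return tuple(specs)
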