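"""Second-order response-surface fitting on coded designs.

Fits y = B0 + sum B_i x_i + sum B_ii x_i^2 + sum B_ij x_i x_j by ordinary
least squares on the coded (-1/0/+1) predictors, removes non-significant
terms by backward elimination at a fixed alpha with weak heredity, and
reports standardized effects (coefficient / standard error, the per-term
t statistic), residual degrees of freedom and adjusted R^2 in the layout
customary for screening studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .doe import DesignTable, FactorSpec

__all__ = [
    "Term",
    "TermCoefficient",
    "ModelMatrix",
    "QuadraticFit",
    "AliasingError",
    "build_model_matrix",
    "model_matrix_from_codes",
    "fit_quadratic",
    "backward_eliminate",
    "standardized_effects_table",
    "predict_surface",
]


class AliasingError(np.linalg.LinAlgError):
    """Raised when confounded columns make the requested fit impossible."""


@dataclass(frozen=True)
class Term:
    """One polynomial term: linear x_i, quadratic x_i^2 or interaction
    x_i*x_j.  Factor indices are 0-based; labels use 1-based numbering."""

    kind: str  # "linear" | "quadratic" | "interaction"
    i: int
    j: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "interaction":
            if self.j is None or self.j <= self.i:
                raise ValueError("interaction needs ordered indices i < j")
        elif self.j is not None:
            raise ValueError(f"{self.kind} term takes a single index")

    def involves(self, factor_index: int) -> bool:
        return factor_index == self.i or factor_index == self.j

    def label(self, factors: tuple[FactorSpec, ...] | None = None) -> str:
        def disp(idx: int) -> str:
            return factors[idx].display if factors is not None else f"x{idx + 1}"

        if self.kind == "linear":
            return f"({self.i + 1}) {disp(self.i)} (L)"
        if self.kind == "quadratic":
            return f"{disp(self.i)} (Q)"
        return f"{self.i + 1}L by {self.j + 1}L"

    def column(self, codes: np.ndarray) -> np.ndarray:
        x = codes.astype(float)
        if self.kind == "linear":
            return x[:, self.i]
        if self.kind == "quadratic":
            return x[:, self.i] ** 2
        return x[:, self.i] * x[:, self.j]


def full_term_set(n_factors: int, include_interactions: bool = True) -> list[Term]:
    """Intercept-free term list in report order: all linear, all quadratic,
    then interactions (i < j)."""
    terms = [Term("linear", i) for i in range(n_factors)]
    terms += [Term("quadratic", i) for i in range(n_factors)]
    if include_interactions:
        terms += [
            Term("interaction", i, j)
            for i in range(n_factors)
            for j in range(i + 1, n_factors)
        ]
    return terms


@dataclass
class ModelMatrix:
    """Predictor matrix (first column = intercept) plus its term list."""

    X: np.ndarray
    terms: list[Term]
    factors: tuple[FactorSpec, ...] | None = None

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column_labels(self) -> list[str]:
        return ["intercept"] + [t.label(self.factors) for t in self.terms]


def model_matrix_from_codes(
    codes: np.ndarray,
    include_interactions: bool = True,
    factors: tuple[FactorSpec, ...] | None = None,
) -> ModelMatrix:
    codes = np.asarray(codes, dtype=float)
    terms = full_term_set(codes.shape[1], include_interactions)
    X = np.column_stack([np.ones(codes.shape[0])] + [t.column(codes) for t in terms])
    return ModelMatrix(X=X, terms=terms, factors=factors)


def build_model_matrix(design: DesignTable, include_interactions: bool = True) -> ModelMatrix:
    """Second-order predictor matrix for a coded design: intercept, k
    linear, k quadratic and (optionally) k(k-1)/2 interaction columns."""
    return model_matrix_from_codes(design.codes, include_interactions, design.factors)


@dataclass(frozen=True)
class TermCoefficient:
    """Fitted coefficient of one term, with its classical OLS standard
    error, standardized effect (estimate / std_error) and two-sided
    t-test p-value."""

    term: Term
    estimate: float
    std_error: float
    standardized_effect: float
    p_value: float


@dataclass
class QuadraticFit:
    """A fitted (possibly reduced) second-order model."""

    response_name: str
    intercept: float
    intercept_se: float
    terms: list[TermCoefficient]
    df_residual: int
    r2_adj: float
    eliminated: list[str] = field(default_factory=list)
    aliased: list[str] = field(default_factory=list)
    factors: tuple[FactorSpec, ...] | None = None
    full_terms: list[Term] = field(default_factory=list)
    # retained design info so the model can be refit and used for prediction
    _codes: np.ndarray | None = None
    _y: np.ndarray | None = None

    def term_map(self) -> dict[Term, TermCoefficient]:
        return {tc.term: tc for tc in self.terms}

    def predict(self, codes: np.ndarray) -> np.ndarray:
        """Evaluate the fitted polynomial at coded points (n, k)."""
        codes = np.atleast_2d(np.asarray(codes, dtype=float))
        y = np.full(codes.shape[0], self.intercept)
        for tc in self.terms:
            y += tc.estimate * tc.term.column(codes)
        return y


def _drop_aliased(X: np.ndarray, terms: list[Term],
                  factors) -> tuple[np.ndarray, list[Term], list[str]]:
    """Greedily drop columns (in reverse report order) until full rank."""
    keep = list(range(X.shape[1]))
    aliased: list[str] = []
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, terms, aliased
    # walk from the last term backwards; the intercept is never dropped
    idx = len(keep) - 1
    while np.linalg.matrix_rank(X[:, keep]) < len(keep) and idx >= 1:
        trial = [c for c in keep if c != idx]
        if np.linalg.matrix_rank(X[:, trial]) == np.linalg.matrix_rank(X[:, keep]):
            aliased.append(terms[idx - 1].label(factors))
            keep = trial
        idx -= 1
    kept_terms = [terms[c - 1] for c in keep[1:]]
    return X[:, keep], kept_terms, aliased


def _ols_fit(X: np.ndarray, y: np.ndarray):
    return sm.OLS(y, X).fit()


def _fit_terms(
    codes: np.ndarray,
    terms: list[Term],
    y: np.ndarray,
    response_name: str,
    factors,
    full_terms: list[Term],
    eliminated: list[str],
    aliased: list[str],
) -> QuadraticFit:
    X = np.column_stack([np.ones(codes.shape[0])] + [t.column(codes) for t in terms])
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more observations ({X.shape[0]}) than parameters ({X.shape[1]})"
        )
    res = _ols_fit(X, y)
    # an (almost) exact interpolation leaves no residual variance, so the
    # classical t-test is undefined; report NaN rather than spurious
    # near-zero p-values driven by floating-point noise
    scale = float(np.mean(y * y))
    degenerate = float(res.ssr) <= 1e-20 * max(scale, 1e-30) * len(y)
    coeffs = []
    for pos, term in enumerate(terms, start=1):
        est = float(res.params[pos])
        se = float(res.bse[pos])
        if degenerate or se == 0.0:
            teff = math.nan
            pval = math.nan
        else:
            teff = est / se
            pval = float(res.pvalues[pos])
        coeffs.append(TermCoefficient(term, est, se, teff, pval))
    r2_adj = float(res.rsquared_adj)
    if not math.isfinite(r2_adj) or r2_adj < 0:
        r2_adj = 0.0
    return QuadraticFit(
        response_name=response_name,
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        terms=coeffs,
        df_residual=int(res.df_resid),
        r2_adj=r2_adj,
        eliminated=list(eliminated),
        aliased=list(aliased),
        factors=factors,
        full_terms=list(full_terms),
        _codes=codes,
        _y=np.asarray(y, dtype=float),
    )


def fit_quadratic(matrix: ModelMatrix, y: np.ndarray, response_name: str = "y",
                  codes: np.ndarray | None = None) -> QuadraticFit:
    """Ordinary least squares fit of the second-order model.

    Censored responses must be excluded upstream; ``y`` must align with the
    rows of ``matrix``.  If the design fraction aliases some columns, the
    confounded columns are dropped (last-in-report-order first), recorded
    in ``fit.aliased``, and the fit proceeds on a maximal linearly
    independent subset.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != matrix.X.shape[0]:
        raise ValueError("response length does not match design rows")
    if np.isnan(y).any():
        raise ValueError("censored (NaN) responses must be excluded before fitting")
    X, terms, aliased = _drop_aliased(matrix.X, matrix.terms, matrix.factors)
    if codes is None:
        # reconstruct coded columns from the linear terms when possible
        n_factors = 1 + max(
            max((t.i for t in matrix.terms), default=0),
            max((t.j for t in matrix.terms if t.j is not None), default=0),
        )
        lin = {t.i: pos for pos, t in enumerate(matrix.terms) if t.kind == "linear"}
        if len(lin) == n_factors:
            codes = np.column_stack([matrix.X[:, 1 + lin[i]] for i in range(n_factors)])
        else:
            raise ValueError("pass `codes` when the matrix lacks all linear columns")
    return _fit_terms(
        np.asarray(codes, dtype=float), terms, y, response_name,
        matrix.factors, matrix.terms, eliminated=[], aliased=aliased,
    )


def _p_for_elimination(tc: TermCoefficient) -> float:
    # a NaN p-value (zero residual variance / zero SE) gives no evidence
    # the term is needed, so treat it as maximally removable
    return 1.0 if math.isnan(tc.p_value) else tc.p_value


def backward_eliminate(fit: QuadraticFit, alpha: float = 0.05) -> QuadraticFit:
    """Iteratively drop the least significant removable term with p > alpha.

    Weak heredity: a linear term is not removable while its quadratic or
    any interaction involving its factor is retained; interactions and
    quadratics are always removable.  The model is refit after every
    removal; elimination stops when every removable term has p <= alpha
    (the model may reduce to the intercept alone).  Idempotent.
    """
    if fit._codes is None or fit._y is None:
        raise ValueError("fit does not carry its design; refit with fit_quadratic")
    current = fit
    while True:
        protected: set[int] = set()
        for tc in current.terms:
            if tc.term.kind == "quadratic":
                protected.add(tc.term.i)
            elif tc.term.kind == "interaction":
                protected.add(tc.term.i)
                protected.add(tc.term.j)
        candidates = [
            tc for tc in current.terms
            if _p_for_elimination(tc) > alpha
            and not (tc.term.kind == "linear" and tc.term.i in protected)
        ]
        if not candidates:
            return current
        worst = max(candidates, key=_p_for_elimination)
        remaining = [tc.term for tc in current.terms if tc.term != worst.term]
        eliminated = current.eliminated + [worst.term.label(current.factors)]
        if remaining:
            current = _fit_terms(
                current._codes, remaining, current._y, current.response_name,
                current.factors, current.full_terms, eliminated, current.aliased,
            )
        else:
            y = current._y
            n = len(y)
            resid = y - y.mean()
            current = QuadraticFit(
                response_name=current.response_name,
                intercept=float(y.mean()),
                intercept_se=float(resid.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
                terms=[],
                df_residual=n - 1,
                r2_adj=0.0,
                eliminated=eliminated,
                aliased=current.aliased,
                factors=current.factors,
                full_terms=current.full_terms,
                _codes=current._codes,
                _y=y,
            )
            return current


def standardized_effects_table(fits: dict[str, QuadraticFit]) -> pd.DataFrame:
    """Report table of standardized effects, one column per response.

    Rows follow the screening-report layout: the linear and quadratic term
    of each factor in design order, then every two-way interaction, then
    residual degrees of freedom and adjusted R^2.  Eliminated (or aliased)
    terms show a dash.
    """
    if not fits:
        raise ValueError("at least one fit required")
    first = next(iter(fits.values()))
    factors = first.factors
    n_factors = (
        len(factors)
        if factors is not None
        else 1 + max(max(t.i, t.j if t.j is not None else 0) for t in first.full_terms)
    )
    has_interactions = any(t.kind == "interaction" for t in first.full_terms)
    rows: list[Term] = []
    for i in range(n_factors):
        rows.append(Term("linear", i))
        rows.append(Term("quadratic", i))
    if has_interactions:
        for i in range(n_factors):
            for j in range(i + 1, n_factors):
                rows.append(Term("interaction", i, j))
    labels = [t.label(factors) for t in rows]
    table: dict[str, list[object]] = {}
    for name, fit in fits.items():
        by_term = fit.term_map()
        col: list[object] = []
        for t in rows:
            tc = by_term.get(t)
            col.append(round(tc.standardized_effect, 3) if tc is not None else "-")
        col.append(fit.df_residual)
        col.append(round(fit.r2_adj, 3))
        table[name] = col
    return pd.DataFrame(table, index=labels + ["df_residual", "r2_adj"])


def predict_surface(
    fit: QuadraticFit,
    factor_a: str,
    factor_b: str,
    resolution: int = 21,
    others_at: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Predicted response over a coded [-1, 1]^2 grid for two factors.

    Remaining factors are fixed at ``others_at`` (coded; default 0).
    ``predicted_nonneg`` floors negative predictions at 0, the overlay
    used to read predicted growth inhibition off rate surfaces.
    """
    if fit.factors is None:
        raise ValueError("fit carries no factor metadata")
    names = [f.name for f in fit.factors]
    for fname in (factor_a, factor_b):
        if fname not in names:
            raise KeyError(f"unknown factor {fname!r}")
    ia, ib = names.index(factor_a), names.index(factor_b)
    others_at = others_at or {}
    base = np.zeros(len(names))
    for fname, code in others_at.items():
        if fname not in names:
            raise KeyError(f"unknown factor {fname!r}")
        base[names.index(fname)] = code
    grid = np.linspace(-1.0, 1.0, resolution)
    records = []
    for ca in grid:
        for cb in grid:
            point = base.copy()
            point[ia], point[ib] = ca, cb
            yhat = float(fit.predict(point)[0])
            records.append(
                {
                    f"{factor_a}_coded": ca,
                    f"{factor_b}_coded": cb,
                    "predicted": yhat,
                    "predicted_nonneg": max(0.0, yhat),
                }
            )
    return pd.DataFrame(records)
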