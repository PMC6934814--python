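"""Exhaustive lag-combination search for the linearized additive calculator.

Each macronutrient may act on the response with a delay ("precedence
period") of 0..max_lag whole years. For a life period, the calculator is fit
at *every* combination of per-nutrient lags — (max_lag+1)^5 ordinary
least-squares fits of the response on the five lag-shifted availability
columns plus an intercept — and the combination with the highest multiple
correlation R = sqrt(R²) is selected.

Implementation note on speed: with contiguous years, a response year t is
usable for lag vector (l1..l5) iff t − max(l) is inside the availability
span, so the usable window depends only on max(l). The scan therefore groups
lag vectors by their maximum, precomputes centered cross-product (Gram)
tables over each group's window for every (nutrient, lag) column pair, and
obtains each vector's R² from a batched 5×5 normal-equation solve. This is
algebraically identical to fitting each design by least squares, and the
equivalence is enforced by tests against direct per-vector fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    N_NUTRIENTS,
    NUTRIENTS,
    AnalysisConfig,
    CollinearityError,
    InsufficientDataError,
    LifePeriod,
    NutrientSeries,
    RSeries,
)

LagVector = tuple[int, ...]


@dataclass(frozen=True)
class CalculatorFit:
    """One fitted calculator equation: r(t) = alpha + sum_i beta_i·x_i(t−lag_i).

    ``r_fit`` is the non-negative multiple correlation sqrt(R²), unadjusted,
    defined as 0 when the response is constant.
    """

    alpha: float
    betas: np.ndarray
    r_fit: float
    lags: LagVector | None = None
    period: LifePeriod | None = None
    n_obs: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", np.asarray(self.betas, dtype=float))

    def predict(self, grams: np.ndarray) -> float | np.ndarray:
        grams = np.asarray(grams, dtype=float)
        return self.alpha + grams @ self.betas

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "betas": dict(zip(NUTRIENTS, self.betas.tolist())),
            "r_fit": float(self.r_fit),
            "lags": list(self.lags) if self.lags is not None else None,
            "period": self.period.name if self.period is not None else None,
            "n_obs": int(self.n_obs),
        }


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of the exhaustive scan over one life period.

    ``r_grid`` holds sqrt(R²) for every lag vector, shaped
    ``(max_lag+1,)*5`` and indexed by the lag vector itself; vectors with too
    few usable years are NaN ("unusable", recorded, never silently skipped).
    """

    period: LifePeriod
    max_lag: int
    r_grid: np.ndarray
    optimal_lags: LagVector
    r_optimal: float
    optimal_fit: CalculatorFit
    usable_count: int
    unusable_count: int

    def to_dict(self) -> dict:
        return {
            "period": {
                "name": self.period.name,
                "start_year": self.period.start_year,
                "end_year": self.period.end_year,
            },
            "max_lag": int(self.max_lag),
            "optimal_lags": dict(zip(NUTRIENTS, [int(v) for v in self.optimal_lags])),
            "r_optimal": float(self.r_optimal),
            "optimal_fit": self.optimal_fit.to_dict(),
            "usable_count": int(self.usable_count),
            "unusable_count": int(self.unusable_count),
        }


def count_lag_combinations(max_lag: int, n_nutrients: int = N_NUTRIENTS) -> int:
    """Number of lag vectors on the full grid: (max_lag + 1)^n_nutrients."""
    if max_lag < 0 or n_nutrients < 1:
        raise ValueError("max_lag must be >= 0 and n_nutrients >= 1")
    return (max_lag + 1) ** n_nutrients


def _usable_years(
    series: NutrientSeries, r: RSeries, period: LifePeriod, max_component: int
) -> np.ndarray:
    """Response years inside the period with full lagged coverage."""
    start = max(period.start_year, r.start_year, series.start_year + max_component)
    end = min(period.end_year, r.end_year, series.end_year)
    if start > end:
        return np.empty(0, dtype=int)
    return np.arange(start, end + 1)


def shift_alignment(
    series: NutrientSeries,
    r: RSeries,
    lags: LagVector,
    period: LifePeriod,
    min_rows: int = 7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair the response with lag-shifted predictors over one life period.

    Returns ``(X, y, years)`` where row t pairs r(t) with x_i(t − lag_i).
    Years whose lagged predictors fall outside the availability span are
    dropped; fewer than ``min_rows`` surviving rows raises
    :class:`InsufficientDataError`.
    """
    lags = tuple(int(v) for v in lags)
    if len(lags) != N_NUTRIENTS or any(l < 0 for l in lags):
        raise ValueError("lags must be 5 non-negative integers")
    years = _usable_years(series, r, period, max(lags))
    if years.size < min_rows:
        raise InsufficientDataError(
            f"period {period.name}, lags {lags}: {years.size} usable rows "
            f"(< {min_rows})"
        )
    X = np.column_stack(
        [series.values[years - lag - series.start_year, i] for i, lag in enumerate(lags)]
    )
    return X, r.at(years), years


def fit_calculator(
    X: np.ndarray,
    y: np.ndarray,
    lags: LagVector | None = None,
    period: LifePeriod | None = None,
    min_rows: int = 7,
) -> CalculatorFit:
    """Least-squares fit of the linearized additive calculator.

    The smooth per-nutrient terms of the additive model are linearized, so
    the fit is ordinary least squares of the response on an intercept plus
    the five predictor columns. ``r_fit`` is sqrt(R²); a constant response
    gives r_fit = 0 with zero coefficients; a rank-deficient design raises
    :class:`CollinearityError` naming the dependent columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape != (n, N_NUTRIENTS):
        raise ValueError(f"design must be (n, {N_NUTRIENTS})")
    if n < min_rows:
        raise InsufficientDataError(f"{n} rows < minimum {min_rows}")
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise CollinearityError(
            "rank-deficient design; dependent columns: "
            + ", ".join(_collinear_columns(A))
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if np.all(y == y[0]):  # exactly constant response (float-exact test)
        return CalculatorFit(
            alpha=float(y.mean()),
            betas=np.zeros(N_NUTRIENTS),
            r_fit=0.0,
            lags=lags,
            period=period,
            n_obs=n,
        )
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return CalculatorFit(
        alpha=float(coef[0]),
        betas=coef[1:],
        r_fit=float(np.sqrt(np.clip(r2, 0.0, 1.0))),
        lags=lags,
        period=period,
        n_obs=n,
    )


def _collinear_columns(A: np.ndarray) -> list[str]:
    """Columns of the intercept-augmented design in the span of the others."""
    names = ["intercept", *NUTRIENTS]
    out = []
    for j in range(1, A.shape[1]):
        others = np.delete(A, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, A[:, j], rcond=None)
        resid = A[:, j] - others @ coef
        scale = max(float(np.abs(A[:, j]).max()), 1.0)
        if np.abs(resid).max() < 1e-8 * scale:
            out.append(names[j])
    return out or ["<undetermined>"]


def _lex_lag_grid(L: int) -> np.ndarray:
    """All lag vectors on [0, L)⁵ in lexicographic order, shape (L^5, 5)."""
    idx = np.arange(L**N_NUTRIENTS)
    out = np.empty((idx.size, N_NUTRIENTS), dtype=np.int64)
    for i in range(N_NUTRIENTS):
        out[:, i] = (idx // L ** (N_NUTRIENTS - 1 - i)) % L
    return out


def _group_r2(
    series: NutrientSeries,
    r: RSeries,
    years: np.ndarray,
    max_component: int,
    sub: np.ndarray,
) -> np.ndarray:
    """R² for the lag vectors ``sub``, all sharing the response window ``years``.

    Uses centered Gram tables over the shared window and batched 5×5
    normal-equation solves; near-singular systems fall back to the
    pseudoinverse (same fitted subspace, hence same R²).
    """
    offs = years - series.start_year
    k = np.arange(max_component + 1)
    # Am[i, k, t] = availability of nutrient i at year t − k
    Am = series.values[offs[None, :] - k[:, None], :].transpose(2, 0, 1)
    Ac = Am - Am.mean(axis=2, keepdims=True)
    y = r.at(years)
    if np.all(y == y[0]):  # constant response: r_fit defined as 0
        return np.zeros(sub.shape[0])
    yc = y - y.mean()
    syy = float(yc @ yc)
    C = np.einsum("ikn,jln->ikjl", Ac, Ac)
    cy = np.einsum("ikn,n->ik", Ac, yc)
    ii = np.arange(N_NUTRIENTS)
    Sxx = C[ii[None, :, None], sub[:, :, None], ii[None, None, :], sub[:, None, :]]
    sxy = cy[ii[None, :], sub]
    try:
        beta = np.linalg.solve(Sxx, sxy[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = (np.linalg.pinv(Sxx) @ sxy[..., None])[..., 0]
    r2 = np.einsum("ni,ni->n", beta, sxy) / syy
    bad = ~np.isfinite(r2) | (r2 > 1.0 + 1e-8)
    if np.any(bad):
        beta_b = (np.linalg.pinv(Sxx[bad]) @ sxy[bad][..., None])[..., 0]
        r2[bad] = np.einsum("ni,ni->n", beta_b, sxy[bad]) / syy
    return np.clip(r2, 0.0, 1.0)


def global_optimize(
    series: NutrientSeries,
    r: RSeries,
    period: LifePeriod,
    config: AnalysisConfig | None = None,
) -> OptimizationResult:
    """Evaluate every lag vector on the grid and select the best fit.

    Every vector on the (max_lag+1)^5 grid is either fitted or recorded as
    unusable (too few covered years); the argmax of r_fit is returned, ties
    broken by the lexicographically smallest lag vector. The result is
    deterministic and independent of evaluation order.
    """
    config = config or AnalysisConfig()
    L = config.max_lag + 1
    lags_all = _lex_lag_grid(L)
    n_total = lags_all.shape[0]
    r2_flat = np.full(n_total, np.nan)

    if config.coverage == "common_window":
        years = _usable_years(series, r, period, config.max_lag)
        if years.size >= config.min_rows:
            r2_flat[:] = _group_r2(series, r, years, config.max_lag, lags_all)
    else:
        m_all = lags_all.max(axis=1)
        for m in range(L):
            sel = np.nonzero(m_all == m)[0]
            years = _usable_years(series, r, period, m)
            if years.size < config.min_rows:
                continue  # whole group unusable, stays NaN
            r2_flat[sel] = _group_r2(series, r, years, m, lags_all[sel])

    usable = int(np.count_nonzero(np.isfinite(r2_flat)))
    if usable == 0:
        raise InsufficientDataError(
            f"period {period.name}: no lag combination has {config.min_rows}+ "
            "usable rows"
        )
    r_flat = np.sqrt(r2_flat)
    best = int(np.nanargmax(r_flat))  # first occurrence = lexicographically smallest
    optimal_lags = tuple(int(v) for v in lags_all[best])
    X, y, _ = shift_alignment(series, r, optimal_lags, period, config.min_rows)
    fit = fit_calculator(X, y, lags=optimal_lags, period=period, min_rows=config.min_rows)
    return OptimizationResult(
        period=period,
        max_lag=config.max_lag,
        r_grid=r_flat.reshape((L,) * N_NUTRIENTS),
        optimal_lags=optimal_lags,
        r_optimal=float(r_flat[best]),
        optimal_fit=fit,
        usable_count=usable,
        unusable_count=n_total - usable,
    )


def evaluate_lag_vectors(
    series: NutrientSeries,
    r: RSeries,
    period: LifePeriod,
    vectors: np.ndarray,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """r_fit from a direct per-vector least-squares fit; NaN where unusable.

    This is the plain one-fit-per-vector route, useful for spot-checking the
    grouped scan on arbitrary subsets of the grid.
    """
    config = config or AnalysisConfig()
    vectors = np.asarray(vectors, dtype=int)
    out = np.full(vectors.shape[0], np.nan)
    for j, vec in enumerate(vectors):
        try:
            X, y, _ = shift_alignment(series, r, tuple(vec), period, config.min_rows)
            out[j] = fit_calculator(X, y, min_rows=config.min_rows).r_fit
        except InsufficientDataError:
            pass
    return out
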