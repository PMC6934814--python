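"""Synthetic availability panels and correlation series with known truth.

Every downstream stage (lag optimization, confidence sequencing, diet
optimization) is exercised against data whose generative parameters — true
lags, intercept, per-gram coefficients, noise level — are known, so parameter
recovery can be checked exactly. The generator emulates the structure of the
historical US series: slow multi-decade trends (linear drift plus one
sinusoid per nutrient) with additive Gaussian noise, and a response built as
an intercept plus a linear combination of lag-shifted availabilities plus
noise, clamped to the valid correlation range.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64 (``numpy.random.default_rng``), which is versioned and reproducible
across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    N_NUTRIENTS,
    NUTRIENTS,
    LifePeriod,
    NutrientSeries,
    RSeries,
    ValidationError,
)

#: Full-span fitting window used by ground-truth validation studies.
FULL_SPAN = LifePeriod("full_span", 1929, 2005)


@dataclass(frozen=True)
class TrendSpec:
    """Deterministic trend of one nutrient: baseline + slope·t + sinusoid.

    ``baseline`` is grams/day at the first year; ``slope`` grams/year;
    ``amplitude`` grams and ``period_years``/``phase`` shape the slow
    oscillation.
    """

    baseline: float
    slope: float = 0.0
    amplitude: float = 0.0
    period_years: float = 40.0
    phase: float = 0.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (
            self.baseline
            + self.slope * t
            + self.amplitude * np.sin(2 * np.pi * t / self.period_years + self.phase)
        )


#: Default trends, loosely matching the scale of the 1929-2005 US
#: availability series: carbohydrates near 450 g with a slow dip and
#: recovery, protein near 95 g, the three fat classes between 20 and 60 g
#: with mild growth.
DEFAULT_TRENDS: tuple[TrendSpec, ...] = (
    TrendSpec(baseline=450.0, slope=-0.4, amplitude=30.0, period_years=55.0, phase=0.8),
    TrendSpec(baseline=95.0, slope=0.15, amplitude=6.0, period_years=42.0, phase=2.1),
    TrendSpec(baseline=50.0, slope=0.10, amplitude=5.0, period_years=33.0, phase=4.0),
    TrendSpec(baseline=48.0, slope=0.25, amplitude=4.0, period_years=27.0, phase=1.2),
    TrendSpec(baseline=18.0, slope=0.30, amplitude=2.0, period_years=22.0, phase=5.3),
)

#: Default availability noise (grams/day), a few percent of the fat series.
DEFAULT_AVAILABILITY_NOISE_SD = 5.0

#: Stationary availability used by ground-truth validation studies: constant
#: baselines with iid year-to-year variation and no secular trend. Lag
#: recovery in the strong sense — all three confidence criteria agreeing on
#: the true lag — requires lag-shifted copies of a column to be statistically
#: distinguishable, and a slow multi-decade trend makes neighbouring lags
#: near-duplicates (that graded ambiguity is precisely what the star scale
#: expresses on real data). Validation therefore uses the white-dominated
#: configuration, while :data:`DEFAULT_TRENDS` keeps the realistic slow
#: trends for emulation.
VALIDATION_TRENDS: tuple[TrendSpec, ...] = tuple(
    TrendSpec(baseline=spec.baseline) for spec in DEFAULT_TRENDS
)

#: Availability noise of the validation configuration (grams/day).
VALIDATION_NOISE_SD = 10.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth generative parameters behind a synthetic response series."""

    true_lags: tuple[int, ...]
    alpha: float
    betas: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_lags) != N_NUTRIENTS or len(self.betas) != N_NUTRIENTS:
            raise ValidationError("true_lags and betas need one entry per nutrient")
        if any(l < 0 for l in self.true_lags):
            raise ValidationError("true_lags must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def synth_availability(
    start_year: int = 1929,
    end_year: int = 2005,
    trends: tuple[TrendSpec, ...] = DEFAULT_TRENDS,
    noise_sd: float = DEFAULT_AVAILABILITY_NOISE_SD,
    seed: int = 0,
) -> NutrientSeries:
    """Generate a yearly availability panel with trend + Gaussian noise.

    Values are clipped at zero so the panel always satisfies the
    non-negativity invariant. Fixed seed gives an identical panel.
    """
    if end_year < start_year:
        raise ValidationError("end_year must be >= start_year")
    if len(trends) != N_NUTRIENTS:
        raise ValidationError("need one TrendSpec per nutrient")
    years = np.arange(start_year, end_year + 1)
    t = years - start_year
    rng = np.random.default_rng(seed)
    values = np.column_stack([spec.evaluate(t) for spec in trends])
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return NutrientSeries(years=years, values=np.clip(values, 0.0, None))


def synth_roriginal(
    series: NutrientSeries,
    truth: SyntheticTruth,
    start_year: int | None = None,
    end_year: int | None = None,
) -> RSeries:
    """Generate a response series from lag-shifted availabilities.

    r(t) = alpha + sum_i beta_i · x_i(t − lag_i) + Normal(0, noise_sd²),
    clamped to [−1, 1]. The response span defaults to the widest span the
    availability panel can back-cover: it starts max(true_lags) years after
    the panel starts.
    """
    max_lag = max(truth.true_lags)
    start = series.start_year + max_lag if start_year is None else start_year
    end = series.end_year if end_year is None else end_year
    if start > end:
        raise ValidationError("synth_roriginal: empty response span")
    years = np.arange(start, end + 1)
    for i, lag in enumerate(truth.true_lags):
        needed = years - lag
        if needed[0] < series.start_year or needed[-1] > series.end_year:
            first_bad = int(
                years[(needed < series.start_year) | (needed > series.end_year)][0]
            )
            raise ValidationError(
                f"synth_roriginal: availability does not back-cover year "
                f"{first_bad} for {NUTRIENTS[i]} at lag {lag}"
            )
    r = np.full(years.shape, truth.alpha)
    for i, (lag, beta) in enumerate(zip(truth.true_lags, truth.betas)):
        r = r + beta * series.values[years - lag - series.start_year, i]
    rng = np.random.default_rng(truth.seed)
    r = r + rng.normal(0.0, truth.noise_sd, size=r.shape)
    return RSeries(years=years, r=np.clip(r, -1.0, 1.0))


@dataclass(frozen=True)
class StatePanel:
    """State-level panel: income per state-year, death rate per state.

    ``pcpi`` has shape (n_states, n_years); ``aadr`` one value per state.
    A per-year cross-state Pearson correlation of the two reproduces the
    construction of the response series from raw state data.
    """

    states: tuple[str, ...]
    years: np.ndarray
    pcpi: np.ndarray
    aadr: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        pcpi = np.asarray(self.pcpi, dtype=float)
        aadr = np.asarray(self.aadr, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "pcpi", pcpi)
        object.__setattr__(self, "aadr", aadr)
        _ns = len(self.states)
        if pcpi.shape != (_ns, years.size):
            raise ValidationError("StatePanel: pcpi must be (n_states, n_years)")
        if aadr.shape != (_ns,):
            raise ValidationError("StatePanel: aadr needs one value per state")
        if years.size > 1 and not np.all(np.diff(years) == 1):
            raise ValidationError("StatePanel: years must be contiguous")


def synth_state_panel(
    n_states: int = 48,
    start_year: int = 1929,
    end_year: int = 2005,
    coupling: float = 0.5,
    seed: int = 0,
) -> StatePanel:
    """Generate a state panel whose death rates track final-year income.

    Each state's income follows exponential growth with state-specific level
    and idiosyncratic year-to-year noise. The per-state death rate is a
    mixture ``coupling · z + sqrt(1 − coupling²) · noise`` of the
    standardized final-year income ``z`` and independent noise, so
    ``coupling`` is exactly the expected cross-state correlation in the
    final year; at coupling = 1 the correlation is 1 by construction.
    """
    if n_states < 3:
        raise ValidationError("synth_state_panel: need at least 3 states")
    if not -1.0 <= coupling <= 1.0:
        raise ValidationError("synth_state_panel: coupling must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    t = years - start_year
    levels = rng.lognormal(mean=0.0, sigma=0.3, size=n_states)
    growth = rng.normal(0.04, 0.005, size=n_states)
    shocks = rng.normal(0.0, 0.05, size=(n_states, years.size))
    pcpi = 700.0 * levels[:, None] * np.exp(growth[:, None] * t[None, :] + shocks)
    z = pcpi[:, -1] - pcpi[:, -1].mean()
    z = z / z.std()
    noise = rng.normal(0.0, 1.0, size=n_states)
    noise = (noise - noise.mean()) / noise.std()
    mix = coupling * z + np.sqrt(max(0.0, 1.0 - coupling**2)) * noise
    aadr = 20.0 + 5.0 * mix  # deaths per 100,000, centered on a plausible rate
    states = tuple(f"S{i:02d}" for i in range(n_states))
    return StatePanel(states=states, years=years, pcpi=pcpi, aadr=aadr)


def compute_roriginal(panel: StatePanel) -> RSeries:
    """Per-year Pearson correlation across states of income vs. death rate.

    Years in which income is constant across states have an undefined
    correlation; they are emitted as NaN with a warning.
    """
    if len(panel.states) < 3:
        raise ValidationError("compute_roriginal: need at least 3 states")
    x = panel.pcpi - panel.pcpi.mean(axis=0, keepdims=True)
    y = panel.aadr - panel.aadr.mean()
    sx = np.sqrt((x**2).sum(axis=0))
    sy = np.sqrt((y**2).sum())
    r = np.full(panel.years.size, np.nan)
    ok = (sx > 0) & (sy > 0)
    num = (x * y[:, None]).sum(axis=0)
    r[ok] = num[ok] / (sx[ok] * sy)
    if not np.all(ok):
        bad = panel.years[~ok].tolist()
        warnings.warn(
            f"compute_roriginal: correlation undefined (constant column) in years {bad}",
            stacklevel=2,
        )
    # float round-off can push |r| epsilon past 1
    return RSeries(years=panel.years, r=np.clip(r, -1.0, 1.0))


def synth_dataset(
    truth: SyntheticTruth,
    start_year: int = 1929,
    end_year: int = 2005,
    trends: tuple[TrendSpec, ...] = DEFAULT_TRENDS,
    availability_noise_sd: float = DEFAULT_AVAILABILITY_NOISE_SD,
) -> tuple[NutrientSeries, RSeries]:
    """Convenience: availability panel + matching response from one truth.

    The availability panel is extended ``max(true_lags)`` years before
    ``start_year`` so the response covers the full requested span.
    """
    max_lag = max(truth.true_lags)
    series = synth_availability(
        start_year=start_year - max_lag,
        end_year=end_year,
        trends=trends,
        noise_sd=availability_noise_sd,
        seed=truth.seed,
    )
    r = synth_roriginal(series, truth, start_year=start_year, end_year=end_year)
    return series, r


def random_truth(
    rng: np.random.Generator,
    max_lag: int = 5,
    noise_sd: float = 0.0,
    trends: tuple[TrendSpec, ...] = DEFAULT_TRENDS,
    availability_noise_sd: float = DEFAULT_AVAILABILITY_NOISE_SD,
    target_contribution_sd: float = 0.08,
    span_years: int = 77,
    center_range: tuple[float, float] = (-0.2, 0.4),
) -> SyntheticTruth:
    """Draw a random ground truth with lags on [0, max_lag].

    Coefficients are balanced: each beta is scaled by the inverse of its
    nutrient's expected within-span variability, so every nutrient moves the
    response by roughly ``target_contribution_sd`` correlation units (±20%).
    Without balancing, gram-scaled coefficients let the wide carbohydrate
    series dominate and the narrow polyunsaturated-fat series contribute
    less than finite-sample fluctuation, making its lag unidentifiable in
    principle. The intercept is calibrated against the trend baselines so
    the noiseless response stays inside [−1, 1]: a response flattened by the
    clamp carries no lag information and would make any truth unrecoverable
    by construction.
    """
    lags = tuple(int(v) for v in rng.integers(0, max_lag + 1, size=N_NUTRIENTS))
    column_sd = np.array(
        [
            np.sqrt(
                availability_noise_sd**2
                + spec.amplitude**2 / 2.0
                + (spec.slope * span_years) ** 2 / 12.0
            )
            for spec in trends
        ]
    )
    signs = rng.choice([-1.0, 1.0], size=N_NUTRIENTS)
    betas = signs * rng.uniform(0.9, 1.1, N_NUTRIENTS) * target_contribution_sd / column_sd
    baselines = np.array([spec.baseline for spec in trends])
    center = rng.uniform(*center_range)
    alpha = float(center - betas @ baselines)
    return SyntheticTruth(
        true_lags=lags,
        alpha=alpha,
        betas=tuple(float(b) for b in betas),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def synth_validation_dataset(
    seed: int,
    max_lag: int = 5,
    noise_sd: float = 0.0,
    start_year: int = 1929,
    end_year: int = 2005,
) -> tuple[NutrientSeries, RSeries, SyntheticTruth]:
    """One ground-truth dataset under the stationary validation configuration.

    Uses :data:`VALIDATION_TRENDS` and :data:`VALIDATION_NOISE_SD` with a
    balanced random truth; the standard fitting window for validation
    studies is the full response span (77 years by default). The response
    center and per-nutrient contributions are kept small enough that the
    [−1, 1] clamp essentially never engages — a clamped year would make an
    otherwise noiseless response inexactly linear.
    """
    rng = np.random.default_rng(seed)
    truth = random_truth(
        rng,
        max_lag=max_lag,
        noise_sd=noise_sd,
        trends=VALIDATION_TRENDS,
        availability_noise_sd=VALIDATION_NOISE_SD,
        target_contribution_sd=0.08,
        center_range=(-0.15, 0.15),
    )
    series, r = synth_dataset(
        truth,
        start_year=start_year,
        end_year=end_year,
        trends=VALIDATION_TRENDS,
        availability_noise_sd=VALIDATION_NOISE_SD,
    )
    return series, r, truth
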