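"""Turnover kinetics: exponential-rise fits, rate comparison, growth correction.

At steady state, the fraction of newly synthesized protein follows a
single-exponential rise to complete replacement,

    f(t) = 1 - exp(-k_obs * t),        k_obs = ln 2 / t_half,

where ``k_obs`` is the fractional synthesis rate. In proliferating cells,
synthesis serves both cell growth and replacement of degraded protein, and
the contributions are additive:

    k_obs = k_cell + k_TO,

with ``k_cell`` the fractional cell growth rate (ln 2 / doubling time, from
exponential growth curves) and ``k_TO`` the fractional protein turnover
rate (ln 2 / turnover half-life). In non-proliferating cells k_cell = 0 and
fractional synthesis equals turnover.

Whether two or more peptide time courses share a single rate is decided by
the extra-sum-of-squares F test between the pooled (one shared k) and
separate (one k per series) nested models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError

__all__ = [
    "FractionalSynthesisSeries",
    "KineticFitResult",
    "GrowthFit",
    "TurnoverEstimate",
    "RateComparison",
    "fit_single_exponential",
    "compare_rates_f_test",
    "fit_exponential_growth",
    "correct_for_growth",
]

LN2 = float(np.log(2.0))

Weighting = Literal["none", "inverse_variance"]


@dataclass(frozen=True)
class FractionalSynthesisSeries:
    """A labeled time course for one peptide, allele, or isotype."""

    label: str
    times_h: tuple[float, ...]
    f: tuple[float, ...]
    sd: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.f):
            raise ValueError("times_h and f must have equal length")
        if self.sd is not None and len(self.sd) != len(self.f):
            raise ValueError("sd must match f in length")
        if any(t < 0 for t in self.times_h):
            raise ValueError("times must be >= 0")

    def __len__(self) -> int:
        return len(self.f)

    @staticmethod
    def concat(
        series: Sequence["FractionalSynthesisSeries"], label: str = "pooled"
    ) -> "FractionalSynthesisSeries":
        sds: tuple[float, ...] | None
        if all(s.sd is not None for s in series):
            sds = tuple(x for s in series for x in s.sd)
        else:
            sds = None
        return FractionalSynthesisSeries(
            label=label,
            times_h=tuple(t for s in series for t in s.times_h),
            f=tuple(x for s in series for x in s.f),
            sd=sds,
        )


@dataclass(frozen=True)
class KineticFitResult:
    """Nonlinear least-squares fit of f(t) = 1 - exp(-k t)."""

    label: str
    k_obs: float
    sem: float
    ci95: tuple[float, float]
    rss: float
    df: int
    n_points: int
    t_half_h: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth rate from log-linear regression of cell counts."""

    k_cell: float
    sem: float
    t_double_h: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TurnoverEstimate:
    """Growth-corrected protein turnover rate and half-life."""

    label: str
    k_obs: float
    k_cell: float
    k_to: float
    t_half_to_h: float
    sem_k_to: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RateComparison:
    """Extra-sum-of-squares F test: one shared rate vs one rate per series."""

    labels: tuple[str, ...]
    F: float
    df_num: int
    df_den: int
    p: float
    shared_fit: KineticFitResult
    separate_fits: tuple[KineticFitResult, ...]


def _weights(series: FractionalSynthesisSeries, weighting: Weighting) -> np.ndarray:
    n = len(series)
    if weighting == "none":
        return np.ones(n)
    if weighting == "inverse_variance":
        if series.sd is None:
            raise FitError("inverse-variance weighting requires per-point sd")
        sd = np.asarray(series.sd, dtype=float)
        # guard zero sds (noise-free points) with the smallest positive sd
        floor = sd[sd > 0].min() if np.any(sd > 0) else 1.0
        return 1.0 / np.maximum(sd, floor) ** 2
    raise ValueError(f"unknown weighting scheme {weighting!r}")


def _initial_k(t: np.ndarray, f: np.ndarray) -> float:
    mask = (t > 0) & (f > 0)
    if not np.any(mask):
        return 1e-3
    ff = np.clip(f[mask], None, 0.99)
    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = -np.log(1.0 - np.clip(ff, 0.0, 0.99)) / t[mask]
    k0 = k0[np.isfinite(k0) & (k0 > 0)]
    return float(np.median(k0)) if k0.size else 1e-3


def fit_single_exponential(
    series: FractionalSynthesisSeries,
    weighting: Weighting = "none",
) -> KineticFitResult:
    """Fit the fractional synthesis rate ``k_obs`` to one time course.

    Minimizes sum of w_i * (f_i - (1 - exp(-k t_i)))^2 over k >= 0 with the
    plateau fixed at 1 (complete replacement). The standard error comes
    from the linearized curvature at the optimum (s^2 / sum w J^2 with
    J = t exp(-k t)), df = n - 1, and the 95 % CI is the asymptotic
    t-interval.
    """
    if len(series) < 3:
        raise FitError(
            f"series {series.label!r}: need >= 3 points, got {len(series)}"
        )
    t = np.asarray(series.times_h, dtype=float)
    f = np.asarray(series.f, dtype=float)
    if t.max() - t.min() <= 0:
        raise FitError(f"series {series.label!r}: times span zero")
    w = _weights(series, weighting)
    sw = np.sqrt(w)

    def resid(k: np.ndarray) -> np.ndarray:
        return sw * (f - (1.0 - np.exp(-k[0] * t)))

    def jac(k: np.ndarray) -> np.ndarray:
        return (-sw * t * np.exp(-k[0] * t)).reshape(-1, 1)

    sol = optimize.least_squares(
        resid,
        x0=[_initial_k(t, f)],
        jac=jac,
        bounds=([0.0], [np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    k = float(sol.x[0])
    rss = float(np.sum(sol.fun**2))
    df = len(series) - 1
    s2 = rss / df if df > 0 else np.nan
    curvature = float(np.sum(w * (t * np.exp(-k * t)) ** 2))
    sem = float(np.sqrt(s2 / curvature)) if curvature > 0 else np.inf
    tcrit = float(stats.t.ppf(0.975, df)) if df > 0 else np.inf
    ci = (k - tcrit * sem, k + tcrit * sem)
    flags = set()
    if k < 1e-6:
        flags.add("no_detectable_synthesis")
    return KineticFitResult(
        label=series.label,
        k_obs=k,
        sem=sem,
        ci95=ci,
        rss=rss,
        df=df,
        n_points=len(series),
        t_half_h=LN2 / k if k > 0 else np.inf,
        flags=frozenset(flags),
    )


def compare_rates_f_test(
    series_group: Sequence[FractionalSynthesisSeries],
    weighting: Weighting = "none",
) -> RateComparison:
    """Extra-sum-of-squares F test across >= 2 time courses.

    The null (shared) model fits one k to the pooled points; the
    alternative fits one k per series. F has (df_shared - df_sep, df_sep)
    degrees of freedom. A large p supports pooling — the situation in which
    pooled estimates are reported as primary downstream.
    """
    if len(series_group) < 2:
        raise FitError("need >= 2 series to compare rates")
    shared = fit_single_exponential(
        FractionalSynthesisSeries.concat(series_group), weighting
    )
    separate = tuple(
        fit_single_exponential(s, weighting) for s in series_group
    )
    n_total = sum(len(s) for s in series_group)
    df_shared = n_total - 1
    df_sep = n_total - len(series_group)
    if df_sep <= 0:
        raise FitError("degenerate residual degrees of freedom in F test")
    rss_sep = sum(fit.rss for fit in separate)
    df_num = df_shared - df_sep
    if rss_sep <= 0:
        # perfect separate fits: F is infinite unless shared fit is also exact
        F = 0.0 if shared.rss <= 1e-30 else np.inf
    else:
        F = max(0.0, (shared.rss - rss_sep) / df_num / (rss_sep / df_sep))
    p = float(stats.f.sf(F, df_num, df_sep))
    return RateComparison(
        labels=tuple(s.label for s in series_group),
        F=float(F),
        df_num=df_num,
        df_den=df_sep,
        p=p,
        shared_fit=shared,
        separate_fits=separate,
    )


def fit_exponential_growth(
    counts: Sequence[tuple[float, float]],
) -> GrowthFit:
    """Exponential growth rate from (time_h, cells/ml) pairs.

    Linear regression of ln(count) on time; ``k_cell`` is the slope and the
    doubling time ln 2 / k_cell. A non-positive slope is clamped to zero
    and flagged ``non_proliferating`` (counts constant within noise).
    """
    if len(counts) < 3:
        raise FitError(f"need >= 3 count points, got {len(counts)}")
    t = np.asarray([c[0] for c in counts], dtype=float)
    n = np.asarray([c[1] for c in counts], dtype=float)
    if np.any(n <= 0):
        raise FitError("cell counts must be positive")
    res = stats.linregress(t, np.log(n))
    slope, sem = float(res.slope), float(res.stderr)
    flags = set()
    if slope <= 0 or not np.isfinite(slope):
        slope = 0.0
        flags.add("non_proliferating")
    k_cell = slope
    return GrowthFit(
        k_cell=k_cell,
        sem=sem,
        t_double_h=LN2 / k_cell if k_cell > 0 else np.inf,
        flags=frozenset(flags),
    )


def correct_for_growth(
    fit: KineticFitResult, growth: GrowthFit
) -> TurnoverEstimate:
    """Convert an observed synthesis rate into a turnover rate.

    ``k_TO = k_obs - k_cell``; when synthesis does not exceed growth the
    turnover rate is clamped at zero and flagged ``turnover_not_measurable``
    (all synthesis is accounted for by cell proliferation). The standard
    error combines both fit uncertainties in quadrature.
    """
    k_to = fit.k_obs - growth.k_cell
    flags = set(fit.flags)
    if k_to <= 0:
        k_to = 0.0
        flags.add("turnover_not_measurable")
    sem = float(np.sqrt(fit.sem**2 + growth.sem**2))
    return TurnoverEstimate(
        label=fit.label,
        k_obs=fit.k_obs,
        k_cell=growth.k_cell,
        k_to=k_to,
        t_half_to_h=LN2 / k_to if k_to > 0 else np.inf,
        sem_k_to=sem,
        flags=frozenset(flags),
    )
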