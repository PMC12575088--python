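"""Growth-physiology estimators.

Covers the bench-side quantities of a bacterial growth-physiology study:

* exponential growth rate lambda (h^-1, natural-log base) from OD600
  time series, fitted over the exponential OD window;
* total RNA per OD600 from OD260 (the standard perchloric-acid protocol
  coefficient: RNA [ug/ml/OD600] = OD260 * 31 / OD600);
* total protein from a BSA (biuret) standard curve;
* the RNA/protein ratio, the classic proxy for ribosome content;
* beta-galactosidase activity in Miller units;
* promoter-activity ratios between strains with first-order error
  propagation;
* lag time after a nutrient downshift by back-extrapolation of the
  post-shift steady exponential to the pre-shift OD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, DomainError, EstimationError, FitError

#: ug RNA per ml per OD600 unit, per unit OD260 (perchloric-acid extraction)
RNA_OD260_COEFFICIENT = 31.0


@dataclass
class GrowthCurve:
    """An OD600 time series with strictly increasing times in hours."""

    times: np.ndarray
    od600: np.ndarray
    strain: str = ""
    medium: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape or self.times.size < 3:
            raise DomainError("growth curve needs >= 3 matched (time, OD) points")
        if not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(self.od600 > 0):
            raise DomainError("OD600 values must be positive")


@dataclass
class GrowthFit:
    """Log-linear fit of an exponential growth window."""

    lam: float              # growth rate, h^-1
    intercept: float        # ln OD600 at t = 0
    r_squared: float
    window: tuple[int, ...]  # indices of the fitted points
    low_r2_warning: bool = False

    @property
    def doubling_time(self) -> float:
        """Doubling time ln2/lambda in hours (inf for lambda <= 0)."""
        return math.log(2.0) / self.lam if self.lam > 0 else math.inf


@dataclass
class LagEstimate:
    """Post-downshift lag by back-extrapolation of the late exponential."""

    lag: float           # hours, >= 0
    lambda_post: float   # h^-1 on the steady post-shift window
    t0: float
    r_squared: float
    window: tuple[int, ...] = ()


class ProteinAmount(NamedTuple):
    conc: float          # mg/ml
    extrapolated: bool   # reading outside the standards' OD range


class ActivityRatio(NamedTuple):
    ratio: float
    sd: float


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept, r^2; a perfectly flat y is a perfect fit."""
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_growth_rate(
    curve: GrowthCurve,
    od_window: tuple[float, float] = (0.05, 0.5),
    min_points: int = 4,
) -> GrowthFit:
    """Fit lambda as the OLS slope of ln OD600 vs time inside the OD window.

    Only points with OD600 in ``od_window`` (the usual exponential range)
    enter the fit. A fit with r^2 < 0.98 is flagged, not rejected.

    Raises
    ------
    FitError
        If fewer than ``min_points`` points fall inside the window.
    """
    lo, hi = od_window
    mask = (curve.od600 >= lo) & (curve.od600 <= hi)
    if int(mask.sum()) < min_points:
        raise FitError(
            f"only {int(mask.sum())} points inside OD window {od_window}, need {min_points}"
        )
    idx = np.flatnonzero(mask)
    slope, intercept, r2 = _linfit(curve.times[idx], np.log(curve.od600[idx]))
    return GrowthFit(
        lam=slope, intercept=intercept, r_squared=r2,
        window=tuple(int(i) for i in idx), low_r2_warning=r2 < 0.98,
    )


def rna_amount(od260: float, od600: float) -> float:
    """Total RNA in ug/ml/OD600: OD260 * 31 / OD600."""
    if od600 <= 0:
        raise DomainError("OD600 must be positive")
    if od260 < 0:
        raise DomainError("OD260 must be nonnegative")
    return od260 * RNA_OD260_COEFFICIENT / od600


def protein_amount(
    od555: float,
    bsa_standards: Sequence[tuple[float, float]],
) -> ProteinAmount:
    """Protein concentration (mg/ml) from a BSA standard curve.

    Standards are (concentration mg/ml, OD555) pairs, typically spanning
    0.4-2 mg/ml; the curve is an OLS line od555 = a*conc + b and the
    sample concentration is (od555 - b)/a. A reading outside the
    standards' OD range is flagged as extrapolated.

    Raises
    ------
    CalibrationError
        On fewer than two distinct standards or a flat standard curve.
    """
    if len(bsa_standards) < 2 or len({c for c, _ in bsa_standards}) < 2:
        raise CalibrationError("need >= 2 BSA standards at distinct concentrations")
    conc = np.array([c for c, _ in bsa_standards], dtype=float)
    od = np.array([o for _, o in bsa_standards], dtype=float)
    slope, intercept, _ = _linfit(conc, od)
    if slope == 0.0:
        raise CalibrationError("degenerate BSA standard curve (zero slope)")
    extrapolated = not (od.min() <= od555 <= od.max())
    return ProteinAmount(conc=(od555 - intercept) / slope, extrapolated=extrapolated)


def rna_protein_ratio(rna: float, protein: float) -> float:
    """RNA/protein mass ratio, the proxy for ribosome content."""
    if protein <= 0:
        raise DomainError("protein amount must be positive")
    if rna < 0:
        raise DomainError("RNA amount must be nonnegative")
    return rna / protein


def miller_units(od420: float, time_min: float, volume_ml: float, od600: float) -> float:
    """Beta-galactosidase activity: 1000 * OD420 / (t_min * V_ml * OD600).

    The classical Miller convention without the OD550 debris-correction
    term (no OD550 reading in this protocol).
    """
    if od420 < 0:
        raise DomainError("OD420 must be nonnegative")
    if time_min <= 0 or volume_ml <= 0 or od600 <= 0:
        raise DomainError("time, volume and OD600 must be positive")
    return 1000.0 * od420 / (time_min * volume_ml * od600)


def promoter_activity_ratio(
    activity_null: tuple[float, float],
    activity_wt: tuple[float, float],
) -> ActivityRatio:
    """Ratio of promoter activities (mean, sd) with propagated SD.

    First-order propagation: relative variances add, so
    sd(ratio) = ratio * sqrt((sd_n/mean_n)^2 + (sd_w/mean_w)^2).
    """
    mean_n, sd_n = activity_null
    mean_w, sd_w = activity_wt
    if mean_w <= 0:
        raise DomainError("wild-type activity mean must be positive")
    if sd_n < 0 or sd_w < 0:
        raise DomainError("standard deviations must be nonnegative")
    ratio = mean_n / mean_w
    rel = math.hypot(sd_n / mean_n if mean_n else 0.0, sd_w / mean_w)
    return ActivityRatio(ratio=ratio, sd=abs(ratio) * rel)


def estimate_lag_time(
    curve: GrowthCurve,
    t0: float | None = None,
    min_points: int = 4,
    min_r_squared: float = 0.99,
) -> LagEstimate:
    """Lag time after a nutrient downshift (back-extrapolation definition).

    The steady post-shift exponential is the trailing window (>= 4
    points) whose ln-OD-vs-time fit has the highest r^2 (ties broken
    toward the longer window); lambda_post is its slope. The lag is the
    time the back-extrapolated exponential crosses the OD at the shift,
    minus t0, clipped at 0:

        lag = (ln OD(t0) - intercept) / lambda_post - t0

    Raises
    ------
    EstimationError
        If no trailing window reaches ``min_r_squared``, or the fitted
        post-shift slope is not positive.
    """
    t = curve.times
    ln_od = np.log(curve.od600)
    if t0 is None:
        t0 = float(t[0])
    if t0 < t[0] or t0 > t[-1]:
        raise DomainError("t0 outside the recorded time range")
    ln_od0 = float(np.interp(t0, t, ln_od))

    n = t.size
    best: tuple[float, int] | None = None  # (r2, start index)
    fits: dict[int, tuple[float, float, float]] = {}
    for start in range(0, n - min_points + 1):
        slope, intercept, r2 = _linfit(t[start:], ln_od[start:])
        fits[start] = (slope, intercept, r2)
        # prefer higher r2; on a numerical tie keep the longer window
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, start)
    assert best is not None
    r2, start = best
    if r2 < min_r_squared:
        raise EstimationError(f"no steady exponential window found (best r^2 = {r2:.4f})")
    slope, intercept, _ = fits[start]
    if slope <= 0:
        raise EstimationError("post-shift window has nonpositive growth rate")
    lag = (ln_od0 - intercept) / slope - t0
    lag = max(0.0, lag)
    if lag > t[-1] - t0:
        raise EstimationError("estimated lag exceeds the post-shift record")
    return LagEstimate(
        lag=lag, lambda_post=slope, t0=t0, r_squared=r2,
        window=tuple(range(start, n)),
    )


def two_sample_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Unpaired two-sided t-test (Welch by default) -> (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("need >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
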