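"""Growth laws: the R-line and the coarse-grained Q/R/A partition model.

The R-line is the empirical linear relation between ribosome content
(measured as the RNA/protein mass ratio) and the exponential growth rate
across nutrient conditions. Strains that lie on the same line differ
only in where nutrient quality (or proteome burden) places them along
it; a shared-line F-test makes that comparison quantitative.

The partition model coarse-grains the proteome into a constant
housekeeping sector Q, a ribosomal/translation sector R, an
amino-acid-supply sector A and an optional useless-burden sector U:

    phi_Q + phi_U + phi_R + phi_A = 1
    lambda = gamma * (phi_R - phi_R0)      (translation flux)
    lambda = nu * phi_A                    (amino-acid supply flux)

where gamma is the translational efficiency, nu the nutrient-dependent
supply efficiency and phi_R0 an inactive-ribosome offset. At steady
state both fluxes balance, giving the closed form

    lambda = gamma * nu * (1 - phi_Q - phi_U - phi_R0) / (gamma + nu).

Derepressed protein that contributes nothing to growth enters as phi_U
and compresses R and A, reducing lambda linearly — the passive-burden
picture. In the supply-saturated limit nu -> inf this reduces to
lambda = lambda0 * (1 - phi_U / phi_max) with phi_max = 1 - phi_Q - phi_R0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, FitError


@dataclass
class RLineFit:
    """OLS fit of RNA/protein on growth rate lambda."""

    slope: float       # (RNA/protein) per (h^-1)
    intercept: float   # RNA/protein at lambda = 0
    r_squared: float
    n_points: int
    residuals: tuple[float, ...] = ()


@dataclass
class SharedLineTest:
    """F-test of one pooled R-line vs separate per-strain lines."""

    f_statistic: float
    p_value: float
    alpha: float
    shared: bool       # True if the pooled single line is not rejected


@dataclass(frozen=True)
class AllocationModel:
    """Parameters of the Q/R/A(/U) proteome-partition growth model.

    phi_Q : constant housekeeping fraction (dimensionless, in (0,1))
    gamma : translational efficiency, h^-1 per unit phi_R
    nu    : amino-acid supply efficiency, h^-1 per unit phi_A
    phi_U : useless-burden fraction (growth-irrelevant expression)
    phi_R0: inactive-ribosome offset fraction
    """

    phi_Q: float
    gamma: float
    nu: float
    phi_U: float = 0.0
    phi_R0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_Q < 1.0:
            raise DomainError("phi_Q must be in (0, 1)")
        if self.gamma <= 0 or self.nu <= 0:
            raise DomainError("gamma and nu must be positive")
        if self.phi_U < 0 or self.phi_R0 < 0:
            raise DomainError("phi_U and phi_R0 must be nonnegative")
        if self.phi_Q + self.phi_U + self.phi_R0 >= 1.0:
            raise DomainError("no allocatable proteome: phi_Q + phi_U + phi_R0 >= 1")


@dataclass
class ModelPrediction:
    """Steady-state growth rate and R/A allocation; sectors close to 1."""

    lam: float
    phi_R: float
    phi_A: float


def fit_rline(points: Sequence[tuple[float, float]]) -> RLineFit:
    """Fit the R-line: OLS of RNA/protein ratio on growth rate.

    Raises
    ------
    FitError
        If fewer than two distinct growth rates are provided.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise FitError("need >= 2 (lambda, RNA/protein) points")
    lam, rp = pts[:, 0], pts[:, 1]
    if np.ptp(lam) == 0.0:
        raise FitError("all growth rates identical; R-line undefined")
    if np.ptp(rp) == 0.0:
        slope, intercept, r2 = 0.0, float(rp[0]), 1.0
    else:
        res = stats.linregress(lam, rp)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    resid = rp - (intercept + slope * lam)
    return RLineFit(slope=slope, intercept=intercept, r_squared=r2,
                    n_points=int(pts.shape[0]), residuals=tuple(float(r) for r in resid))


def _sse(points: np.ndarray) -> float:
    lam, rp = points[:, 0], points[:, 1]
    if np.ptp(lam) == 0.0:
        return float(np.sum((rp - rp.mean()) ** 2))
    res = stats.linregress(lam, rp)
    return float(np.sum((rp - (res.intercept + res.slope * lam)) ** 2))


def compare_rlines(
    points_a: Sequence[tuple[float, float]],
    points_b: Sequence[tuple[float, float]],
    alpha: float = 0.05,
) -> SharedLineTest:
    """Do two strains share one R-line? Nested-model F-test.

    Compares the pooled single-line fit (2 parameters) against separate
    per-strain lines (4 parameters):

        F = ((SSE_pooled - SSE_separate) / 2) / (SSE_separate / (n - 4))

    ``shared`` is True when the pooled model is not rejected at ``alpha``.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    n = a.shape[0] + b.shape[0]
    if n < 5:
        raise FitError("need >= 5 points total for the shared-line F-test")
    sse_sep = _sse(a) + _sse(b)
    sse_pool = _sse(np.vstack([a, b]))
    df_sep = n - 4
    if sse_sep <= 0.0:
        # separate fits are exact; any pooled excess is infinitely significant
        f_stat = math.inf if sse_pool > sse_sep + 1e-30 else 0.0
        p = 0.0 if math.isinf(f_stat) else 1.0
    else:
        f_stat = ((sse_pool - sse_sep) / 2.0) / (sse_sep / df_sep)
        p = float(stats.f.sf(f_stat, 2, df_sep))
    return SharedLineTest(f_statistic=float(f_stat), p_value=p, alpha=alpha, shared=p >= alpha)


def steady_state(model: AllocationModel) -> ModelPrediction:
    """Steady-state growth rate and allocation of the Q/R/A(/U) model.

    Balances the translation flux gamma*(phi_R - phi_R0) against the
    supply flux nu*phi_A under phi_R + phi_A = 1 - phi_Q - phi_U:

        lambda = gamma*nu*(1 - phi_Q - phi_U - phi_R0) / (gamma + nu)
    """
    allocatable = 1.0 - model.phi_Q - model.phi_U - model.phi_R0
    if allocatable <= 0.0:
        raise DomainError("no allocatable proteome mass")
    lam = model.gamma * model.nu * allocatable / (model.gamma + model.nu)
    phi_R = lam / model.gamma + model.phi_R0
    phi_A = lam / model.nu
    return ModelPrediction(lam=lam, phi_R=phi_R, phi_A=phi_A)


def burden_growth(lambda0: float, phi_U: float, phi_max: float) -> float:
    """Growth rate under a useless-protein burden: lambda0*(1 - phi_U/phi_max).

    ``phi_max`` is the burden fraction that abolishes growth
    (= 1 - phi_Q - phi_R0 in the supply-saturated model).
    """
    if lambda0 <= 0:
        raise DomainError("lambda0 must be positive")
    if not 0.0 < phi_max <= 1.0:
        raise DomainError("phi_max must be in (0, 1]")
    if not 0.0 <= phi_U < phi_max:
        raise DomainError("phi_U must satisfy 0 <= phi_U < phi_max")
    return lambda0 * (1.0 - phi_U / phi_max)


def downshift_readiness(
    phi_A_pre: Mapping[str, float],
    model: AllocationModel,
) -> list[tuple[str, float]]:
    """Rank strains by preparedness for a downshift to minimal medium.

    The post-shift steady state demands an A-sector fraction phi_A*
    (from ``model``, parameterized for the minimal medium). A strain's
    readiness score is phi_A_pre / phi_A*; a higher score predicts a
    shorter lag. The prediction is ordinal only.

    Returns (strain, score) pairs sorted from shortest- to
    longest-predicted lag; equal scores keep input order (a tie).
    """
    target = steady_state(model).phi_A
    if target <= 0.0:
        raise DomainError("post-shift phi_A* must be positive")
    for strain, phi in phi_A_pre.items():
        if phi < 0:
            raise DomainError(f"negative pre-shift phi_A for {strain!r}")
    scores = [(strain, phi / target) for strain, phi in phi_A_pre.items()]
    return sorted(scores, key=lambda sp: -sp[1])
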