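"""Error-weighted line fits, slope/intercept t-tests, fold-change curves.

Per-bin rate estimates come with per-point standard errors, so straight
lines are fitted by minimizing chi^2 = sum(((y_i - b - m x_i)/sigma_i)^2)
with the classical closed-form normal-equation sums; the parameter standard
errors follow from the same sums (s_m^2 = S/Delta, s_b^2 = S_xx/Delta with
S = sum 1/sigma^2, Delta = S*S_xx - S_x^2).

Two fitted lines are compared on a parameter via
t = (p_1 - p_2) / sqrt(s_1^2 + s_2^2) against a two-tailed t-distribution
with n_1 + n_2 - 4 degrees of freedom; a single parameter is tested against
a null value with n - 2 degrees of freedom. For fold-change-versus-RSA
curves the natural nulls are slope = 0 (structure-independent effect) and
intercept = 1 (no effect among fully buried residues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "WeightedPoint",
    "LineFit",
    "ComparisonResult",
    "FoldChangePoint",
    "weighted_line_fit",
    "compare_line_params",
    "test_param_null",
    "fold_change_curve",
]


@dataclass
class WeightedPoint:
    x: float  # RSA percent
    y: float  # rate, fold change, or CAI ratio
    sigma: float  # standard error of y


@dataclass
class LineFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    n: int
    chi2: float


@dataclass
class ComparisonResult:
    t: float
    df: int
    p: float  # two-tailed
    parameter: str  # "slope" | "intercept"
    null_value: float | None = None


@dataclass
class FoldChangePoint:
    x: float
    ratio: float
    sigma: float


def _as_points(points) -> list[WeightedPoint]:
    out = []
    for p in points:
        if isinstance(p, WeightedPoint):
            out.append(p)
        else:
            x, y, s = p
            out.append(WeightedPoint(float(x), float(y), float(s)))
    return out


def weighted_line_fit(points) -> LineFit:
    """Chi^2-minimizing straight line with known per-point errors.

    Points with non-finite y or sigma <= 0 are excluded (and counted in a
    warning); at least 3 usable points with non-identical x are required.
    """
    pts = _as_points(points)
    usable = [
        p
        for p in pts
        if np.isfinite(p.x) and np.isfinite(p.y) and np.isfinite(p.sigma) and p.sigma > 0
    ]
    if len(usable) < len(pts):
        warnings.warn(
            f"excluded {len(pts) - len(usable)} points with undefined value or error",
            stacklevel=2,
        )
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable points, got {len(usable)}")
    x = np.array([p.x for p in usable])
    y = np.array([p.y for p in usable])
    sig = np.array([p.sigma for p in usable])
    if np.all(x == x[0]):
        raise ValueError("all x identical: no line defined")
    w = 1.0 / sig**2
    S = w.sum()
    Sx = (w * x).sum()
    Sy = (w * y).sum()
    # centered form of the normal-equation sums (algebraically identical to
    # slope = (S*Sxy - Sx*Sy)/Delta etc., but immune to cancellation when the
    # weights are large): t_i = (x_i - Sx/S)/sigma_i, Stt = Delta/S
    t = (x - Sx / S) / sig
    Stt = (t * t).sum()
    if Stt <= 0:
        raise ValueError("degenerate design: no line defined")
    slope = (t * y / sig).sum() / Stt
    intercept = (Sy - Sx * slope) / S
    se_slope = np.sqrt(1.0 / Stt)  # = sqrt(S/Delta)
    se_intercept = np.sqrt((1.0 + Sx * Sx / (S * Stt)) / S)  # = sqrt(Sxx/Delta)
    chi2 = float(np.sum(((y - intercept - slope * x) / sig) ** 2))
    return LineFit(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        n=len(usable),
        chi2=chi2,
    )


def _param(fit: LineFit, parameter: str) -> tuple[float, float]:
    if parameter == "slope":
        return fit.slope, fit.se_slope
    if parameter == "intercept":
        return fit.intercept, fit.se_intercept
    raise ValueError(f"parameter must be 'slope' or 'intercept', got {parameter!r}")


def compare_line_params(fit_a: LineFit, fit_b: LineFit, parameter: str) -> ComparisonResult:
    """Two-line parameter comparison: t with n_a + n_b - 4 degrees of freedom."""
    pa, sa = _param(fit_a, parameter)
    pb, sb = _param(fit_b, parameter)
    se = np.sqrt(sa**2 + sb**2)
    if se == 0:
        raise ValueError("zero combined standard error")
    t = (pa - pb) / se
    df = fit_a.n + fit_b.n - 4
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ComparisonResult(t=float(t), df=df, p=min(p, 1.0), parameter=parameter)


def test_param_null(fit: LineFit, parameter: str, null_value: float) -> ComparisonResult:
    """One-line parameter test against a null value: n - 2 degrees of freedom."""
    value, se = _param(fit, parameter)
    if se == 0:
        raise ValueError("zero standard error")
    t = (value - null_value) / se
    df = fit.n - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ComparisonResult(
        t=float(t), df=df, p=min(p, 1.0), parameter=parameter, null_value=null_value
    )


def fold_change_curve(series_a, series_b) -> list[FoldChangePoint]:
    """Per-bin ratio A/B with delta-method errors.

    Both series are sequences of (x, y, sigma) on identical bins (matching
    x). Bins where either estimate is undefined or y_B <= 0 are dropped with
    a warning; an empty result is an error.
    """
    A = _as_points(series_a)
    Bp = _as_points(series_b)
    if len(A) != len(Bp):
        raise ValueError("series must cover identical bins")
    out = []
    n_dropped = 0
    for pa, pb in zip(A, Bp):
        if not np.isclose(pa.x, pb.x, rtol=1e-9, atol=1e-9):
            raise ValueError(f"bin x mismatch: {pa.x} vs {pb.x}")
        if (
            not np.isfinite(pa.y)
            or not np.isfinite(pb.y)
            or pb.y <= 0
            or not np.isfinite(pa.sigma)
            or not np.isfinite(pb.sigma)
        ):
            n_dropped += 1
            continue
        ratio = pa.y / pb.y
        # delta method, written to stay finite when y_A = 0
        sigma = np.sqrt((pa.sigma / pb.y) ** 2 + (pa.y * pb.sigma / pb.y**2) ** 2)
        out.append(FoldChangePoint(x=pa.x, ratio=float(ratio), sigma=float(sigma)))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} bins with undefined ratios", stacklevel=2)
    if not out:
        raise ValueError("no bins with a defined fold change")
    return out
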