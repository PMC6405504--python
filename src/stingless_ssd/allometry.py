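"""Major-axis (MA) line fitting and the isometry test (Rensch's rule).

MA regression minimizes perpendicular squared distances to the line and is the
appropriate line-fitting method when both variables are on the same scale and
both carry error — the situation for contrasts of two caste sizes. With sums
of squares/cross-products S_xx, S_yy, S_xy (uncentered for through-origin
fits, centered otherwise) the MA slope is

    beta = [S_yy - S_xx + sqrt((S_yy - S_xx)^2 + 4 S_xy^2)] / (2 S_xy)

and r^2 = S_xy^2 / (S_xx S_yy). The slope test against H0: beta = b0 uses the
classic residual-vs-axis-score construction: with u_i = y_i - b0 x_i and
w_i = x_i + b0 y_i, beta = b0 iff corr(u, w) = 0, and

    F = r_uw^2 * df / (1 - r_uw^2),   df = n - 1 (origin) or n - 2,

is compared against F(1, df). Contrast regressions are conventionally fit
through the origin (a contrast has no defined sign, so no intercept), giving
df = n_contrasts - 1.

Rensch's rule corresponds to a male-on-female slope significantly above 1;
a slope significantly below 1 is the converse pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ALPHA = 0.05


class DegenerateCloudError(ValueError):
    """Isotropic point cloud: the major axis is undefined."""


@dataclass
class MAFit:
    slope: float
    through_origin: bool
    n_pairs: int
    r2: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    pair: tuple[str, str] = ("y", "x")  # (response, predictor) labels
    # filled by ma_slope_test
    b0: float | None = None
    F: float | None = None
    df: int | None = None
    p: float | None = None
    verdict: str | None = None

    @property
    def dof(self) -> int:
        return self.n_pairs - 1 if self.through_origin else self.n_pairs - 2

    def to_dict(self) -> dict:
        return {
            "pair": f"{self.pair[0]}~{self.pair[1]}",
            "n_pairs": self.n_pairs,
            "slope": self.slope,
            "r2": self.r2,
            "through_origin": self.through_origin,
            "b0": self.b0,
            "F": self.F,
            "df": self.df,
            "p": self.p,
            "verdict": self.verdict,
        }


def _sums(x: np.ndarray, y: np.ndarray, through_origin: bool):
    if not through_origin:
        x = x - x.mean()
        y = y - y.mean()
    return float(x @ x), float(y @ y), float(x @ y), x, y


def ma_fit(x_values, y_values, through_origin: bool = True, pair=("y", "x")) -> MAFit:
    """Fit the major axis of (x, y), slope reported in y-on-x orientation."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    sxx, syy, sxy, xc, yc = _sums(x, y, through_origin)
    if sxx == 0 and syy == 0:
        raise DegenerateCloudError("all points identical")
    if sxy == 0:
        if np.isclose(sxx, syy):
            raise DegenerateCloudError("isotropic cloud: major axis undefined")
        slope = 0.0 if sxx > syy else np.inf
    else:
        slope = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    r2 = sxy**2 / (sxx * syy) if sxx > 0 and syy > 0 else 1.0
    return MAFit(
        slope=float(slope),
        through_origin=through_origin,
        n_pairs=len(x),
        r2=float(r2),
        x=x,
        y=y,
        pair=tuple(pair),
    )


def ma_slope_test(fit: MAFit, b0: float = 1.0) -> tuple[float, int, float]:
    """F test of H0: MA slope == b0. Returns (F, df, p) and records them on
    the fit. ``b0`` must not be perpendicular to the fitted axis."""
    if fit.n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    if np.isfinite(fit.slope) and 1.0 + b0 * fit.slope <= 0:
        raise ValueError(
            f"b0={b0} is at or beyond the perpendicular of the fitted axis "
            f"(slope {fit.slope:.4g}); the test orientation is undefined"
        )
    u = fit.y - b0 * fit.x
    w = fit.x + b0 * fit.y
    if not fit.through_origin:
        u = u - u.mean()
        w = w - w.mean()
    df = fit.dof
    su, sw, suw = float(u @ u), float(w @ w), float(u @ w)
    if su == 0:  # perfect fit exactly at b0
        F, p = 0.0, 1.0
    elif sw == 0:
        raise ValueError("axis scores degenerate at this b0")
    else:
        r2 = suw**2 / (su * sw)
        if r2 >= 1.0:
            F, p = np.inf, 0.0
        else:
            F = r2 * df / (1.0 - r2)
            p = float(stats.f.sf(F, 1, df))
    fit.b0, fit.F, fit.df, fit.p = float(b0), float(F), int(df), float(p)
    return F, df, p


def _verdict(fit: MAFit, alpha: float = ALPHA) -> str:
    if fit.p is None:
        raise ValueError("run ma_slope_test first")
    if fit.p < alpha and fit.slope > fit.b0:
        return "Rensch"
    if fit.p < alpha and fit.slope < fit.b0:
        return "converse-Rensch"
    return "isometry not rejected"


def rensch_regressions(
    contrast_pairs: dict,
    through_origin: bool = True,
    b0: float = 1.0,
    alpha: float = ALPHA,
) -> list[MAFit]:
    """MA fit + isometry test for each caste pair.

    ``contrast_pairs`` maps ``(y_label, x_label)`` -> ``(x_contrasts,
    y_contrasts)``, each pair pre-aligned on the same pruned tree (same nodes,
    same order).
    """
    fits = []
    for (ylab, xlab), (x, y) in contrast_pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"misaligned contrast pair {ylab}~{xlab}: {x.shape} vs {y.shape}")
        fit = ma_fit(x, y, through_origin=through_origin, pair=(ylab, xlab))
        ma_slope_test(fit, b0=b0)
        fit.verdict = _verdict(fit, alpha=alpha)
        fits.append(fit)
    return fits


def studentized_residuals(fit: MAFit) -> np.ndarray:
    """Internally studentized perpendicular residuals of an MA fit.

    Used to screen for outliers (|t| > 3 is the conventional flag); outliers
    are reported, never removed.
    """
    b = fit.slope
    if not np.isfinite(b):
        resid = fit.x.astype(float)
    else:
        x, y = fit.x, fit.y
        if not fit.through_origin:
            x = x - x.mean()
            y = y - y.mean()
        resid = (y - b * x) / np.hypot(1.0, b)
    s = resid.std(ddof=1)
    if s == 0:
        return np.zeros_like(resid)
    return (resid - (0.0 if fit.through_origin else resid.mean())) / s
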