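"""Diagnostics of converged contacts: area-load curves, fits, scalings.

Loads are reported dimensionless as ``sigma0 / (E* sqrt(<grad h^2>))``;
surfaces are generated with unit rms gradient, so the denominator is E*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

__all__ = [
    "AreaLoadCurve",
    "ScalingFit",
    "reduced_area",
    "normalized_separation",
    "adhesion_parameter",
    "fit_erf_k",
    "collapse_coefficient",
    "fit_power_exponent",
]

CURVE_COLUMNS = [
    "sigma0", "area_fraction", "s_tilde", "Uel", "Uad", "theta", "converged",
]


@dataclass
class AreaLoadCurve:
    """Load sweep record for one layer width.

    ``W`` is the dimensionless width ``w/lambda_s`` (``inf`` marks the
    half-space).  ``points`` is a DataFrame with columns ``sigma0``
    (dimensionless load), ``area_fraction``, ``s_tilde``, ``Uel``, ``Uad``,
    ``theta`` and ``converged``, sorted by load.
    """

    W: float
    points: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sigma0", "area_fraction") if c not in self.points]
        if missing:
            raise ValueError(f"curve is missing columns {missing}")
        self.points = self.points.sort_values("sigma0").reset_index(drop=True)

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df.insert(0, "W", self.W)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AreaLoadCurve":
        df = pd.read_csv(path)
        W = float(df.pop("W").iloc[0])
        return cls(W=W, points=df)


@dataclass
class ScalingFit:
    """Log-log power-law fit ``y = prefactor * x**exponent``."""

    exponent: float
    prefactor: float
    window: tuple[float, float]
    stderr: float


def reduced_area(A, A0):
    """``A (A0 - A) / A0^2``: vanishes at zero and full contact, peaks at 1/4.

    In Persson theory this combination is, at low load, proportional to the
    load itself for *any* layer width, which is what makes the thin-layer
    curves collapsible onto the half-space master by a load rescaling.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or np.any(A > np.asarray(A0) * (1 + 1e-12)):
        raise ValueError("need 0 <= A <= A0")
    out = A * (A0 - A) / np.asarray(A0, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def normalized_separation(mean_u: float, u_max: float) -> float:
    """``s_tilde = 1 - <u>/u_max``: 1 at first touch, 0 at full contact."""
    if not u_max > 0:
        raise ValueError("u_max must be positive (flat substrate is degenerate)")
    if mean_u < -1e-12 * u_max or mean_u > u_max * (1 + 1e-9):
        raise ValueError("mean displacement outside [0, u_max]")
    return 1.0 - mean_u / u_max


def adhesion_parameter(Uel: float, Uad: float) -> float:
    """``theta = Uel/Uad``; the smaller, the better the adhesive performance."""
    if not Uad > 0:
        raise ValueError("theta undefined: adhesion energy must be positive "
                         "(needs gamma0 > 0 and nonzero contact)")
    return Uel / Uad


def fit_erf_k(
    curve: AreaLoadCurve,
    area_window: tuple[float, float] = (0.01, 0.9),
) -> tuple[float, float]:
    """Fit ``A/A0 = erf(k * sigma0_dimensionless)``; returns ``(k, stderr)``.

    Restricted to low-to-moderate areas (default ``A/A0 < 0.9``) where the
    erf law is meaningful; needs at least 4 points there.
    """
    pts = curve.points
    sel = (pts["area_fraction"] > area_window[0]) & (pts["area_fraction"] < area_window[1])
    if sel.sum() < 4:
        raise ValueError(f"need >= 4 points with area fraction in {area_window}, "
                         f"have {int(sel.sum())}")
    x = pts.loc[sel, "sigma0"].to_numpy()
    y = pts.loc[sel, "area_fraction"].to_numpy()
    k0 = 1.0
    with np.errstate(all="ignore"):
        popt, pcov = curve_fit(lambda xx, k: erf(k * xx), x, y, p0=[k0])
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def collapse_coefficient(
    curve: AreaLoadCurve,
    master: AreaLoadCurve,
    area_window: tuple[float, float] = (0.01, 0.5),
) -> float:
    """Load-rescaling factor ``c`` that superposes ``curve`` on ``master``.

    Matches the reduced-area curves by least squares in log load: for each
    point of ``curve`` with area fraction inside ``area_window`` (below 1/2,
    where reduced area is monotone in area), the master's log load at the
    same area fraction is interpolated, and ``log c`` is the mean log-load
    offset.  Thin sheets reach a given area at lower load, so ``c >= 1``
    and multiplying the thin-sheet loads by ``c`` recovers the half-space
    master.  Exactly scale-consistent: dividing the curve's loads by ``s``
    multiplies ``c`` by ``s``.
    """
    mpts = master.points
    msel = (
        (mpts["area_fraction"] > area_window[0])
        & (mpts["area_fraction"] < area_window[1])
        & (mpts["sigma0"] > 0)
    )
    ma = mpts.loc[msel, "area_fraction"].to_numpy()
    ms = np.log(mpts.loc[msel, "sigma0"].to_numpy())
    order = np.argsort(ma)
    ma, ms = ma[order], ms[order]

    cpts = curve.points
    lo = max(area_window[0], float(ma.min())) if ma.size else area_window[0]
    hi = min(area_window[1], float(ma.max())) if ma.size else area_window[1]
    csel = (
        (cpts["area_fraction"] >= lo)
        & (cpts["area_fraction"] <= hi)
        & (cpts["sigma0"] > 0)
    )
    if ma.size < 2 or csel.sum() < 1:
        raise ValueError("no overlapping area-fraction range between curve and master")
    ca = cpts.loc[csel, "area_fraction"].to_numpy()
    cs = np.log(cpts.loc[csel, "sigma0"].to_numpy())
    interp_master = np.interp(ca, ma, ms)
    return float(np.exp(np.mean(interp_master - cs)))


def fit_power_exponent(
    xs, ys, window: tuple[float, float] | None = None
) -> ScalingFit:
    """OLS power-law fit on ``(log x, log y)`` inside ``window`` on x."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    if window is None:
        window = (float(xs.min()), float(xs.max()))
    sel = (xs >= window[0]) & (xs <= window[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 points inside the fit window")
    lx, ly = np.log(xs[sel]), np.log(ys[sel])
    if sel.sum() == 3:
        coef = np.polyfit(lx, ly, 1)
        stderr = 0.0
    else:
        coef, cov = np.polyfit(lx, ly, 1, cov=True)
        stderr = float(np.sqrt(cov[0, 0]))
    return ScalingFit(
        exponent=float(coef[0]),
        prefactor=float(np.exp(coef[1])),
        window=window,
        stderr=stderr,
    )
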