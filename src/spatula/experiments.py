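"""Orchestrated numerical experiments: sweeps, width scans, theory checks.

Desk-scale defaults follow the roughness recipe ``lambda_s = 4a`` (cut-off),
``lambda_r = 16 lambda_s`` (roll-off) and Hurst exponent 0.8, with the
system length a multiple of ``lambda_r`` so the scale separation
``lambda_s << lambda_r <= L`` survives on tractable grids.  Program units:
``a = 1``, ``E* = 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erfinv

from .kernel import LayerSpec, build_kernel, persson_broadening
from .observables import (
    AreaLoadCurve,
    ScalingFit,
    adhesion_parameter,
    collapse_coefficient,
    fit_power_exponent,
)
from .solver import SolverConfig, relax
from .surface import RoughSurface, SpectrumSpec, generate_heightfield

__all__ = [
    "ExperimentConfig",
    "make_surface",
    "load_ladder",
    "sweep_curve",
    "run_area_load_sweep",
    "run_width_scan",
    "run_theta_scan",
    "run_theory_comparison",
]

HALF_SPACE = float("inf")


@dataclass
class ExperimentConfig:
    """Shared parameters of the numerical experiments.

    ``widths`` are dimensionless widths ``W = w/lambda_s``; ``inf`` is the
    half-space.  ``loads`` (dimensionless, sorted) may be left None to place
    a ladder automatically so area fractions span ``area_span``.
    """

    n: int = 512
    spacing: float = 1.0
    lambda_s: float = 4.0
    lambda_r: float = 64.0
    hurst: float = 0.8
    seeds: tuple[int, ...] = (0, 1, 2)
    widths: tuple[float, ...] = (HALF_SPACE,)
    estar: float = 1.0
    loads: tuple[float, ...] | None = None
    n_loads: int = 8
    area_span: tuple[float, float] = (0.02, 0.6)
    gamma0: float = 5e-4
    rho: float = 0.25
    area_targets: tuple[float, ...] = (0.2, 0.3, 0.4)
    force_tol: float = 1e-4
    max_steps: int = 6000
    outdir: str | None = None

    def spectrum(self) -> SpectrumSpec:
        return SpectrumSpec.from_wavelengths(self.lambda_r, self.lambda_s, self.hurst)

    def layer(self, W: float) -> LayerSpec:
        if np.isinf(W):
            return LayerSpec.half_space(self.estar)
        return LayerSpec(estar=self.estar, w=W * self.lambda_s)

    def validate(self) -> None:
        if not self.seeds:
            raise ValueError("need at least one seed")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive (inf = half-space)")
        if self.loads is not None and (
            any(l <= 0 for l in self.loads) or list(self.loads) != sorted(self.loads)
        ):
            raise ValueError("loads must be positive and sorted")


def make_surface(config: ExperimentConfig, seed: int) -> RoughSurface:
    return generate_heightfield(config.spectrum(), config.n, config.spacing, seed)


def load_ladder(config: ExperimentConfig, W: float) -> np.ndarray:
    """Dimensionless loads spanning the requested area-fraction range.

    Placed with the Persson predictor ``A/A0 = erf(sigma0/(sqrt2 dsigma))``
    for the given width, so curves for different widths overlap in area —
    a prerequisite for the master-curve collapse.
    """
    if config.loads is not None:
        return np.asarray(config.loads, dtype=float)
    dsig = persson_broadening(config.spectrum(), config.layer(W))
    targets = np.geomspace(config.area_span[0], config.area_span[1], config.n_loads)
    return np.sqrt(2.0) * dsig / config.estar * erfinv(targets)


def sweep_curve(
    config: ExperimentConfig,
    surface: RoughSurface,
    W: float,
    adhesion: bool = False,
) -> AreaLoadCurve:
    """Relax one surface/kernel pair over the load ladder (warm-started)."""
    kernel = build_kernel(config.layer(W), config.n, config.spacing)
    loads = load_ladder(config, W)
    rows = []
    z_prev = None
    for sig in loads:
        solver_cfg = SolverConfig(
            sigma0=sig * config.estar,
            force_tol=config.force_tol,
            max_steps=config.max_steps,
            gamma0=config.gamma0 if adhesion else 0.0,
            rho=config.rho,
            adhesion_enabled=adhesion,
        )
        res = relax(surface, kernel, solver_cfg, z0=z_prev)
        z_prev = res.z
        theta = (
            adhesion_parameter(res.elastic_energy, res.adhesion_energy)
            if adhesion and res.adhesion_energy > 0
            else np.nan
        )
        rows.append(
            dict(
                sigma0=sig,
                area_fraction=res.area_fraction,
                s_tilde=res.normalized_separation,
                Uel=res.elastic_energy,
                Uad=res.adhesion_energy,
                theta=theta,
                converged=res.converged,
            )
        )
    return AreaLoadCurve(W=W, points=pd.DataFrame(rows))


def run_area_load_sweep(
    config: ExperimentConfig, adhesion: bool = False
) -> tuple[dict[tuple[float, int], AreaLoadCurve], pd.DataFrame]:
    """Area-load sweep for every (width, seed) pair.

    Returns the individual curves plus an aggregate table with the
    seed-geometric-mean load at each ladder rung (quantities span decades,
    so averaging is done in log space).
    """
    config.validate()
    curves: dict[tuple[float, int], AreaLoadCurve] = {}
    frames = []
    for seed in config.seeds:
        surface = make_surface(config, seed)
        for W in config.widths:
            curve = sweep_curve(config, surface, W, adhesion=adhesion)
            curves[(W, seed)] = curve
            df = curve.points.copy()
            df.insert(0, "seed", seed)
            df.insert(0, "W", W)
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    agg = (
        table.assign(log_area=np.log(table["area_fraction"].clip(lower=1e-12)))
        .groupby(["W", "sigma0"], as_index=False)
        .agg(area_fraction=("log_area", lambda v: float(np.exp(np.mean(v)))),
             s_tilde=("s_tilde", "mean"),
             n_seeds=("seed", "count"))
    )
    _maybe_write(config, table, "sweep_points.csv")
    _maybe_write(config, agg, "sweep_aggregate.csv")
    return curves, agg


def run_width_scan(
    config: ExperimentConfig,
    fit_upper_W: float = 0.5,
) -> tuple[pd.DataFrame, ScalingFit]:
    """Collapse coefficient c(W) against the half-space master, and its
    small-W power law (expected exponent -3, the thin-plate signature)."""
    config.validate()
    finite = sorted(w for w in config.widths if np.isfinite(w))
    if not finite:
        raise ValueError("width scan needs at least one finite width")
    rows = []
    for seed in config.seeds:
        surface = make_surface(config, seed)
        master = sweep_curve(config, surface, HALF_SPACE)
        for W in finite:
            curve = sweep_curve(config, surface, W)
            rows.append(dict(seed=seed, W=W, c=collapse_coefficient(curve, master)))
    table = pd.DataFrame(rows)
    agg = (
        table.assign(logc=np.log(table["c"]))
        .groupby("W", as_index=False)
        .agg(c=("logc", lambda v: float(np.exp(np.mean(v)))))
    )
    fit = fit_power_exponent(agg["W"], agg["c"], window=(0.0, fit_upper_W))
    _maybe_write(config, agg, "width_scan.csv")
    return agg, fit


def _bisect_load_for_area(config, surface, kernel, W, target, adhesion=True,
                          start=None, area_tol=0.01):
    """Load reaching a target area fraction by warm-started bisection.

    Returns ``(result, guess_state)`` where ``result`` is None when the
    target cannot be bracketed or hit (e.g. adhesive jump-in puts the
    zero-load area already above the target).  ``start`` may carry the
    ``(load, z)`` of a previous, lower target to seed the bracket.
    """
    dsig = persson_broadening(config.spectrum(), config.layer(W))
    lo = np.sqrt(2.0) * dsig * erfinv(max(target / 8.0, 1e-3))
    hi = np.sqrt(2.0) * dsig * erfinv(min(target * 2.5, 0.95))
    z_seed = None
    if start is not None:
        lo = max(lo, start[0])
        hi = max(hi, lo * 1.5)
        z_seed = start[1]

    def area_at(sig, z0):
        cfg = SolverConfig(
            sigma0=sig, force_tol=config.force_tol, max_steps=config.max_steps,
            gamma0=config.gamma0 if adhesion else 0.0, rho=config.rho,
            adhesion_enabled=adhesion,
        )
        return relax(surface, kernel, cfg, z0=z0)

    res_lo = area_at(lo, z_seed)
    for _ in range(8):
        if res_lo.area_fraction <= target:
            break
        lo /= 4.0
        res_lo = area_at(lo, None)
    res_hi = area_at(hi, res_lo.z)
    for _ in range(8):
        if res_hi.area_fraction >= target:
            break
        hi *= 4.0
        res_hi = area_at(hi, res_hi.z)
    if not (res_lo.area_fraction <= target <= res_hi.area_fraction):
        return None, (hi, res_hi.z)
    res = res_hi
    for _ in range(16):
        if abs(res.area_fraction - target) <= area_tol:
            break
        mid = np.sqrt(lo * hi)
        res = area_at(mid, res.z)
        if res.area_fraction < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0005:
            break
    if abs(res.area_fraction - target) > 2 * area_tol:
        return None, (res.sigma0, res.z)
    return res, (res.sigma0, res.z)


def run_theta_scan(
    config: ExperimentConfig,
    fit_upper_W: float = 0.5,
) -> tuple[pd.DataFrame, ScalingFit]:
    """Adhesion parameter theta = Uel/Uad versus W at fixed area fractions.

    For each finite width and each target area fraction, the load reaching
    that area is found by bisection and theta is recorded there; the small-W
    rows are fitted with a power law (expected exponent +3: at fixed contact
    geometry the stored elastic energy carries the bending stiffness
    ``~ w^3``).  Rows whose target area could not be bracketed are flagged
    with NaN theta and excluded from the fit.
    """
    config.validate()
    if not config.gamma0 > 0:
        raise ValueError("theta scan requires gamma0 > 0")
    finite = sorted(w for w in config.widths if np.isfinite(w))
    rows = []
    for seed in config.seeds:
        surface = make_surface(config, seed)
        for W in finite:
            kernel = build_kernel(config.layer(W), config.n, config.spacing)
            start = None
            for target in sorted(config.area_targets):
                res, start = _bisect_load_for_area(
                    config, surface, kernel, W, target, start=start
                )
                if res is None or res.adhesion_energy <= 0:
                    rows.append(dict(seed=seed, W=W, target=target, sigma0=np.nan,
                                     area_fraction=np.nan, theta=np.nan))
                    continue
                rows.append(dict(
                    seed=seed, W=W, target=target, sigma0=res.sigma0,
                    area_fraction=res.area_fraction,
                    theta=adhesion_parameter(res.elastic_energy, res.adhesion_energy),
                ))
    table = pd.DataFrame(rows)
    good = table.dropna(subset=["theta"])
    agg = (
        good.assign(logth=np.log(good["theta"]))
        .groupby("W", as_index=False)
        .agg(theta=("logth", lambda v: float(np.exp(np.mean(v)))))
    )
    fit = fit_power_exponent(agg["W"], agg["theta"], window=(0.0, fit_upper_W))
    _maybe_write(config, table, "theta_scan.csv")
    return table, fit


def run_theory_comparison(
    config: ExperimentConfig,
    W_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ScalingFit]:
    """Persson-theory broadening across widths and its small-W power law.

    Tabulates ``Delta_sigma(W)`` and the low-load area/load coefficient
    ``kappa(W) = sqrt(2/pi)/Delta_sigma`` (the slope of the erf relation at
    zero load); fits the log-log slope of the coefficient, expected -3
    (equivalently Delta_sigma ~ W^{+3}).
    """
    spec = config.spectrum()
    if W_grid is None:
        W_grid = np.geomspace(1e-2, 1e-1, 13)
    rows = []
    for W in W_grid:
        dsig = persson_broadening(spec, config.layer(float(W)))
        rows.append(dict(W=float(W), delta_sigma=dsig,
                         area_coefficient=np.sqrt(2 / np.pi) / dsig))
    table = pd.DataFrame(rows)
    fit = fit_power_exponent(table["W"], table["area_coefficient"])
    _maybe_write(config, table, "theory_broadening.csv")
    return table, fit


def _maybe_write(config: ExperimentConfig, df: pd.DataFrame, name: str) -> None:
    if config.outdir is None:
        return
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / name, index=False)
    manifest = out / "manifest.json"
    if not manifest.exists():
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(config).items()}
        manifest.write_text(json.dumps(cfg, indent=2, default=str))
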