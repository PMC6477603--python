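"""Synthesis and characterization of periodic self-affine rough surfaces.

The rigid counterface is a random height field ``h(r)`` on an ``n x n``
periodic grid with spacing ``a``, generated spectrally from an isotropic
power spectral density (PSD)

    C(q) = C0                          for 0 < q < q_r       (plateau)
    C(q) = C0 * (q/q_r)^(-2(1+H))      for q_r <= q <= q_s   (self-affine band)
    C(q) = 0                           for q > q_s

where ``q_r = 2*pi/lambda_r`` and ``q_s = 2*pi/lambda_s`` are the roll-off
and cut-off wavenumbers and ``H`` is the Hurst exponent.

Fourier convention: ``h_tilde = fft2(h)`` (unnormalized forward transform,
``1/N`` on the inverse, ``N = n*n`` grid points).  The continuum PSD is
related to the discrete coefficients by ``E[|h_tilde(q)|^2] = C(|q|) * L^2 /
a^4`` with ``L = n*a``, so that ``<h^2> = sum_q C(q)/L^2 ~ int C d^2q/(2pi)^2``.
The absolute scale of ``C0`` is irrelevant downstream: surfaces are finalized
by rescaling to unit rms gradient and shifting the highest point to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSpec",
    "RoughSurface",
    "psd_value",
    "generate_heightfield",
    "rms_gradient",
    "normalize_rms_gradient",
    "shift_to_zero_max",
    "estimate_psd",
    "fit_hurst",
    "write_surface",
    "read_surface",
]


@dataclass(frozen=True)
class SpectrumSpec:
    """Isotropic roll-off/cut-off power-law height spectrum.

    Parameters
    ----------
    qr, qs : float
        Roll-off and cut-off wavenumbers (1/length), ``0 < qr < qs``.
    hurst : float
        Hurst exponent ``H`` in (0, 1); the self-affine band decays as
        ``q**(-2*(1+H))``.
    C0 : float
        Plateau value ``C(qr)`` (length^4).  Free scale; unit rms-gradient
        normalization removes it from every downstream quantity.
    """

    qr: float
    qs: float
    hurst: float
    C0: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.qr < self.qs):
            raise ValueError(f"need 0 < qr < qs, got qr={self.qr}, qs={self.qs}")
        if not (0 < self.hurst < 1):
            raise ValueError(f"Hurst exponent must be in (0,1), got {self.hurst}")
        if not self.C0 > 0:
            raise ValueError("C0 must be positive")

    @classmethod
    def from_wavelengths(
        cls, lambda_r: float, lambda_s: float, hurst: float, C0: float = 1.0
    ) -> "SpectrumSpec":
        """Build from roll-off / cut-off wavelengths (lambda_r > lambda_s)."""
        return cls(qr=2 * np.pi / lambda_r, qs=2 * np.pi / lambda_s, hurst=hurst, C0=C0)


@dataclass
class RoughSurface:
    """Periodic height grid with its generation metadata.

    ``heights`` is an ``n x n`` real array, grid index ``i`` at position
    ``i*spacing``; periodic in both directions.  A *finalized* surface has
    unit spectral rms gradient and ``max(heights) == 0``.
    """

    heights: np.ndarray
    spacing: float
    seed: int | None = None
    spectrum: SpectrumSpec | None = None

    @property
    def n(self) -> int:
        return self.heights.shape[0]

    @property
    def length(self) -> float:
        return self.n * self.spacing

    @property
    def rms_gradient(self) -> float:
        return rms_gradient(self)

    @property
    def rms_height(self) -> float:
        h = self.heights
        return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def psd_value(spec: SpectrumSpec, q):
    """Evaluate the height PSD ``C(q)`` (length^4) at wavenumber(s) ``q``.

    Continuous at ``q = qr``; zero above the cut-off and at ``q = 0``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("wavenumber must be nonnegative")
    out = np.zeros_like(q)
    plateau = (q > 0) & (q < spec.qr)
    band = (q >= spec.qr) & (q <= spec.qs)
    out[plateau] = spec.C0
    out[band] = spec.C0 * (q[band] / spec.qr) ** (-2.0 * (1.0 + spec.hurst))
    if out.ndim == 0:
        return float(out)
    return out


def _wavevector_grids(n: int, a: float):
    q1 = 2 * np.pi * np.fft.fftfreq(n, d=a)
    qx = q1[:, None]
    qy = q1[None, :]
    return qx, qy, np.hypot(qx, qy)


def generate_heightfield(
    spec: SpectrumSpec, n: int, a: float, seed: int, finalize: bool = True
) -> RoughSurface:
    """Synthesize a periodic random height field from the target spectrum.

    Fourier amplitudes: real and imaginary parts of each free mode are drawn
    independently from a zero-mean *uniform* distribution whose second moment
    gives ``E[|h_tilde|^2]`` equal to the target spectrum (uniform rather
    than Gaussian to exclude rare extreme outliers; the spectrum only
    constrains second moments).  Hermitian symmetry is built in so the field
    is exactly real; self-conjugate modes (q=0 and Nyquist lines) are drawn
    real with matching variance.  The q=0 (mean height) mode is set to zero.

    With ``finalize=True`` (default) the field is scaled to unit rms gradient
    and shifted so its highest point is zero, in that order.
    """
    if n < 8 or n % 2 != 0:
        raise ValueError(f"grid size must be even and >= 8, got n={n}")
    if spec.qs > np.pi / a * (1 + 1e-12):
        raise ValueError(
            f"cut-off qs={spec.qs:g} exceeds the Nyquist wavenumber pi/a={np.pi/a:g}"
        )
    rng = np.random.default_rng(seed)

    _, _, qmag = _wavevector_grids(n, a)
    L = n * a
    # E[|h_tilde|^2] = C(q) * L^2 / a^4 (see module docstring)
    s = psd_value(spec, qmag) * L**2 / a**4

    half = np.sqrt(3.0 * s / 2.0)  # uniform [-b, b] has variance b^2/3
    re = rng.uniform(-1.0, 1.0, size=(n, n)) * half
    im = rng.uniform(-1.0, 1.0, size=(n, n)) * half
    coeff = re + 1j * im

    # Hermitian symmetrization: keep the independently drawn half-plane and
    # mirror the conjugate half, so each retained mode keeps its variance.
    m = n // 2
    idx = np.arange(n)
    conj_rows = (-idx) % n
    full = np.zeros((n, n), dtype=complex)
    # free columns 1..m-1 (their mirrors are columns n-1..m+1)
    full[:, 1:m] = coeff[:, 1:m]
    full[:, m + 1:] = np.conj(full[conj_rows][:, (-idx[m + 1:]) % n])
    # self-conjugate columns 0 and m: Hermitian along rows
    for j in (0, m):
        col = np.empty(n, dtype=complex)
        col[1:m] = coeff[1:m, j]
        col[m + 1:] = np.conj(col[1:m][::-1])
        # self-conjugate points: real, variance s (not s/2 per component)
        col[0] = rng.uniform(-1.0, 1.0) * np.sqrt(3.0 * s[0, j])
        col[m] = rng.uniform(-1.0, 1.0) * np.sqrt(3.0 * s[m, j])
        full[:, j] = col
    full[qmag > spec.qs] = 0.0
    full[0, 0] = 0.0  # mean height carries no information

    h = np.fft.ifft2(full)
    assert np.max(np.abs(h.imag)) <= 1e-10 * max(np.max(np.abs(h.real)), 1e-300)
    surf = RoughSurface(heights=h.real, spacing=a, seed=seed, spectrum=spec)
    if finalize:
        if rms_gradient(surf) > 0:
            surf = normalize_rms_gradient(surf)
        surf = shift_to_zero_max(surf)
    return surf


def rms_gradient(surface: RoughSurface) -> float:
    """Spectral root-mean-square slope ``sqrt(<|grad h|^2>)``.

    Computed as ``sqrt(sum_q q^2 |h_tilde(q)|^2 / N^2)`` which equals the
    cell average of the squared spectral gradient (Parseval).
    """
    h = surface.heights
    if h.size == 0:
        raise ValueError("empty height grid")
    n = h.shape[0]
    _, _, qmag = _wavevector_grids(n, surface.spacing)
    ht = np.fft.fft2(h)
    return float(np.sqrt(np.sum(qmag**2 * np.abs(ht) ** 2)) / h.size)


def normalize_rms_gradient(surface: RoughSurface, target: float = 1.0) -> RoughSurface:
    """Rescale heights so the spectral rms gradient equals ``target``."""
    g = rms_gradient(surface)
    if g <= 0:
        raise ValueError("cannot normalize a surface with zero rms gradient")
    return replace(surface, heights=surface.heights * (target / g))


def shift_to_zero_max(surface: RoughSurface) -> RoughSurface:
    """Shift heights so the highest substrate point sits at zero.

    Finalization order is normalize-then-shift: a uniform shift leaves
    gradients unchanged, while rescaling after the shift would move the
    maximum off zero.
    """
    return replace(surface, heights=surface.heights - surface.heights.max())


def estimate_psd(surface: RoughSurface, nbins: int = 40) -> pd.DataFrame:
    """Radially averaged PSD estimate ``C_hat(q)``.

    Bins ``|h_tilde(q)|^2 * a^4 / L^2`` (the convention inverse to
    :func:`generate_heightfield`) over log-spaced radial shells.  Returns a
    DataFrame with columns ``q`` (geometric bin center), ``psd`` (shell mean)
    and ``count``.
    """
    h = surface.heights
    n = h.shape[0]
    a = surface.spacing
    _, _, qmag = _wavevector_grids(n, a)
    power = np.abs(np.fft.fft2(h)) ** 2 * a**4 / (n * a) ** 2

    qpos = qmag[qmag > 0]
    qlo, qhi = qpos.min() * 0.999, qpos.max() * 1.001
    edges = np.geomspace(qlo, qhi, nbins + 1)
    which = np.digitize(qmag.ravel(), edges) - 1
    ok = (qmag.ravel() > 0) & (which >= 0) & (which < nbins)
    counts = np.bincount(which[ok], minlength=nbins)
    sums = np.bincount(which[ok], weights=power.ravel()[ok], minlength=nbins)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        raise ValueError("grid too small for a radial PSD estimate (< 3 bins)")
    centers = np.sqrt(edges[:-1] * edges[1:])
    return pd.DataFrame(
        {
            "q": centers[nonempty],
            "psd": sums[nonempty] / counts[nonempty],
            "count": counts[nonempty],
        }
    )


def fit_hurst(
    surface: RoughSurface,
    spec: SpectrumSpec | None = None,
    band: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Recover the Hurst exponent from the radial PSD slope.

    Fits the log-log slope ``s`` of the estimated PSD inside the power-law
    band (by default the inner part of ``(qr, qs)``, trimmed to avoid the
    roll-off shoulder and cut-off edge) and returns ``(H, stderr_H)`` with
    ``H = -s/2 - 1``.
    """
    spec = spec or surface.spectrum
    if spec is None and band is None:
        raise ValueError("need either the surface's spectrum or an explicit band")
    if band is None:
        band = (spec.qr * 1.5, spec.qs * 0.7)
    tab = estimate_psd(surface)
    sel = (tab["q"] >= band[0]) & (tab["q"] <= band[1]) & (tab["psd"] > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 PSD bins inside the fit band")
    x = np.log(tab.loc[sel, "q"].to_numpy())
    y = np.log(tab.loc[sel, "psd"].to_numpy())
    (slope, _), cov = np.polyfit(x, y, 1, cov=True)
    return -slope / 2.0 - 1.0, float(np.sqrt(cov[0, 0]) / 2.0)


# ---------------------------------------------------------------------------
# portable plain-text grid format


def write_surface(surface: RoughSurface, path) -> None:
    """Write a surface as a plain-text grid with a commented header."""
    meta = [f"# n={surface.n}", f"# spacing={surface.spacing!r}", f"# seed={surface.seed}"]
    if surface.spectrum is not None:
        sp = surface.spectrum
        meta.append(f"# qr={sp.qr!r} qs={sp.qs!r} hurst={sp.hurst!r} C0={sp.C0!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(meta) + "\n")
        np.savetxt(fh, surface.heights, fmt="%.17e")


def read_surface(path) -> RoughSurface:
    """Read a surface written by :func:`write_surface` (bit-exact round-trip)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        for tok in line[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    heights = np.loadtxt(path)
    spectrum = None
    if "qr" in meta:
        spectrum = SpectrumSpec(
            qr=float(meta["qr"]), qs=float(meta["qs"]),
            hurst=float(meta["hurst"]), C0=float(meta.get("C0", 1.0)),
        )
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return RoughSurface(
        heights=heights, spacing=float(meta["spacing"]), seed=seed, spectrum=spectrum
    )
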