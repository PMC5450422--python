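"""Elliptic Fourier description of leaflet contours.

A closed contour (x(t), y(t)) parameterized by arc length is expanded in
the classical four-coefficient elliptic Fourier series

    x(t) = A0 + sum_f a_f cos(2 pi f t / T) + b_f sin(2 pi f t / T)
    y(t) = C0 + sum_f c_f cos(2 pi f t / T) + d_f sin(2 pi f t / T)

with 120 harmonics by default.  Amplitudes are normalized to be invariant
to translation (constant term dropped), rotation and starting point (first
harmonic phase normalization) but NOT to scale: the description keeps
absolute size, so A(f) carries both shape and size information.  The
per-axis amplitudes are A(f)_x = sqrt(a_f^2 + b_f^2) and A(f)_y =
sqrt(c_f^2 + d_f^2), combined as A(f)^2 = A(f)_x^2 + A(f)_y^2.

The spectrum is summarized in three bands of the combined power A(f)^2 --
Delta (harmonics 1-19, blade outline), Alpha (20-55, serrations) and Beta
(56-120, fine margin detail) -- plus the 50% frequency: the harmonic at
which the cumulative power reaches half of the total.  Band-limited inverse
transforms reconstruct the outline alone (Delta), outline plus teeth
(Delta+Alpha) or the full margin, and double as a spectral low-pass filter
that strips hair-like spikes from a contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import Contour

N_HARMONICS = 120
#: band upper edges: Delta 1..19, Alpha 20..55, Beta 56..N
BAND_EDGES = (19, 55, 120)
RESAMPLE_POINTS = 16384


@dataclass
class EFDSpectrum:
    """Elliptic Fourier coefficients and invariance-normalized amplitudes."""

    coeffs: np.ndarray        # (N, 4) raw a_f, b_f, c_f, d_f (image frame)
    a0: float
    c0: float
    amp_x: np.ndarray         # normalized per-axis amplitudes, length N
    amp_y: np.ndarray
    phase_x: np.ndarray
    phase_y: np.ndarray
    n_points: int             # original contour point count
    band_edges: tuple[int, int, int] = BAND_EDGES

    @property
    def n_harmonics(self) -> int:
        return len(self.coeffs)

    @property
    def amplitude(self) -> np.ndarray:
        """Combined amplitude A(f) = sqrt(A(f)_x^2 + A(f)_y^2)."""
        return np.hypot(self.amp_x, self.amp_y)

    @property
    def power(self) -> np.ndarray:
        return self.amp_x**2 + self.amp_y**2


@dataclass
class BandSummary:
    delta_power: float
    alpha_power: float
    beta_power: float
    half_power_frequency: float
    hpf_mode: str = "amplitude"


def _harmonic_ranges(edges: tuple[int, int, int]) -> dict[str, tuple[int, int]]:
    d, a, b = edges
    return {"delta": (1, d), "alpha": (d + 1, a), "beta": (a + 1, b)}


def efd_transform(
    contour: Contour,
    n_harmonics: int = N_HARMONICS,
    n_samples: int = RESAMPLE_POINTS,
) -> EFDSpectrum:
    """Elliptic Fourier transform of a closed contour.

    The contour is resampled to *n_samples* equally spaced arc-length
    points for stable coefficient estimates.  Requires at least
    ``2 * n_harmonics + 1`` original points.
    """
    if len(contour) < 2 * n_harmonics + 1:
        raise ValueError(
            f"contour has {len(contour)} points; "
            f"need >= {2 * n_harmonics + 1} for {n_harmonics} harmonics"
        )
    rs = contour.resample(max(n_samples, 2 * n_harmonics + 1))
    pts = np.vstack([rs.points, rs.points[:1]])
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt <= 0):
        keep = dt > 0
        d, dt = d[keep], dt[keep]
        pts = np.vstack([pts[:-1][keep], pts[:1]])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T

    n = np.arange(1, n_harmonics + 1)[:, None]
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = const * (dx_dt * cos_d).sum(axis=1)
    b = const * (dx_dt * sin_d).sum(axis=1)
    c = const * (dy_dt * cos_d).sum(axis=1)
    dd = const * (dy_dt * sin_d).sum(axis=1)
    coeffs = np.column_stack([a, b, c, dd])

    # constant terms: arc-length average of the coordinates
    mid = 0.5 * (pts[1:] + pts[:-1])
    a0 = float((mid[:, 0] * dt).sum() / T)
    c0 = float((mid[:, 1] * dt).sum() / T)

    norm = _normalize(coeffs)
    amp_x = np.hypot(norm[:, 0], norm[:, 1])
    amp_y = np.hypot(norm[:, 2], norm[:, 3])
    phase_x = np.arctan2(norm[:, 1], norm[:, 0])
    phase_y = np.arctan2(norm[:, 3], norm[:, 2])
    return EFDSpectrum(
        coeffs=coeffs, a0=a0, c0=c0,
        amp_x=amp_x, amp_y=amp_y, phase_x=phase_x, phase_y=phase_y,
        n_points=len(contour),
    )


def _normalize(coeffs: np.ndarray) -> np.ndarray:
    """Rotation and starting-point normalization (no size scaling).

    Standard first-harmonic phase normalization: the starting point is
    rotated to the first semi-major axis crossing and the coordinate frame
    aligned with the first-harmonic ellipse orientation.
    """
    a1, b1, c1, d1 = coeffs[0]
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    n = np.arange(1, len(coeffs) + 1)
    cos_nt = np.cos(n * theta)
    sin_nt = np.sin(n * theta)
    a = coeffs[:, 0] * cos_nt + coeffs[:, 1] * sin_nt
    b = -coeffs[:, 0] * sin_nt + coeffs[:, 1] * cos_nt
    c = coeffs[:, 2] * cos_nt + coeffs[:, 3] * sin_nt
    d = -coeffs[:, 2] * sin_nt + coeffs[:, 3] * cos_nt
    psi = np.arctan2(c[0], a[0])
    cp, sp = np.cos(psi), np.sin(psi)
    a2 = cp * a + sp * c
    c2 = -sp * a + cp * c
    b2 = cp * b + sp * d
    d2 = -sp * b + cp * d
    return np.column_stack([a2, b2, c2, d2])


def band_summary(
    spectrum: EFDSpectrum,
    hpf_mode: str = "amplitude",
) -> BandSummary:
    """Delta/Alpha/Beta band powers and the 50% frequency.

    Band sums always accumulate the power A(f)^2, so the three bands
    partition the total spectral power exactly.  The 50% frequency is the
    smallest harmonic at which the cumulative sum reaches half of the
    total, linearly interpolated between the bracketing harmonics and
    clamped to [1, N]; by default it accumulates the combined amplitude
    A(f) (``hpf_mode="power"`` switches to A(f)^2).
    """
    if hpf_mode == "power":
        p_hpf = spectrum.power
    elif hpf_mode == "amplitude":
        p_hpf = spectrum.amplitude
    else:
        raise ValueError("hpf_mode must be 'power' or 'amplitude'")
    p = spectrum.power
    total = float(p.sum())
    if total <= 0:
        raise ValueError("zero total spectral power")
    ranges = _harmonic_ranges(spectrum.band_edges)
    sums = {}
    for name, (lo, hi) in ranges.items():
        sums[name] = float(p[lo - 1: hi].sum())
    # any harmonics beyond the last band edge count toward beta
    if spectrum.n_harmonics > spectrum.band_edges[2]:
        sums["beta"] += float(p[spectrum.band_edges[2]:].sum())

    # the 50% frequency accumulates shape detail: the first harmonic is
    # the gross ellipse (dominated by size) and is left out, otherwise it
    # alone always holds more than half the total and the descriptor
    # degenerates to 1 for every leaflet
    p_shape = p_hpf.copy()
    p_shape[0] = 0.0
    if p_shape.sum() <= 0:
        hpf = 1.0
    else:
        cum = np.cumsum(p_shape)
        half = float(cum[-1]) / 2.0
        f = int(np.searchsorted(cum, half) + 1)  # 1-based harmonic
        prev = cum[f - 2] if f >= 2 else 0.0
        frac = (half - prev) / (cum[f - 1] - prev)
        hpf = float(np.clip((f - 1) + frac, 1.0, spectrum.n_harmonics))
    return BandSummary(
        delta_power=sums["delta"],
        alpha_power=sums["alpha"],
        beta_power=sums["beta"],
        half_power_frequency=hpf,
        hpf_mode=hpf_mode,
    )


def reconstruct(
    spectrum: EFDSpectrum,
    bands: set[str] | frozenset[str] = frozenset({"delta", "alpha", "beta"}),
    n_points: int | None = None,
) -> Contour:
    """Inverse elliptic Fourier transform restricted to the given bands.

    Harmonics outside the selected bands are zeroed; the raw (image-frame)
    coefficients are used so the reconstruction lands in the original
    coordinates, sampled at the original point count by default.
    """
    if not bands:
        raise ValueError("empty band subset")
    unknown = set(bands) - {"delta", "alpha", "beta"}
    if unknown:
        raise ValueError(f"unknown bands: {sorted(unknown)}")
    ranges = _harmonic_ranges(spectrum.band_edges)
    mask = np.zeros(spectrum.n_harmonics, dtype=bool)
    for name in bands:
        lo, hi = ranges[name]
        mask[lo - 1: min(hi, spectrum.n_harmonics)] = True
    if "beta" in bands and spectrum.n_harmonics > spectrum.band_edges[2]:
        mask[spectrum.band_edges[2]:] = True
    return _inverse(spectrum, mask, n_points or spectrum.n_points)


def _inverse(spectrum: EFDSpectrum, mask: np.ndarray, n_points: int) -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, spectrum.n_harmonics + 1)[mask]
    co = spectrum.coeffs[mask]
    cos_nt = np.cos(np.outer(n, t))
    sin_nt = np.sin(np.outer(n, t))
    x = spectrum.a0 + co[:, 0] @ cos_nt + co[:, 1] @ sin_nt
    y = spectrum.c0 + co[:, 2] @ cos_nt + co[:, 3] @ sin_nt
    return Contour(np.column_stack([x, y]))


def lowpass_outline_filter(contour: Contour, cutoff_harmonic: int) -> Contour:
    """Low-pass spectral filter: rebuild the contour from harmonics 1..cutoff.

    Hair-like spikes (trichomes) live at high harmonics and vanish; with a
    cutoff at or above the serration band the tooth pattern is preserved.
    """
    if cutoff_harmonic < 1:
        raise ValueError("cutoff harmonic must be >= 1")
    cutoff = int(min(cutoff_harmonic, (len(contour) - 1) // 2))
    spec = efd_transform(contour, n_harmonics=cutoff)
    mask = np.ones(cutoff, dtype=bool)
    return _inverse(spec, mask, len(contour))
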