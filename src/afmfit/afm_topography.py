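"""Pseudo-AFM topograph synthesis and image analytics.

A topograph is simulated from a coarse-grained model with a hard spherical
tip: the recorded height at a pixel is the lowest tip-apex position at which
the tip sphere (radius ``r_t``) touches any bead sphere (radius ``r_b``).
For a bead centered at height ``z`` and lateral distance ``rho`` from the
pixel, the contact height is ``z - r_t + sqrt((r_t + r_b)^2 - rho^2)`` —
a grayscale dilation of the molecule by the tip.  The molecule is first
dropped so its lowest bead surface rests on the stage plane z = 0.

The module also provides Gaussian noise injection at a fraction of the
maximum height, background-noise estimation, Fourier-ring low-pass
filtering and the auto-correlation-value (ACV) resolution profile.

A smooth (C-infinity) variant of the synthesis, used for differentiating
the image with respect to bead positions, replaces the sphere profile by a
softplus-smoothed square root and the per-pixel max by a log-sum-exp with a
temperature of about 1 Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AFMSurface, CoarseModel

__all__ = [
    "TipModel",
    "NoiseEstimate",
    "ACVProfile",
    "synthesize_surface",
    "synthesize_surface_soft",
    "add_gaussian_noise",
    "estimate_background_noise",
    "lowpass_ring",
    "acv",
    "resolution_profile",
    "nyquist_nm_inv",
    "full_band_nm_inv",
]

BENCHMARK_NOISE_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)


@dataclass
class TipModel:
    """Spherical probe tip. Radii in Angstrom."""

    radius: float = 10.0
    bead_radius: float = 4.0

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("tip radius must be >= 0")
        if self.bead_radius <= 0:
            raise ValueError("bead radius must be > 0")

    @property
    def contact_radius(self) -> float:
        return self.radius + self.bead_radius


@dataclass
class NoiseEstimate:
    mean: float
    sigma: float
    n_pixels: int

    def __post_init__(self):
        if self.sigma < 0 or self.n_pixels < 2:
            raise ValueError("invalid noise estimate")


@dataclass
class ACVProfile:
    """ACV versus low-pass cutoff (spatial frequency, nm^-1)."""

    cutoffs: np.ndarray
    acv: np.ndarray
    derivative: np.ndarray

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"cutoff_nm_inv": self.cutoffs, "acv": self.acv,
             "derivative": self.derivative}
        ).to_csv(path, sep="\t", index=False)


def _dropped_coords(model: CoarseModel, bead_radius: float) -> np.ndarray:
    coords = model.coords.copy()
    coords[:, 2] -= coords[:, 2].min() - bead_radius
    return coords


def _grid_axes(coords: np.ndarray, pixel_size: float, margin: float,
               grid_like: AFMSurface | None):
    if grid_like is not None:
        return grid_like.x_coords(), grid_like.y_coords(), grid_like.origin
    x0 = coords[:, 0].min() - margin
    y0 = coords[:, 1].min() - margin
    nx = int(np.ceil((coords[:, 0].max() + margin - x0) / pixel_size)) + 1
    ny = int(np.ceil((coords[:, 1].max() + margin - y0) / pixel_size)) + 1
    xs = x0 + pixel_size * np.arange(max(nx, 2))
    ys = y0 + pixel_size * np.arange(max(ny, 2))
    return xs, ys, (x0, y0)


def synthesize_surface(
    model: CoarseModel,
    pixel_size: float = 5.0,
    tip: TipModel | None = None,
    margin: float = 20.0,
    grid_like: AFMSurface | None = None,
    drop_to_stage: bool = True,
) -> AFMSurface:
    """Back-calculate a pseudo-AFM topograph from a model (hard tip dilation).

    When ``grid_like`` is given the image is rendered on that surface's
    pixel grid (required when scoring against an experimental image).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if model.n_beads == 0:
        raise ValueError("empty model")
    tip = tip or TipModel()
    coords = _dropped_coords(model, tip.bead_radius) if drop_to_stage else model.coords
    if grid_like is not None:
        pixel_size = grid_like.pixel_size
    xs, ys, origin = _grid_axes(coords, pixel_size, margin, grid_like)
    R = tip.contact_radius
    dx = xs[None, :] - coords[:, 0][:, None]          # (n_beads, nx)
    dy = ys[None, :] - coords[:, 1][:, None]          # (n_beads, ny)
    heights = np.zeros((len(ys), len(xs)))
    # per-bead sphere caps, max-composited
    for i in range(coords.shape[0]):
        rho2 = dy[i][:, None] ** 2 + dx[i][None, :] ** 2
        contact = rho2 <= R * R
        if not np.any(contact):
            continue
        h = np.zeros_like(rho2)
        h[contact] = coords[i, 2] - tip.radius + np.sqrt(R * R - rho2[contact])
        np.maximum(heights, h, out=heights)
    np.clip(heights, 0.0, None, out=heights)
    return AFMSurface(heights, pixel_size=pixel_size, origin=origin)


def synthesize_surface_soft(
    coords: np.ndarray,
    grid_like: AFMSurface,
    tip: TipModel,
    temperature: float = 1.0,
    return_grad: bool = False,
):
    """Smooth pseudo-image from bead coordinates on an existing pixel grid.

    With q = R^2 - rho^2 and the hyperbolic smooth rectifier
    t = sqrt(q^2 + beta^2), spos = (t + q)/2, sneg = (t - q)/2
    (smooth relu(q) / relu(-q) with smoothing scale beta = 2*R*tau), the
    per-bead smooth contact height is

        c_i = z_i - r_t + sqrt(spos) - sneg / lam,     lam = R / 2,

    i.e. the tip-sphere contact profile with a smoothed cap edge plus a
    smooth lateral decay that drives far-away contributions to -infinity
    (so distant beads never raise the background).  Per pixel the bead
    heights combine with the bare stage (height 0) through a
    log-sum-exp of temperature ``tau``, giving a C-infinity surrogate of
    the hard dilation whose analytic gradient the force routine uses.
    Returns heights (ny, nx); with ``return_grad=True`` also returns
    (p, dx, dy, dc_dq), where p = dh/dc_i.
    """
    coords = np.asarray(coords, dtype=float)
    xs, ys = grid_like.x_coords(), grid_like.y_coords()
    R = tip.contact_radius
    tau = temperature
    beta = 2.0 * R * tau
    lam = R / 2.0
    dx = xs[None, None, :] - coords[:, 0][:, None, None]     # (n, 1, nx)
    dy = ys[None, :, None] - coords[:, 1][:, None, None]     # (n, ny, 1)
    rho2 = dx * dx + dy * dy                                  # (n, ny, nx)
    q = R * R - rho2
    t = np.sqrt(q * q + beta * beta)
    root = np.sqrt(0.5 * (t + q) + 1e-12)
    c = coords[:, 2][:, None, None] - tip.radius + root - 0.5 * (t - q) / lam
    dc_dq = (q / t + 1.0) / (4.0 * root) + (1.0 - q / t) / (2.0 * lam)
    cmax = np.maximum(c.max(axis=0), 0.0)                     # (ny, nx)
    expc = np.exp(np.maximum((c - cmax[None]) / tau, -700.0))
    denom = np.exp(-cmax / tau) + expc.sum(axis=0)            # stage term + beads
    h = cmax + tau * np.log(denom)
    if not return_grad:
        return h
    p = expc / denom[None]                                    # d h / d c_i
    return h, (p, dx, dy, dc_dq)


def add_gaussian_noise(surface: AFMSurface, level: float, seed: int) -> AFMSurface:
    """Add i.i.d. zero-mean Gaussian noise with sigma = level * max height.

    Negative results are clipped to zero (heights are non-negative after
    background leveling).  Deterministic per seed.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("noise level must lie in [0, 1]")
    if level == 0.0:
        return AFMSurface(surface.heights.copy(), surface.pixel_size, surface.origin)
    rng = np.random.default_rng(seed)
    sigma = level * float(surface.heights.max())
    noisy = surface.heights + rng.normal(0.0, sigma, size=surface.heights.shape)
    return AFMSurface(np.clip(noisy, 0.0, None), surface.pixel_size, surface.origin)


def estimate_background_noise(
    surface: AFMSurface,
    particle_mask: np.ndarray | None = None,
    auto_threshold: float = 0.05,
) -> NoiseEstimate:
    """Mean and standard deviation of background (particle-free) heights.

    ``particle_mask`` marks particle pixels (True = particle).  Without a
    mask, pixels below ``auto_threshold`` of the maximum height are taken
    as background.
    """
    z = surface.heights
    if particle_mask is not None:
        particle_mask = np.asarray(particle_mask, dtype=bool)
        if particle_mask.shape != z.shape:
            raise ValueError("mask shape mismatch")
        background = z[~particle_mask]
    else:
        background = z[z < auto_threshold * z.max()]
    if background.size < 2:
        raise ValueError("no background pixels to estimate noise from")
    return NoiseEstimate(
        mean=float(background.mean()),
        sigma=float(background.std(ddof=1)),
        n_pixels=int(background.size),
    )


# ---------------------------------------------------------------------------
# Fourier-ring resolution analysis
# ---------------------------------------------------------------------------

def nyquist_nm_inv(surface: AFMSurface) -> float:
    """Nyquist frequency along an axis, nm^-1 (10 / (2 * pixel size in A))."""
    return 10.0 / (2.0 * surface.pixel_size)


def full_band_nm_inv(surface: AFMSurface) -> float:
    """Largest radial frequency on the grid (at the spectrum corner), nm^-1."""
    fy = np.fft.fftfreq(surface.heights.shape[0], d=surface.pixel_size)
    fx = np.fft.fftfreq(surface.heights.shape[1], d=surface.pixel_size)
    return 10.0 * float(np.hypot(np.abs(fy).max(), np.abs(fx).max()))


def _radial_freq_nm_inv(surface: AFMSurface) -> np.ndarray:
    ny, nx = surface.heights.shape
    fy = np.fft.fftfreq(ny, d=surface.pixel_size)
    fx = np.fft.fftfreq(nx, d=surface.pixel_size)
    return 10.0 * np.hypot(fy[:, None], fx[None, :])


def lowpass_ring(surface: AFMSurface, cutoff_nm_inv: float) -> AFMSurface:
    """Low-pass Fourier-ring filter: zero radial frequencies above the cutoff.

    Cutoff is a spatial frequency in nm^-1.  Cutoffs at or above the corner
    frequency (:func:`full_band_nm_inv`) pass the image unchanged.
    """
    if cutoff_nm_inv <= 0:
        raise ValueError("cutoff must be positive")
    spec = np.fft.fft2(surface.heights)
    mask = _radial_freq_nm_inv(surface) <= cutoff_nm_inv + 1e-12
    filtered = np.fft.ifft2(spec * mask).real
    return AFMSurface(filtered, surface.pixel_size, surface.origin)


def acv(reference: AFMSurface, filtered: AFMSurface) -> float:
    """Mean-centered normalized cross-correlation between two images."""
    r = reference.heights.ravel()
    f = filtered.heights.ravel()
    if r.shape != f.shape:
        raise ValueError("surfaces must share shape")
    dr = r - r.mean()
    df = f - f.mean()
    nr = np.sqrt(np.sum(dr * dr) * np.sum(df * df))
    if nr == 0:
        raise ValueError("zero-variance input")
    return float(np.clip(np.sum(dr * df) / nr, -1.0, 1.0))


def resolution_profile(surface: AFMSurface, n_rings: int = 32) -> ACVProfile:
    """ACV of low-pass reconstructions over increasing ring cutoffs.

    Cutoffs run from the lowest non-zero grid frequency to the corner
    frequency; the profile reaches 1 at the endpoint.  The derivative is a
    finite difference of ACV over cutoff; local structure (kinks) marks the
    frequencies where real image features live.
    """
    if n_rings < 4:
        raise ValueError("need at least 4 rings")
    if np.ptp(surface.heights) == 0:
        raise ValueError("degenerate (flat) surface")
    fmax = full_band_nm_inv(surface)
    fmin = 10.0 / (surface.pixel_size * max(surface.heights.shape))
    cutoffs = np.linspace(fmin, fmax, n_rings)
    values = np.array([acv(surface, lowpass_ring(surface, c)) for c in cutoffs])
    derivative = np.gradient(values, cutoffs)
    return ACVProfile(cutoffs=cutoffs, acv=values, derivative=derivative)


def detect_kinks(profile: ACVProfile, prominence: float = 3.0) -> np.ndarray:
    """Heuristic kink detection: local maxima of the ACV derivative above
    ``prominence`` times its median.  The profile itself is the primary
    output; visual inspection is the reference practice."""
    d = profile.derivative
    med = np.median(np.abs(d)) or 1e-12
    peaks = []
    for i in range(1, len(d) - 1):
        if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] > prominence * med:
            peaks.append(i)
    return profile.cutoffs[np.array(peaks, dtype=int)] if peaks else np.array([])
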