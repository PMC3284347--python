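"""Zone-plate optics, magnification correction, and phase-correlation alignment.

The objective Fresnel zone plate's focal length depends on the incident X-ray
energy (f = D*delta_r/lambda at first diffraction order), so images recorded
at different energies have different magnifications and must be rescaled to a
common reference before per-pixel analysis. Residual stage/motor shifts are
then removed by FFT phase correlation with subpixel (parabolic) refinement.

Shift convention: ``Shift(dy, dx)`` is the displacement that must be *added*
to the moving image's content to land on the reference. If the moving image
is the reference displaced by ``(ty, tx)`` (its content appears at
``(row + ty, col + tx)``), the measured shift is ``(-ty, -tx)``, and
``apply_shift`` translates the moving image by that amount to align it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.ndimage

from txmkit.io import EnergyStack, ProjectionSeries

#: hc in eV*nm, used to convert photon energy to wavelength.
HC_EV_NM = 1239.842

#: Default minimum phase-correlation peak quality before a frame is flagged.
Q_MIN = 0.05


@dataclass(frozen=True)
class ZonePlate:
    """Fresnel zone-plate optic: diameter D (um) and outermost zone width (nm)."""

    D_um: float
    delta_r_nm: float

    def __post_init__(self) -> None:
        if self.D_um <= 0 or self.delta_r_nm <= 0:
            raise ValueError("zone-plate dimensions must be positive")

    @property
    def n_zones(self) -> float:
        """Total number of zones, N = D / (4 * delta_r)."""
        return self.D_um * 1e3 / (4.0 * self.delta_r_nm)


@dataclass(frozen=True)
class Geometry:
    """Imaging geometry: fixed sample-to-detector distance L (mm)."""

    L_mm: float

    def __post_init__(self) -> None:
        if self.L_mm <= 0:
            raise ValueError("L must be positive")


@dataclass(frozen=True)
class Shift:
    """Measured (dy, dx) displacement in pixels plus correlation peak quality."""

    dy: float
    dx: float
    peak_quality: float = 1.0


def zp_focal_length(zp: ZonePlate, energy_eV: float) -> float:
    """First-order focal length of a zone plate in mm, f = D*delta_r/lambda."""
    if energy_eV <= 0:
        raise ValueError("energy must be positive")
    lam_nm = HC_EV_NM / energy_eV
    f_nm = (zp.D_um * 1e3) * zp.delta_r_nm / lam_nm
    return f_nm * 1e-6


def magnification(zp: ZonePlate, geom: Geometry, energy_eV: float) -> float:
    """Magnification M = v/u from the thin-lens equation at fixed u + v = L.

    Solves 1/u + 1/v = 1/f with u + v = L and takes the magnifying root
    u = (L - sqrt(L^2 - 4 f L)) / 2, so M > 1.
    """
    f = zp_focal_length(zp, energy_eV)
    L = geom.L_mm
    disc = L * L - 4.0 * f * L
    if disc <= 0:
        raise ValueError(
            f"no real focus for this geometry: f={f:.4g} mm >= L/4={L / 4:.4g} mm"
        )
    u = (L - math.sqrt(disc)) / 2.0
    v = L - u
    return v / u


def rescale_to_reference(
    img: np.ndarray, M: float, M_ref: float, order: int = 3
) -> np.ndarray:
    """Resample an image about its center by scale s = M_ref / M (bicubic).

    Output has the input's shape; regions scaled in from outside the frame are
    filled by edge replication. Scales outside [0.5, 2] are rejected as
    implausible metadata.
    """
    if M <= 0 or M_ref <= 0:
        raise ValueError("magnifications must be positive")
    s = M_ref / M
    if not 0.5 <= s <= 2.0:
        raise ValueError(f"scale {s:.3g} outside [0.5, 2]; check metadata")
    img = np.asarray(img, dtype=float)
    if s == 1.0:
        return img.copy()
    center = (np.asarray(img.shape) - 1) / 2.0
    # output coord r maps to input coord center + (r - center)/s
    matrix = np.eye(2) / s
    offset = center - matrix @ center
    return scipy.ndimage.affine_transform(
        img, matrix, offset=offset, order=order, mode="nearest"
    )


def _parabolic_offset(y_minus: float, y0: float, y_plus: float) -> float:
    denom = 2.0 * (2.0 * y0 - y_minus - y_plus)
    if denom == 0:
        return 0.0
    off = (y_plus - y_minus) / denom
    # parabola vertex outside (-1, 1) means the fit is meaningless
    return float(np.clip(off, -0.999, 0.999))


def phase_correlate(
    reference: np.ndarray,
    moving: np.ndarray,
    window: str | None = "hann",
    eps_frac: float = 1e-12,
) -> Shift:
    """Measure the translation of ``moving`` relative to ``reference``.

    Computes the whitened cross-power spectrum
    ``R = F_ref * conj(F_mov) / |F_ref * conj(F_mov)|`` (with an eps floor on
    the magnitude), inverse transforms it, and maps the correlation peak to a
    signed shift in ``[-H/2, H/2) x [-W/2, W/2)``. Subpixel refinement uses a
    separable 3-point parabolic fit. ``peak_quality`` is the height of the
    normalized correlation peak, clipped to [0, 1].

    A raised-cosine (Hann) window is applied before the FFT by default to
    suppress wrap-around edge artifacts on non-periodic images; pass
    ``window=None`` for strictly periodic (circularly shifted) data.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    if ref.ndim != 2:
        raise ValueError("images must be 2D")
    if np.ptp(ref) == 0 and np.ptp(mov) == 0:
        raise ValueError("no spectral content: both images are constant")

    if window == "hann":
        wr = np.hanning(ref.shape[0])[:, None]
        wc = np.hanning(ref.shape[1])[None, :]
        w2d = wr * wc
        ref = (ref - ref.mean()) * w2d
        mov = (mov - mov.mean()) * w2d
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")

    F_ref = scipy.fft.fft2(ref)
    F_mov = scipy.fft.fft2(mov)
    cross = F_ref * np.conj(F_mov)
    mag = np.abs(cross)
    floor = eps_frac * mag.max()
    if mag.max() == 0:
        raise ValueError("no spectral content")
    R = cross / np.maximum(mag, floor)
    corr = scipy.fft.ifft2(R).real

    peak_flat = int(np.argmax(corr))
    py, px = np.unravel_index(peak_flat, corr.shape)
    H, W = corr.shape

    dy = _parabolic_offset(
        corr[(py - 1) % H, px], corr[py, px], corr[(py + 1) % H, px]
    )
    dx = _parabolic_offset(
        corr[py, (px - 1) % W], corr[py, px], corr[py, (px + 1) % W]
    )

    # map peak index to signed shift in [-H/2, H/2)
    sy = py - H if py >= H / 2 else py
    sx = px - W if px >= W / 2 else px
    quality = float(np.clip(corr[py, px], 0.0, 1.0))
    return Shift(dy=sy + dy, dx=sx + dx, peak_quality=quality)


def apply_shift(img: np.ndarray, shift: Shift, order: int = 3) -> np.ndarray:
    """Translate an image so that a frame measured as ``shift`` lands on the
    reference (bicubic resampling, edge replication)."""
    return scipy.ndimage.shift(
        np.asarray(img, dtype=float),
        (shift.dy, shift.dx),
        order=order,
        mode="nearest",
    )


def align_stack(
    stack: EnergyStack | ProjectionSeries,
    reference_index: int = 0,
    q_min: float = Q_MIN,
    window: str | None = "hann",
) -> tuple[EnergyStack | ProjectionSeries, list[Shift]]:
    """Align every frame of a stack onto the frame at ``reference_index``.

    Returns the aligned stack plus the per-frame measured shifts. Frames whose
    correlation peak quality falls below ``q_min`` are still shifted but a
    warning is emitted; dropping them is the caller's decision.
    """
    n = stack.data.shape[0]
    if not 0 <= reference_index < n:
        raise IndexError(f"reference_index {reference_index} out of range")
    ref = stack.data[reference_index]
    aligned = np.empty_like(stack.data)
    shifts: list[Shift] = []
    for i in range(n):
        if i == reference_index:
            s = Shift(0.0, 0.0, 1.0)
            aligned[i] = stack.data[i]
        else:
            s = phase_correlate(ref, stack.data[i], window=window)
            if s.peak_quality < q_min:
                warnings.warn(
                    f"frame {i}: peak quality {s.peak_quality:.3g} < {q_min}"
                )
            aligned[i] = apply_shift(stack.data[i], s)
        shifts.append(s)
    if isinstance(stack, EnergyStack):
        out = EnergyStack(
            aligned,
            stack.energies_eV,
            corrected=stack.corrected,
            pixel_size_nm=stack.pixel_size_nm,
            motor_xy_um=stack.motor_xy_um,
        )
    else:
        out = ProjectionSeries(
            aligned, stack.angles_deg, pixel_size_nm=stack.pixel_size_nm
        )
    return out, shifts


def log_polar_correlate(
    reference: np.ndarray,
    moving: np.ndarray,
    rho_min: float = 2.0,
    n_theta: int = 360,
) -> tuple[float, float]:
    """Optional second registration stage: rotation (deg) and scale of the
    moving image relative to the reference via log-polar phase correlation.

    Intended for images whose translation has already been removed (the
    primary, translation-only path); off by default in every pipeline. Both
    images are resampled onto a log-polar grid about their center, the
    rotation-invariant radial profile is subtracted (otherwise it pins the
    correlation peak at zero), and the residual rotation appears as a
    circular shift along the angle axis, the scale as a shift along log-rho.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    H, W = ref.shape
    n_rho = min(H, W)
    radius = min(H, W) / 2.0
    base = (radius / rho_min) ** (1.0 / n_rho)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rho = rho_min * base ** np.arange(n_rho)
    rr = rho[None, :] * np.sin(theta[:, None]) + (H - 1) / 2.0
    cc = rho[None, :] * np.cos(theta[:, None]) + (W - 1) / 2.0

    def to_lp(img: np.ndarray) -> np.ndarray:
        lp = scipy.ndimage.map_coordinates(img, [rr, cc], order=1, mode="nearest")
        return lp - lp.mean(axis=0, keepdims=True)

    s = phase_correlate(to_lp(ref), to_lp(mov), window=None)
    rotation_deg = s.dy * 360.0 / n_theta
    scale = base ** (-s.dx)
    return rotation_deg, scale
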