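"""Parallel-beam tomography: forward projection, FBP, iterative ART.

Geometry convention shared by every routine here: for a projection at angle
``theta`` the detector coordinate of image pixel ``(r, c)`` is

    t = (c - cc) * cos(theta) + (r - cr) * sin(theta)

with ``(cr, cc)`` the image center ``((n-1)/2, (n-1)/2)``, so at 0 degrees the
detector axis coincides with the column axis. The rotation axis maps to
sinogram column ``center`` (default ``(W-1)/2``).

Angles are degrees in every public interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage

from txmkit.io import ProjectionSeries
from txmkit.registration import Shift, apply_shift, phase_correlate

FILTERS = ("ramlak", "shepp", "hann")


@dataclass
class Sinogram:
    """One slice row's projections: (n_angles x n_detector_cols)."""

    data: np.ndarray
    angles_deg: np.ndarray
    center: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("sinogram must be 2D (angles x detector)")
        if self.data.shape[0] != self.angles_deg.size:
            raise ValueError("angle count mismatch")
        if self.center is None:
            self.center = (self.data.shape[1] - 1) / 2.0
        if not 0 <= self.center <= self.data.shape[1] - 1:
            raise ValueError("center outside detector range")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


@dataclass
class ReconVolume:
    """Reconstructed slice (2D) or volume (3D) of attenuation values."""

    data: np.ndarray
    voxel_size_nm: float = np.nan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reconstruction contains non-finite values")


# ---------------------------------------------------------------------------
# forward projection


def forward_project(image: np.ndarray, angles_deg) -> Sinogram:
    """Parallel-beam Radon transform by bilinear ray sampling (unit step)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square 2D")
    n = image.shape[0]
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    c = (n - 1) / 2.0
    t = np.arange(n) - c  # detector offsets
    s = np.arange(n) - c  # path offsets
    tt, ss = np.meshgrid(t, s, indexing="ij")  # (detector, path)
    sino = np.empty((angles.size, n))
    for i, a in enumerate(angles):
        th = np.deg2rad(a)
        rr = c + tt * np.sin(th) + ss * np.cos(th)
        cc = c + tt * np.cos(th) - ss * np.sin(th)
        vals = scipy.ndimage.map_coordinates(
            image, [rr, cc], order=1, mode="constant", cval=0.0
        )
        sino[i] = vals.sum(axis=1)
    return Sinogram(sino, angles, center=c)


# ---------------------------------------------------------------------------
# filtered back projection


def _ramp_filter(n_pad: int, kind: str) -> np.ndarray:
    # ramp from the FFT of the band-limited spatial kernel (Kak & Slaney);
    # sampling |f| directly would zero DC and introduce a cupping bias
    kernel = np.zeros(n_pad)
    kernel[0] = 0.25
    odd = np.arange(1, n_pad // 2 + 1, 2)
    kernel[odd] = -1.0 / (np.pi * odd) ** 2
    kernel[-odd] = -1.0 / (np.pi * odd) ** 2
    filt = 2.0 * np.real(scipy.fft.fft(kernel))
    f = scipy.fft.fftfreq(n_pad)
    if kind == "ramlak":
        return filt
    if kind == "shepp":
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.sinc(f)  # sin(pi f)/(pi f)
        return filt * sinc
    if kind == "hann":
        return filt * 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
    raise ValueError(f"unknown filter {kind!r}; choose from {FILTERS}")


def filter_sinogram(sino: Sinogram, kind: str = "ramlak") -> np.ndarray:
    """Apply the chosen ramp filter row-wise in the frequency domain."""
    n = sino.n_cols
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * n))))
    filt = _ramp_filter(n_pad, kind)
    padded = np.zeros((sino.n_angles, n_pad))
    padded[:, :n] = sino.data
    filtered = scipy.fft.ifft(scipy.fft.fft(padded, axis=1) * filt, axis=1).real
    return filtered[:, :n]


def fbp_reconstruct(
    sino: Sinogram,
    filter: str = "ramlak",
    roi: tuple[int, int, int, int] | None = None,
) -> ReconVolume:
    """Filtered back projection of one sinogram onto an n x n grid.

    ``roi = (r0, c0, h, w)`` restricts back projection to that sub-grid of
    the full reconstruction (local tomography); pixel coordinates stay those
    of the full grid, so the ROI result equals the corresponding crop of the
    full reconstruction.
    """
    span = np.ptp(sino.angles_deg)
    if sino.n_angles >= 2 and span < 120.0:
        warnings.warn("angular span < 120 degrees: limited-angle artifacts expected")
    n = sino.n_cols
    filtered = filter_sinogram(sino, filter)

    if roi is None:
        r0, c0, h, w = 0, 0, n, n
    else:
        r0, c0, h, w = roi
        if not (0 <= r0 and 0 <= c0 and r0 + h <= n and c0 + w <= n):
            raise ValueError("roi outside reconstruction grid")

    c_img = (n - 1) / 2.0
    rows = np.arange(r0, r0 + h) - c_img
    cols = np.arange(c0, c0 + w) - c_img
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.zeros((h, w))
    det = np.arange(n, dtype=float)
    for i, a in enumerate(sino.angles_deg):
        th = np.deg2rad(a)
        t = cc * np.cos(th) + rr * np.sin(th) + sino.center
        out += np.interp(t, det, filtered[i], left=0.0, right=0.0)
    out *= np.pi / (2.0 * sino.n_angles)
    return ReconVolume(out)


# ---------------------------------------------------------------------------
# algebraic reconstruction (Kaczmarz)


def _system_rows(n: int, angles_deg: np.ndarray, center: float):
    """Bilinear ray footprints, angle-major; yields (indices, weights) rows."""
    c = (n - 1) / 2.0
    s = np.arange(n) - c
    rows = []
    for a in angles_deg:
        th = np.deg2rad(a)
        for d in range(n):
            t = d - center
            rr = c + t * np.sin(th) + s * np.cos(th)
            cc = c + t * np.cos(th) - s * np.sin(th)
            r0 = np.floor(rr).astype(int)
            c0 = np.floor(cc).astype(int)
            fr = rr - r0
            fc = cc - c0
            idx_list = []
            w_list = []
            for dr, dc, w in (
                (0, 0, (1 - fr) * (1 - fc)),
                (0, 1, (1 - fr) * fc),
                (1, 0, fr * (1 - fc)),
                (1, 1, fr * fc),
            ):
                ri = r0 + dr
                ci = c0 + dc
                ok = (ri >= 0) & (ri < n) & (ci >= 0) & (ci < n) & (w > 0)
                idx_list.append(ri[ok] * n + ci[ok])
                w_list.append(w[ok])
            idx = np.concatenate(idx_list)
            wgt = np.concatenate(w_list)
            # merge duplicate pixel indices
            order = np.argsort(idx, kind="stable")
            idx, wgt = idx[order], wgt[order]
            uniq, start = np.unique(idx, return_index=True)
            wgt = np.add.reduceat(wgt, start)
            rows.append((uniq, wgt))
    return rows


def art_reconstruct(
    sino: Sinogram,
    n_iter: int = 10,
    relax: float = 0.25,
    nonneg: bool = False,
    x0: np.ndarray | None = None,
) -> ReconVolume:
    """Kaczmarz ART: cycle rays angle-major, n_iter full sweeps.

    Per-ray update: x <- x + relax * (p_i - <a_i, x>) / ||a_i||^2 * a_i.
    With ``nonneg`` the image is clamped at zero after every sweep. Stops
    early with a warning if the data residual grows 3 sweeps in a row.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < relax <= 1:
        raise ValueError("relax must be in (0, 1]")
    n = sino.n_cols
    rows = _system_rows(n, sino.angles_deg, sino.center)
    p = sino.data.ravel()
    x = np.zeros(n * n) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    norms = np.array([w @ w for _, w in rows])

    def residual() -> float:
        r = 0.0
        for (idx, w), pi in zip(rows, p):
            r += (pi - w @ x[idx]) ** 2
        return np.sqrt(r)

    prev = np.inf
    n_growing = 0
    for sweep in range(n_iter):
        for (idx, w), pi, nrm in zip(rows, p, norms):
            if nrm == 0:
                continue
            x[idx] += relax * (pi - w @ x[idx]) / nrm * w
        if nonneg:
            np.clip(x, 0.0, None, out=x)
        res = residual()
        if res > prev:
            n_growing += 1
            if n_growing >= 3:
                warnings.warn(
                    f"ART residual grew 3 consecutive sweeps; stopping at sweep {sweep + 1}"
                )
                break
        else:
            n_growing = 0
        prev = res
    return ReconVolume(x.reshape(n, n))


# ---------------------------------------------------------------------------
# jitter correction


def jitter_correct(
    series: ProjectionSeries,
    method: str = "auto",
    detrend_order: int = 4,
    template_box: tuple[int, int, int, int] | None = None,
) -> tuple[ProjectionSeries, np.ndarray]:
    """Remove per-angle random stage jitter from a projection series.

    auto mode: phase-correlate consecutive projections (no window:
    projections taper to zero at the detector edges, so wrap-around is not an
    issue and windowing only discards signal), accumulate the chain, then
    subtract a low-order polynomial of angle (the smooth component
    attributable to genuine parallax) so that only jitter is removed. Order 4
    by default: on jitter-free phantom series a quadratic leaves up to ~0.7 px
    of parallax misclassified as jitter, a quartic under 0.1 px.

    template mode: track a user-supplied feature box ``(r0, c0, h, w)`` by
    normalized cross-correlation against the first frame.

    Returns the corrected series and the (n_angles, 2) table of applied
    (dy, dx) shifts.
    """
    n = series.n_angles
    if n < 2:
        return series, np.zeros((n, 2))

    if method == "auto":
        steps = np.zeros((n, 2))
        for i in range(1, n):
            s = phase_correlate(series.data[i - 1], series.data[i], window=None)
            steps[i] = (s.dy, s.dx)
        cum = np.cumsum(steps, axis=0)
        jitter = np.empty_like(cum)
        x = series.angles_deg
        for axis in range(2):
            coeffs = np.polyfit(x, cum[:, axis], detrend_order)
            jitter[:, axis] = cum[:, axis] - np.polyval(coeffs, x)
    elif method == "template":
        if template_box is None:
            raise ValueError("template mode requires template_box")
        jitter = -_track_template(series.data, template_box)
    else:
        raise ValueError(f"unknown method {method!r}")

    corrected = np.empty_like(series.data)
    for i in range(n):
        corrected[i] = apply_shift(series.data[i], Shift(jitter[i, 0], jitter[i, 1]))
    out = ProjectionSeries(
        corrected, series.angles_deg, pixel_size_nm=series.pixel_size_nm
    )
    return out, jitter


def _track_template(
    frames: np.ndarray, box: tuple[int, int, int, int]
) -> np.ndarray:
    from skimage.feature import match_template

    r0, c0, h, w = box
    template = frames[0][r0 : r0 + h, c0 : c0 + w]
    shifts = np.zeros((frames.shape[0], 2))
    for i in range(1, frames.shape[0]):
        ncc = match_template(frames[i], template, pad_input=True)
        peak = np.unravel_index(np.argmax(ncc), ncc.shape)
        # match_template(pad_input) peak is at template center position
        shifts[i] = (
            peak[0] - (r0 + (h - 1) / 2.0),
            peak[1] - (c0 + (w - 1) / 2.0),
        )
    return shifts


# ---------------------------------------------------------------------------
# rotation center


def find_rotation_center(
    sino: Sinogram, search_half_width: float | None = None
) -> float:
    """Rotation-axis column from 0/180-degree mirror consistency.

    Scans candidate centers on a 0.25 px grid and returns the one minimizing
    the squared mismatch between the first projection and the projection
    nearest 180 degrees away, mirrored about the candidate axis. For spans far
    from 180 or 360 degrees a warning is emitted and the geometric center
    returned.
    """
    span = np.ptp(sino.angles_deg)
    geometric = (sino.n_cols - 1) / 2.0
    if not (
        abs(span - 180.0) <= 15.0
        or abs(span - 360.0) <= 15.0
        or (sino.n_angles > 2 and span >= 165.0)
    ):
        warnings.warn(
            f"angular span {span:.1f} deg far from 180/360; returning geometric center"
        )
        return geometric

    a0 = sino.angles_deg[0]
    j = int(np.argmin(np.abs(sino.angles_deg - (a0 + 180.0))))
    p0 = sino.data[0]
    p180 = sino.data[j]
    det = np.arange(sino.n_cols, dtype=float)
    if search_half_width is None:
        search_half_width = sino.n_cols / 8.0
    candidates = geometric + np.arange(
        -search_half_width, search_half_width + 1e-9, 0.25
    )
    best_c, best_score = geometric, np.inf
    for c in candidates:
        mirrored = np.interp(2.0 * c - det, det, p180, left=0.0, right=0.0)
        valid = (2.0 * c - det >= 0) & (2.0 * c - det <= sino.n_cols - 1)
        if valid.sum() < sino.n_cols // 4:
            continue
        score = np.mean((p0[valid] - mirrored[valid]) ** 2)
        if score < best_score:
            best_score, best_c = score, c
    return float(best_c)


# ---------------------------------------------------------------------------
# volume driver


def reconstruct_volume(
    series: ProjectionSeries,
    algorithm: str = "fbp",
    slices: range | None = None,
    center: float | None = None,
    filter: str = "ramlak",
    roi: tuple[int, int, int, int] | None = None,
    **art_kw,
) -> ReconVolume:
    """Reconstruct selected slice rows of a (jitter-corrected) series.

    Each detector row yields one sinogram reconstructed independently with a
    shared rotation center.
    """
    bad = np.where(~np.isfinite(series.data).all(axis=(1, 2)))[0]
    if bad.size:
        raise ValueError(
            f"non-finite projection at angle {series.angles_deg[bad[0]]:.3f} deg"
        )
    n_rows = series.data.shape[1]
    if slices is None:
        slices = range(n_rows)
    out = []
    for r in slices:
        sino = Sinogram(series.data[:, r, :], series.angles_deg, center=center)
        if algorithm == "fbp":
            rec = fbp_reconstruct(sino, filter=filter, roi=roi)
        elif algorithm == "art":
            rec = art_reconstruct(sino, **art_kw)
            if roi is not None:
                r0, c0, h, w = roi
                rec = ReconVolume(rec.data[r0 : r0 + h, c0 : c0 + w])
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        out.append(rec.data)
    return ReconVolume(np.stack(out), voxel_size_nm=series.pixel_size_nm)
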