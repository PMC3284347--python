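"""Synthetic ground-truth generators for every analysis module.

All generators are pure functions of their parameters and ``seed``: calling
twice with identical arguments returns bit-identical data. Each returns the
synthetic measurement together with a truth bundle sufficient to score any
downstream recovery test without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage

from txmkit.io import EnergyStack, ImageFrame, ProjectionSeries
from txmkit.tomo import forward_project

# value, x-half-axis, y-half-axis, x0, y0, angle_deg  (unit square [-1, 1]^2)
_SHEPP_LOGAN_ELLIPSES = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


def make_shepp_logan(n: int, supersample: int = 4) -> np.ndarray:
    """Classic 10-ellipse head phantom (modified contrast) on an n x n grid,
    values in [0, 1].

    Ellipses are rendered at ``supersample`` times the target resolution and
    block-averaged, so partial pixel coverage at ellipse boundaries is
    represented instead of aliased hard edges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    m = n * supersample
    c = (m - 1) / 2.0
    y = (c - np.arange(m)[:, None]) / (m / 2.0)
    x = (np.arange(m)[None, :] - c) / (m / 2.0)
    img = np.zeros((m, m))
    for val, a, b, x0, y0, phi in _SHEPP_LOGAN_ELLIPSES:
        th = np.deg2rad(phi)
        xr = (x - x0) * np.cos(th) + (y - y0) * np.sin(th)
        yr = -(x - x0) * np.sin(th) + (y - y0) * np.cos(th)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
    img = np.clip(img, 0.0, None)
    return img.reshape(n, supersample, n, supersample).mean(axis=(1, 3))


def make_texture(shape: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Deterministic textured test image in [0, 1] (for mosaic/registration)."""
    rng = np.random.default_rng(seed)
    img = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    img = img + 0.3 * np.sin(2 * np.pi * r / 37.0) * np.cos(2 * np.pi * c / 23.0)
    img = img - img.min()
    return img / img.max()


# ---------------------------------------------------------------------------
# XANES phantom


def arctan_edge(energies_eV: np.ndarray, e_half: float, width_eV: float) -> np.ndarray:
    """Normalized absorption-edge profile: 0 -> 1 sigmoid, 0.5 at e_half."""
    e = np.asarray(energies_eV, dtype=float)
    return 0.5 + np.arctan((e - e_half) / width_eV) / np.pi


@dataclass
class XanesPhantom:
    """Generative model for a spectro-imaging stack.

    OD(E, p) = thickness(p) * sum_i weights[i](p) * edge_i(E)
               + offset(p) + slope(p) * (E - E_mid) + N(0, noise_sigma)
    """

    truth_weights: np.ndarray  # (n_refs, H, W), sums to <= 1 per pixel
    thickness: np.ndarray  # (H, W)
    e_half_eV: tuple[float, ...]
    width_eV: tuple[float, ...]
    baseline_offset: np.ndarray  # (H, W)
    baseline_slope: np.ndarray  # (H, W), OD per eV
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_weights.shape[0] != len(self.e_half_eV):
            raise ValueError("one e_half per reference phase required")
        if len(self.width_eV) != len(self.e_half_eV):
            raise ValueError("one width per reference phase required")

    @property
    def n_refs(self) -> int:
        return self.truth_weights.shape[0]


def default_xanes_phantom(
    shape: tuple[int, int] = (128, 128),
    n_refs: int = 2,
    e_half_eV: tuple[float, ...] | None = None,
    width_eV: float = 1.5,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> XanesPhantom:
    """Two-to-three phase disk sample on empty background.

    Inside a disk covering most of the FOV the material thickness varies
    smoothly (OD edge jump roughly 1-2) and the phase fractions form
    smooth but polarized domains (most pixels are dominated by one phase,
    as in a real multi-phase sample); outside the disk there is no absorber,
    so those pixels carry pure noise and exercise the edge-jump noise filter.
    """
    if e_half_eV is None:
        e_half_eV = (7116.0, 7128.0, 7140.0)[:n_refs]
    if len(e_half_eV) != n_refs:
        raise ValueError("need one e_half per phase")
    H, W = shape
    rng = np.random.default_rng(seed)
    r = np.arange(H)[:, None] - (H - 1) / 2.0
    c = np.arange(W)[None, :] - (W - 1) / 2.0
    disk = np.sqrt(r**2 + c**2) <= 0.45 * min(H, W)

    smooth = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), 8.0)
    smooth = (smooth - smooth.min()) / np.ptp(smooth)
    thickness = np.where(disk, 1.0 + 1.0 * smooth, 0.0)

    fields = np.stack(
        [
            scipy.ndimage.gaussian_filter(rng.standard_normal(shape), 10.0)
            for _ in range(n_refs)
        ]
    )
    fields /= fields.std(axis=(1, 2), keepdims=True)
    # softmax with sharpening polarizes the domains while keeping them smooth
    logits = 3.0 * fields
    weights = np.exp(logits - logits.max(axis=0))
    weights /= weights.sum(axis=0, keepdims=True)
    weights = np.clip(weights, 0.02, 0.98)
    weights /= weights.sum(axis=0, keepdims=True)
    weights *= disk  # no phase outside the sample

    offset = 0.1 + 0.1 * scipy.ndimage.gaussian_filter(
        rng.standard_normal(shape), 12.0
    )
    slope = 0.001 * scipy.ndimage.gaussian_filter(rng.standard_normal(shape), 12.0)
    return XanesPhantom(
        truth_weights=weights,
        thickness=thickness,
        e_half_eV=tuple(e_half_eV),
        width_eV=(width_eV,) * n_refs,
        baseline_offset=offset,
        baseline_slope=slope,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_xanes_stack(
    phantom: XanesPhantom, energies_eV: np.ndarray
) -> tuple[EnergyStack, dict]:
    """Render a phantom onto an energy grid.

    Returns the (noisy) OD stack and a truth bundle with keys:
    ``weights`` (relative phase fractions per pixel), ``thickness``,
    ``e_half_map`` (energy of the half-height of the noiseless, baseline-free
    mixture edge; NaN where there is no absorber), ``edge_jump`` (asymptotic
    jump thickness * sum(w)), ``clean`` (noise-free stack), and ``profiles``
    (n_refs x n_energies matrix of the generating edge profiles).
    """
    energies = np.asarray(energies_eV, dtype=float)
    n_refs = phantom.n_refs
    profiles = np.stack(
        [
            arctan_edge(energies, phantom.e_half_eV[i], phantom.width_eV[i])
            for i in range(n_refs)
        ]
    )
    w = phantom.truth_weights
    H, Wd = phantom.thickness.shape
    # (E, H, W) signal
    signal = phantom.thickness * np.tensordot(profiles.T, w, axes=([1], [0]))
    e_mid = 0.5 * (energies[0] + energies[-1])
    baseline = (
        phantom.baseline_offset[None]
        + phantom.baseline_slope[None] * (energies[:, None, None] - e_mid)
    )
    clean = signal + baseline
    rng = np.random.default_rng(phantom.seed)
    noisy = clean + (
        rng.normal(0.0, phantom.noise_sigma, clean.shape)
        if phantom.noise_sigma > 0
        else 0.0
    )

    # analytic half-height energy of the baseline-free mixture edge
    fine = np.arange(energies[0], energies[-1] + 0.005, 0.01)
    fine_profiles = np.stack(
        [
            arctan_edge(fine, phantom.e_half_eV[i], phantom.width_eV[i])
            for i in range(n_refs)
        ]
    )
    wsum = w.sum(axis=0)
    e_half_map = np.full((H, Wd), np.nan)
    valid = wsum > 0
    mix = np.tensordot(fine_profiles.T, w, axes=([1], [0]))  # (fine, H, W)
    half = 0.5 * wsum
    above = mix >= half[None]
    first = above.argmax(axis=0)
    has_cross = above.any(axis=0) & valid & (first > 0)
    f1 = first[has_cross]
    cols = np.where(has_cross.ravel())[0]
    mix_flat = mix.reshape(mix.shape[0], -1)
    y1 = mix_flat[f1, cols]
    y0 = mix_flat[f1 - 1, cols]
    h = half.ravel()[cols]
    frac = np.where(y1 > y0, (h - y0) / np.where(y1 > y0, y1 - y0, 1.0), 0.0)
    e_half_map.ravel()[cols] = fine[f1 - 1] + frac * 0.01

    truth = {
        "weights": w.copy(),
        "thickness": phantom.thickness.copy(),
        "e_half_map": e_half_map,
        "edge_jump": phantom.thickness * wsum,
        "clean": clean,
        "profiles": profiles,
    }
    return EnergyStack(noisy, energies, corrected=True), truth


# ---------------------------------------------------------------------------
# mosaic phantom


def make_mosaic_tiles(
    master: np.ndarray,
    grid: tuple[int, int],
    overlap_frac: float = 0.2,
    jitter_px: int = 0,
    vignette_strength: float = 0.0,
    noise_sigma: float = 0.0,
    pixel_size_nm: float = 50.0,
    seed: int = 0,
) -> tuple[list[ImageFrame], pd.DataFrame, np.ndarray]:
    """Cut a master image into an overlapping tile grid with motor metadata.

    Tiles are cut at integer positions perturbed by uniform integer jitter in
    ``[-jitter_px, jitter_px]`` (tile 0 is never jittered: it anchors the
    layout); the motor metadata reports the unperturbed nominal positions, so
    the jitter emulates motor error. Radial vignetting and Gaussian noise are
    then applied per tile.

    Returns ``(tiles, metadata, truth_offsets)`` where ``truth_offsets`` is
    the (n_tiles, 2) array of actual (row, col) cut positions.
    """
    master = np.asarray(master, dtype=float)
    H, W = master.shape
    rows, cols = grid
    if not 0 <= overlap_frac <= 0.9:
        raise ValueError("overlap_frac must be in [0, 0.9]")
    rng = np.random.default_rng(seed)

    def layout(n_img: int, n_tiles: int) -> tuple[int, np.ndarray]:
        if n_tiles == 1:
            return n_img, np.array([0])
        tile = int(round(n_img / ((n_tiles - 1) * (1.0 - overlap_frac) + 1.0)))
        step = (n_img - tile) / (n_tiles - 1)
        starts = np.round(np.arange(n_tiles) * step).astype(int)
        return tile, starts

    tile_h, starts_r = layout(H, rows)
    tile_w, starts_c = layout(W, cols)

    tiles: list[ImageFrame] = []
    meta_rows = []
    truth = []
    for i, r0 in enumerate(starts_r):
        for j, c0 in enumerate(starts_c):
            idx = i * cols + j
            if jitter_px > 0 and idx > 0:
                jr = int(rng.integers(-jitter_px, jitter_px + 1))
                jc = int(rng.integers(-jitter_px, jitter_px + 1))
            else:
                jr = jc = 0
            ar = int(np.clip(r0 + jr, 0, H - tile_h))
            ac = int(np.clip(c0 + jc, 0, W - tile_w))
            patch = master[ar : ar + tile_h, ac : ac + tile_w].copy()
            if vignette_strength > 0:
                ry = (np.arange(tile_h)[:, None] - (tile_h - 1) / 2) / (tile_h / 2)
                rx = (np.arange(tile_w)[None, :] - (tile_w - 1) / 2) / (tile_w / 2)
                patch *= 1.0 - vignette_strength * (ry**2 + rx**2) / 2.0
            if noise_sigma > 0:
                patch += rng.normal(0.0, noise_sigma, patch.shape)
            tiles.append(
                ImageFrame(
                    patch,
                    motor_x_um=c0 * pixel_size_nm / 1000.0,
                    motor_y_um=r0 * pixel_size_nm / 1000.0,
                    pixel_size_nm=pixel_size_nm,
                )
            )
            meta_rows.append(
                {
                    "motor_x_um": c0 * pixel_size_nm / 1000.0,
                    "motor_y_um": r0 * pixel_size_nm / 1000.0,
                    "pixel_size_nm": pixel_size_nm,
                }
            )
            truth.append((ar, ac))
    return tiles, pd.DataFrame(meta_rows), np.asarray(truth, dtype=float)


# ---------------------------------------------------------------------------
# tomography phantom


def make_test_volume(
    n: int = 64, n_slices: int = 24, twist_deg_per_slice: float = 4.0
) -> np.ndarray:
    """A 3D phantom for projection-series tests: the head phantom twisted
    slice by slice and amplitude-tapered to zero at the axial ends.

    The twist makes the axial structure full-rank (an untwisted stack is a
    separable outer product, which degenerates row-axis phase correlation),
    and the taper keeps projections compact in the frame so non-windowed
    registration is valid.
    """
    base = make_shepp_logan(n)
    prof = np.sin(np.linspace(0.0, np.pi, n_slices)) ** 2
    return np.stack(
        [
            scipy.ndimage.rotate(
                base, twist_deg_per_slice * s, reshape=False, order=1
            )
            * prof[s]
            for s in range(n_slices)
        ]
    )


def make_projection_series(
    phantom: np.ndarray,
    angles_deg,
    jitter_px: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ProjectionSeries, np.ndarray]:
    """Forward-project a phantom and inject per-angle jitter and noise.

    ``phantom`` may be 2D (one slice; frames have one row) or 3D
    ``(n_slices, n, n)``. Jitter is a uniform(-jitter_px, +jitter_px)
    (dy, dx) translation applied to each frame (frame 0 stays fixed);
    the truth table of injected displacements is returned.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    vol = np.asarray(phantom, dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    n_slices, n, _ = vol.shape
    frames = np.empty((angles.size, n_slices, n))
    for s in range(n_slices):
        frames[:, s, :] = forward_project(vol[s], angles).data

    rng = np.random.default_rng(seed)
    truth = np.zeros((angles.size, 2))
    if jitter_px > 0:
        truth[1:] = rng.uniform(-jitter_px, jitter_px, (angles.size - 1, 2))
        for i in range(1, angles.size):
            frames[i] = scipy.ndimage.shift(
                frames[i], truth[i], order=3, mode="nearest"
            )
    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, frames.shape)
    return ProjectionSeries(frames, angles), truth
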