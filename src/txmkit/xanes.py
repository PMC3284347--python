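"""Per-pixel XANES spectro-imaging analysis.

Operates on an aligned, reference-corrected optical-density stack (one XANES
spectrum per pixel). Processing steps, each available standalone and chained
by :func:`analyze`:

1. edge-jump map and noise filtering (pre-edge sigma threshold),
2. pre/post-edge linear-regression normalization with slope filtering,
3. half-height edge-energy map and edge-energy histogram clustering,
4. non-negative least-squares linear-combination fitting against normalized
   reference spectra, graded per pixel by the R-factor
   ``R = sum (data - fit)^2 / sum data^2`` over the fit window,
5. RGB phase maps weighted by the normalized edge jump.

Filtered pixels are set to zero at all energies in the normalized stack and
excluded (zero weights, NaN maps) downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize
from matplotlib.path import Path as MplPath

from txmkit.io import EnergyStack


@dataclass(frozen=True)
class EdgeConfig:
    """User-defined pre/post-edge windows, edge energy, and filter settings."""

    pre_lo: float
    pre_hi: float
    post_lo: float
    post_hi: float
    e0: float
    k: float = 3.0
    slope_min: float = 0.0
    slope_pre_max: float = 0.01  # OD per eV
    slope_post_max: float = 0.02
    half_level: float = 0.5

    def __post_init__(self) -> None:
        if not self.pre_lo < self.pre_hi < self.e0 < self.post_lo < self.post_hi:
            raise ValueError("require pre_lo < pre_hi < e0 < post_lo < post_hi")
        if self.k <= 0:
            raise ValueError("k must be positive")

    def pre_idx(self, energies: np.ndarray) -> np.ndarray:
        return _window(energies, self.pre_lo, self.pre_hi, "pre-edge")

    def post_idx(self, energies: np.ndarray) -> np.ndarray:
        return _window(energies, self.post_lo, self.post_hi, "post-edge")


def _window(energies: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    idx = np.where((energies >= lo) & (energies <= hi))[0]
    if idx.size < 2:
        raise ValueError(f"{name} window [{lo}, {hi}] contains < 2 energy points")
    return idx


@dataclass
class ReferenceSet:
    """Normalized reference XANES resampled onto the stack's energy grid."""

    names: list[str]
    spectra: np.ndarray  # (n_refs, n_energies)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[0] != len(self.names):
            raise ValueError("spectra must be (n_refs, n_energies)")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("reference spectra must be finite")

    @property
    def n_refs(self) -> int:
        return self.spectra.shape[0]

    @classmethod
    def from_files(
        cls, paths: list[str | Path], energies_eV: np.ndarray
    ) -> "ReferenceSet":
        """Load two-column (energy_eV, normalized_mu) text files and resample
        linearly onto the stack grid; extrapolation is refused."""
        energies = np.asarray(energies_eV, dtype=float)
        names, rows = [], []
        for p in paths:
            p = Path(p)
            table = np.loadtxt(str(p), delimiter=None)
            if table.ndim != 2 or table.shape[1] < 2:
                raise ValueError(f"{p}: expected two-column (energy, mu) text")
            e, mu = table[:, 0], table[:, 1]
            if energies[0] < e.min() or energies[-1] > e.max():
                raise ValueError(
                    f"{p}: stack grid [{energies[0]}, {energies[-1]}] outside "
                    f"reference range [{e.min()}, {e.max()}]"
                )
            rows.append(np.interp(energies, e, mu))
            names.append(p.stem)
        return cls(names, np.stack(rows))


@dataclass
class XanesResult:
    """Bundle of all maps produced by the XANES pipeline."""

    edge_jump: np.ndarray
    noise_mask: np.ndarray
    norm_mask: np.ndarray
    combined_mask: np.ndarray
    normalized: EnergyStack
    edge_energy: np.ndarray
    weights: np.ndarray | None = None  # (n_refs, H, W)
    rfactor: np.ndarray | None = None
    rgb: np.ndarray | None = None


# ---------------------------------------------------------------------------
# filtering and normalization


def edge_jump_map(stack: EnergyStack, cfg: EdgeConfig) -> np.ndarray:
    """Post-edge window mean minus pre-edge window mean, per pixel."""
    pre = cfg.pre_idx(stack.energies_eV)
    post = cfg.post_idx(stack.energies_eV)
    return stack.data[post].mean(axis=0) - stack.data[pre].mean(axis=0)


def noise_filter(
    stack: EnergyStack, cfg: EdgeConfig, edge_jump: np.ndarray | None = None
) -> np.ndarray:
    """Keep pixels whose edge jump exceeds k times their pre-edge noise.

    The per-pixel threshold is the sample standard deviation of the pre-edge
    OD (the XANES noise level) multiplied by the user factor ``k``.
    """
    if edge_jump is None:
        edge_jump = edge_jump_map(stack, cfg)
    pre = cfg.pre_idx(stack.energies_eV)
    sigma_pre = stack.data[pre].std(axis=0, ddof=1)
    return edge_jump >= cfg.k * sigma_pre


def _ols_lines(
    data: np.ndarray, energies: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel OLS fit over the window; returns (slope, intercept) maps."""
    e = energies[idx]
    y = data[idx]  # (n_win, H, W)
    e_mean = e.mean()
    y_mean = y.mean(axis=0)
    de = e - e_mean
    slope = np.tensordot(de, y, axes=([0], [0])) / (de @ de)
    intercept = y_mean - slope * e_mean
    return slope, intercept


def normalize_stack(
    stack: EnergyStack, cfg: EdgeConfig, mask: np.ndarray | None = None
) -> tuple[EnergyStack, np.ndarray]:
    """Normalize each pixel's XANES to 0 (pre-edge) / 1 (post-edge).

    Fits a line to the pre-edge and the post-edge window per pixel and maps
    ``mu_n(E) = (mu(E) - L_pre(E)) / (L_post(E) - L_pre(E))``. Pixels whose
    pre/post slope magnitude falls outside the allowed band, or whose edge
    step at E0 is non-positive, fail the normalization filter and are zeroed
    at all energies. Returns ``(normalized stack, norm_mask)``; norm_mask is
    the normalization-filter verdict for every pixel, while zeroing applies to
    pixels failing either it or the supplied ``mask`` (e.g. the noise filter).
    """
    energies = stack.energies_eV
    pre = cfg.pre_idx(energies)
    post = cfg.post_idx(energies)
    s_pre, b_pre = _ols_lines(stack.data, energies, pre)
    s_post, b_post = _ols_lines(stack.data, energies, post)

    step_e0 = (s_post * cfg.e0 + b_post) - (s_pre * cfg.e0 + b_pre)
    ok_pre = (np.abs(s_pre) >= cfg.slope_min) & (np.abs(s_pre) <= cfg.slope_pre_max)
    ok_post = (np.abs(s_post) >= cfg.slope_min) & (
        np.abs(s_post) <= cfg.slope_post_max
    )
    norm_mask = ok_pre & ok_post & (step_e0 > 0)
    keep = norm_mask if mask is None else (norm_mask & mask)

    e_col = energies[:, None, None]
    l_pre = s_pre[None] * e_col + b_pre[None]
    l_post = s_post[None] * e_col + b_post[None]
    denom = l_post - l_pre
    safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
    normalized = (stack.data - l_pre) / safe
    normalized[:, ~keep] = 0.0
    out = EnergyStack(
        normalized,
        energies,
        corrected=stack.corrected,
        pixel_size_nm=stack.pixel_size_nm,
    )
    return out, norm_mask


# ---------------------------------------------------------------------------
# edge energy


def edge_energy_map(
    normalized: EnergyStack, cfg: EdgeConfig, mask: np.ndarray | None = None
) -> np.ndarray:
    """Half-height edge position per pixel (eV); NaN where undefined.

    Scanning energies in increasing order strictly between the pre- and
    post-edge windows, the first bracket with ``mu_n(E_i) < 0.5 <= mu_n(E_i+1)``
    is interpolated linearly.
    """
    energies = normalized.energies_eV
    sel = np.where((energies > cfg.pre_hi) & (energies < cfg.post_lo))[0]
    if sel.size < 2:
        raise ValueError("no energy points between pre and post windows")
    y = normalized.data[sel]
    e = energies[sel]
    lvl = cfg.half_level
    below = y[:-1] < lvl
    above = y[1:] >= lvl
    crossing = below & above
    has = crossing.any(axis=0)
    first = crossing.argmax(axis=0)
    H, W = has.shape
    flat = first.ravel()
    cols = np.arange(H * W)
    y0 = y.reshape(y.shape[0], -1)[flat, cols]
    y1 = y.reshape(y.shape[0], -1)[flat + 1, cols]
    denom = np.where(y1 > y0, y1 - y0, 1.0)
    frac = (lvl - y0) / denom
    e_half = e[flat] + frac * (e[flat + 1] - e[flat])
    out = np.where(has.ravel(), e_half, np.nan).reshape(H, W)
    if mask is not None:
        out[~mask] = np.nan
    return out


@dataclass
class EdgeHistogram:
    counts: np.ndarray
    bin_centers: np.ndarray  # aligned to the scan's energy grid
    bin_of: np.ndarray  # 2D int map, -1 where edge energy is NaN


def edge_energy_histogram(
    edge_energy: np.ndarray, energies_eV: np.ndarray
) -> EdgeHistogram:
    """Histogram of edge energies with bins aligned to the scan grid.

    Bin width equals the energy step (experimental precision): each scan
    energy is a bin center, edges sit midway between grid points. NaN pixels
    are excluded (bin index -1).
    """
    energies = np.asarray(energies_eV, dtype=float)
    edges = np.concatenate(
        (
            [energies[0] - (energies[1] - energies[0]) / 2],
            (energies[1:] + energies[:-1]) / 2,
            [energies[-1] + (energies[-1] - energies[-2]) / 2],
        )
    )
    valid = np.isfinite(edge_energy)
    bin_of = np.full(edge_energy.shape, -1, dtype=int)
    if valid.any():
        b = np.digitize(edge_energy[valid], edges) - 1
        b = np.clip(b, 0, energies.size - 1)
        bin_of[valid] = b
    counts = np.bincount(bin_of[bin_of >= 0], minlength=energies.size)
    return EdgeHistogram(counts=counts, bin_centers=energies, bin_of=bin_of)


def cluster_by_edge_energy(
    normalized: EnergyStack,
    hist: EdgeHistogram,
    selections: list[list[int] | int],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pool pixels by selected histogram bins.

    Each entry of ``selections`` (one bin index or a list of them) becomes one
    cluster. Returns a label map (0 = unlabeled, cluster c = index + 1) and
    the mean normalized XANES of each cluster's member pixels.
    """
    labels = np.zeros(hist.bin_of.shape, dtype=int)
    mean_spectra: list[np.ndarray] = []
    for c, sel in enumerate(selections, start=1):
        bins = [sel] if np.isscalar(sel) else list(sel)
        member = np.isin(hist.bin_of, bins) & (hist.bin_of >= 0)
        labels[member] = c
        if not member.any():
            warnings.warn(f"cluster {c}: selected bins {bins} are empty")
            mean_spectra.append(np.full(normalized.n_energies, np.nan))
        else:
            mean_spectra.append(normalized.data[:, member].mean(axis=1))
    return labels, mean_spectra


# ---------------------------------------------------------------------------
# linear-combination fitting


def lc_fit(
    normalized: EnergyStack,
    refs: ReferenceSet,
    cfg: EdgeConfig,
    mask: np.ndarray | None = None,
    nonneg: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit each pixel's normalized XANES as a combination of references.

    The fit is restricted to energies within ``[pre_hi, post_hi]``. With
    ``nonneg`` (default) weights are solved by non-negative least squares;
    otherwise by ordinary least squares. Returns ``(weights, rfactor)`` where
    weights is (n_refs, H, W) and the R-factor is
    ``sum (data - fit)^2 / sum data^2`` over the fit window (NaN for masked
    pixels, whose weights are zero).
    """
    if refs.n_refs < 2:
        raise ValueError("LC fitting requires at least 2 references")
    energies = normalized.energies_eV
    sel = np.where((energies >= cfg.pre_hi) & (energies <= cfg.post_hi))[0]
    A = refs.spectra[:, sel].T  # (n_E_fit, n_refs)
    if np.linalg.matrix_rank(A, tol=1e-8) < refs.n_refs:
        corr = np.corrcoef(refs.spectra[:, sel])
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"reference matrix is rank-deficient: "
            f"{refs.names[i]!r} and {refs.names[j]!r} are collinear"
        )

    H, W = normalized.frame_shape
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    weights = np.zeros((refs.n_refs, H, W))
    rfactor = np.full((H, W), np.nan)
    Y = normalized.data[sel].reshape(sel.size, -1)
    flat_mask = mask.ravel()
    w_flat = weights.reshape(refs.n_refs, -1)
    r_flat = rfactor.ravel()
    for p in np.where(flat_mask)[0]:
        y = Y[:, p]
        if nonneg:
            w, _ = scipy.optimize.nnls(A, y)
        else:
            w, *_ = np.linalg.lstsq(A, y, rcond=None)
        w_flat[:, p] = w
        resid = y - A @ w
        denom = y @ y
        r_flat[p] = (resid @ resid) / denom if denom > 0 else np.nan
    return weights, rfactor


def rfactor_of(data: np.ndarray, fit: np.ndarray) -> float:
    """R = sum (data - fit)^2 / sum data^2 for a single spectrum."""
    data = np.asarray(data, dtype=float)
    fit = np.asarray(fit, dtype=float)
    return float(((data - fit) ** 2).sum() / (data**2).sum())


def jump_vs_rfactor_cluster(
    edge_jump: np.ndarray,
    rfactor: np.ndarray,
    polygons: list[np.ndarray],
) -> np.ndarray:
    """Cluster pixels by polygon selections in (edge jump, R-factor) space.

    Each polygon (an (n_vertices, 2) array of (J, R) points) becomes one
    cluster; the returned label map holds 0 for unselected pixels and
    cluster index + 1 inside each polygon (earlier polygons win ties).
    Pixels with NaN R-factor are never selected.
    """
    labels = np.zeros(edge_jump.shape, dtype=int)
    valid = np.isfinite(rfactor)
    pts = np.stack([edge_jump[valid], rfactor[valid]], axis=1)
    assigned = np.zeros(pts.shape[0], dtype=bool)
    flat_idx = np.where(valid.ravel())[0]
    for c, poly in enumerate(polygons, start=1):
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3:
            warnings.warn(f"cluster {c}: polygon needs >= 3 vertices, skipped")
            continue
        inside = MplPath(poly).contains_points(pts) & ~assigned
        labels.ravel()[flat_idx[inside]] = c
        assigned |= inside
    return labels


# ---------------------------------------------------------------------------
# RGB phase maps and bulk spectra


def rgb_phase_map(
    weights: np.ndarray,
    edge_jump: np.ndarray,
    channel_assignment: dict[str, list[int]],
    mask: np.ndarray | None = None,
    clip_percentile: float = 99.0,
) -> np.ndarray:
    """Compose an H x W x 3 phase map from LC weights.

    ``channel_assignment`` maps 'r'/'g'/'b' to reference indices; surplus
    references are summed into their assigned channel. Channel fractions are
    the assigned weight sums normalized by the total weight, and the pixel
    intensity is scaled by the edge jump clipped at ``clip_percentile`` and
    mapped to [0, 1] (the transparency weighting). Masked pixels are black.
    """
    n_refs = weights.shape[0]
    covered = sorted(i for idxs in channel_assignment.values() for i in idxs)
    if covered != list(range(n_refs)):
        raise ValueError(
            f"channel assignment {channel_assignment} does not cover all "
            f"{n_refs} references exactly once"
        )
    H, W = weights.shape[1:]
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    total = weights.sum(axis=0)
    safe_total = np.where(total > 0, total, 1.0)
    rgb = np.zeros((H, W, 3))
    for ch, name in enumerate("rgb"):
        idxs = channel_assignment.get(name, [])
        if idxs:
            rgb[..., ch] = weights[idxs].sum(axis=0) / safe_total

    jump_vals = edge_jump[mask & (total > 0)]
    scale = (
        np.percentile(jump_vals, clip_percentile) if jump_vals.size else 1.0
    )
    if scale <= 0:
        scale = 1.0
    amp = np.clip(edge_jump / scale, 0.0, 1.0)
    rgb *= amp[..., None]
    rgb[~mask | (total <= 0)] = 0.0
    return rgb


def bulk_xanes(stack: EnergyStack, mask: np.ndarray | None = None) -> np.ndarray:
    """Average XANES over the (unmasked) field of view — the bulk spectrum."""
    if mask is None:
        return stack.data.mean(axis=(1, 2))
    if not mask.any():
        raise ValueError("empty selection: all pixels masked")
    return stack.data[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# pipeline


def analyze(
    stack: EnergyStack,
    cfg: EdgeConfig,
    refs: ReferenceSet | None = None,
    channel_assignment: dict[str, list[int]] | None = None,
    nonneg: bool = True,
) -> XanesResult:
    """Run the full per-pixel XANES pipeline on an OD stack."""
    jump = edge_jump_map(stack, cfg)
    nmask = noise_filter(stack, cfg, edge_jump=jump)
    normalized, norm_mask = normalize_stack(stack, cfg, mask=nmask)
    combined = nmask & norm_mask
    e_half = edge_energy_map(normalized, cfg, mask=combined)
    result = XanesResult(
        edge_jump=jump,
        noise_mask=nmask,
        norm_mask=norm_mask,
        combined_mask=combined,
        normalized=normalized,
        edge_energy=e_half,
    )
    if refs is not None:
        result.weights, result.rfactor = lc_fit(
            normalized, refs, cfg, mask=combined, nonneg=nonneg
        )
        if channel_assignment is None:
            channel_assignment = default_channel_assignment(refs.n_refs)
        result.rgb = rgb_phase_map(
            result.weights, jump, channel_assignment, mask=combined
        )
    return result


def default_channel_assignment(n_refs: int) -> dict[str, list[int]]:
    """First two references to red/green, everything else summed into blue."""
    if n_refs < 2:
        raise ValueError("need >= 2 references")
    if n_refs == 2:
        return {"r": [0], "g": [1], "b": []}
    return {"r": [0], "g": [1], "b": list(range(2, n_refs))}
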