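"""Diffraction-limited spot detection.

Each frame is decomposed with the undecimated ("a trous") B3-spline wavelet
transform; diffraction-limited spots light up a characteristic scale plane,
which is hard-thresholded at a multiple of a robust (MAD-based) noise
estimate. Candidate maxima are refined by least-squares 2D Gaussian fits to
sub-pixel positions with amplitude, background, and width.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, spatial

from .io import MovieStack

__all__ = [
    "SpotRecord",
    "AtrousDecomposition",
    "atrous_filter",
    "find_candidates",
    "fit_gaussian",
    "detect_frame",
    "detect_movie",
    "flag_isolation",
    "spot_density",
    "spots_to_dataframe",
]

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class SpotRecord:
    """One fitted spot: sub-pixel location, intensity, and fit diagnostics."""

    frame: int
    row: float
    col: float
    amplitude: float
    background: float
    sigma: float
    fit_rss: float
    converged: bool
    isolated: bool = True


@dataclass
class AtrousDecomposition:
    planes: list[np.ndarray]       # detail planes w_1..w_J (fine -> coarse)
    smooth: np.ndarray             # residual smooth c_J
    mask: np.ndarray               # significant support at the detection plane
    detect_level: int
    threshold: float

    def reconstruct(self) -> np.ndarray:
        return sum(self.planes) + self.smooth

    @property
    def bandpass(self) -> np.ndarray:
        """Sum of detail planes up to the detection level.

        Sharper than the detection plane alone, so close pairs keep distinct
        maxima; significance is still judged on the detection plane."""
        return sum(self.planes[: self.detect_level])


def _dilated_smooth(image: np.ndarray, level: int) -> np.ndarray:
    """Separable B3-spline smoothing with 2**level - 1 zeros between taps."""
    step = 2**level
    kernel = np.zeros(4 * step + 1)
    kernel[::step] = _B3
    out = ndimage.convolve1d(image, kernel, axis=0, mode="mirror")
    return ndimage.convolve1d(out, kernel, axis=1, mode="mirror")


def _mad_sigma(plane: np.ndarray) -> float:
    med = np.median(plane)
    return 1.4826 * float(np.median(np.abs(plane - med)))


def atrous_filter(image: np.ndarray, n_levels: int = 3, k_sigma: float = 3.0,
                  detect_level: int = 2) -> AtrousDecomposition:
    """B3-spline a trous decomposition with hard thresholding.

    The detection mask is the support where the ``detect_level`` detail plane
    exceeds ``k_sigma`` times its MAD-based noise scale. A constant image
    yields an empty mask. The planes plus the final smooth reconstruct the
    input exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 8:
        raise ValueError("image must be 2D and at least 8x8")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if not (1 <= detect_level <= n_levels):
        raise ValueError("detect_level must be in 1..n_levels")
    planes = []
    c = image
    for j in range(n_levels):
        c_next = _dilated_smooth(c, j)
        planes.append(c - c_next)
        c = c_next
    w = planes[detect_level - 1]
    threshold = k_sigma * _mad_sigma(w)
    # strict > makes a constant image yield an empty mask even at threshold 0
    mask = w > threshold
    return AtrousDecomposition(planes, c, mask, detect_level, threshold)


def find_candidates(decomp: AtrousDecomposition, min_separation: float = 2.0) -> np.ndarray:
    """Local maxima of the detection plane within the mask, pruned greedily.

    No two candidates end up closer than ``min_separation`` px; the brighter
    one wins, ties broken in row-major order. Returns an (k, 2) int array of
    (row, col) pixel coordinates.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    plane = decomp.bandpass
    local_max = plane == ndimage.maximum_filter(plane, size=3, mode="nearest")
    cand = np.argwhere(local_max & decomp.mask)
    if len(cand) == 0:
        return cand.reshape(0, 2)
    values = plane[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -values))
    cand = cand[order]
    tree = spatial.cKDTree(cand.astype(float))
    neighbors = tree.query_ball_point(cand.astype(float), min_separation - 1e-9)
    keep = np.zeros(len(cand), dtype=bool)
    for idx, nbrs in enumerate(neighbors):
        # neighbors earlier in priority order suppress this candidate
        if not any(j != idx and keep[j] for j in nbrs):
            keep[idx] = True
    return cand[keep]


def _gauss_model(params, rr, cc):
    amp, r0, c0, sigma, bg = params
    return amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)) + bg


def fit_gaussian(image: np.ndarray, candidate, half_window: int = 4,
                 frame: int = 0, expected_sigma: float = 1.3,
                 sigma_bounds: tuple[float, float] = (0.5, 3.0)) -> SpotRecord:
    """Least-squares 2D Gaussian fit around one candidate pixel.

    The fitted model is ``amp * exp(-((r-r0)^2+(c-c0)^2)/(2 sigma^2)) + bg``
    over a (2*half_window+1)^2 window. Windows that cross the image edge, or
    fits that fail to converge, return a record with ``converged=False``
    (retained for diagnostics, never silently dropped).
    """
    image = np.asarray(image, dtype=np.float64)
    r, c = int(candidate[0]), int(candidate[1])
    lo_r, hi_r = r - half_window, r + half_window + 1
    lo_c, hi_c = c - half_window, c + half_window + 1
    if lo_r < 0 or lo_c < 0 or hi_r > image.shape[0] or hi_c > image.shape[1]:
        return SpotRecord(frame, float(r), float(c), 0.0, 0.0, expected_sigma,
                          float("nan"), converged=False)
    window = image[lo_r:hi_r, lo_c:hi_c]
    rr, cc = np.meshgrid(np.arange(lo_r, hi_r, dtype=float),
                         np.arange(lo_c, hi_c, dtype=float), indexing="ij")
    bg0 = float(np.median(window))
    amp0 = max(float(image[r, c] - bg0), 1e-6)
    p0 = np.array([amp0, float(r), float(c), expected_sigma, bg0])
    lower = [0.0, lo_r, lo_c, sigma_bounds[0], -np.inf]
    upper = [np.inf, hi_r - 1, hi_c - 1, sigma_bounds[1], np.inf]
    def jac(p):
        amp, r0, c0, sigma, _bg = p
        e = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
        d_amp = e
        d_r0 = amp * e * (rr - r0) / sigma**2
        d_c0 = amp * e * (cc - c0) / sigma**2
        d_sigma = amp * e * ((rr - r0) ** 2 + (cc - c0) ** 2) / sigma**3
        d_bg = np.ones_like(e)
        return np.column_stack([d.ravel() for d in (d_amp, d_r0, d_c0, d_sigma, d_bg)])

    try:
        res = optimize.least_squares(
            lambda p: (_gauss_model(p, rr, cc) - window).ravel(),
            p0, jac=jac, bounds=(lower, upper), method="trf", xtol=1e-10, ftol=1e-10,
        )
    except Exception:
        return SpotRecord(frame, float(r), float(c), 0.0, bg0, expected_sigma,
                          float("nan"), converged=False)
    amp, r0, c0, sigma, bg = res.x
    rss = float(np.sum(res.fun**2))
    interior = lo_r < r0 < hi_r - 1 and lo_c < c0 < hi_c - 1
    converged = bool(res.success and amp > 0 and interior)
    return SpotRecord(frame, float(r0), float(c0), float(amp), float(bg),
                      float(sigma), rss, converged)


def detect_frame(image: np.ndarray, n_levels: int = 3, k_sigma: float = 3.0,
                 detect_level: int = 2, min_separation: float = 2.0,
                 fit: bool = True, frame: int = 0, half_window: int = 4,
                 expected_sigma: float = 1.3) -> list[SpotRecord]:
    """Detect spots in one frame; optionally refine each by a Gaussian fit.

    With ``fit=False`` the sub-pixel position comes from an intensity-weighted
    centroid of the detection plane (adequate for frame-to-frame linking of
    stationary particles and much cheaper than fitting every frame).
    """
    decomp = atrous_filter(image, n_levels, k_sigma, detect_level)
    candidates = find_candidates(decomp, min_separation)
    records: list[SpotRecord] = []
    if fit:
        for cand in candidates:
            records.append(fit_gaussian(image, cand, half_window, frame, expected_sigma))
        return _dedupe_fits(records, min_separation)
    plane = decomp.bandpass
    if len(candidates) == 0:
        return records
    # batched 3x3 intensity-weighted centroid on the detection plane; the
    # tight window keeps close-pair positions free of neighbor attraction
    pad = 1
    padded = np.pad(np.clip(plane, 0, None), pad, mode="constant")
    off = np.arange(-pad, pad + 1)
    rr = candidates[:, 0][:, None, None] + off[None, :, None] + pad
    cc = candidates[:, 1][:, None, None] + off[None, None, :] + pad
    w = padded[rr, cc]
    tot = w.sum(axis=(1, 2))
    tot[tot <= 0] = np.inf
    dr = (w * off[None, :, None]).sum(axis=(1, 2)) / tot
    dc = (w * off[None, None, :]).sum(axis=(1, 2)) / tot
    r0s = candidates[:, 0] + dr
    c0s = candidates[:, 1] + dc
    amps = plane[candidates[:, 0], candidates[:, 1]]
    for k in range(len(candidates)):
        records.append(SpotRecord(frame, float(r0s[k]), float(c0s[k]), float(amps[k]),
                                  0.0, expected_sigma, float("nan"), converged=True))
    return records


def _dedupe_fits(records: list[SpotRecord], min_separation: float) -> list[SpotRecord]:
    """Collapse converged fits that slid onto the same center.

    Distinct candidate pixels can converge to one spot; keep the brightest
    fit per cluster (non-converged records pass through untouched)."""
    conv = [s for s in records if s.converged]
    rest = [s for s in records if not s.converged]
    if len(conv) < 2:
        return records
    conv.sort(key=lambda s: -s.amplitude)
    kept: list[SpotRecord] = []
    for s in conv:
        if all(np.hypot(s.row - k.row, s.col - k.col) >= min_separation for k in kept):
            kept.append(s)
    return kept + rest


def flag_isolation(records: list[SpotRecord], psf_sigma: float = 1.3,
                   factor: float = 3.0) -> list[SpotRecord]:
    """Mark spots whose centers lie within ``factor * psf_sigma`` of another.

    Crowded spots are flagged (``isolated=False``) rather than removed, so
    detection statistics stay honest; trace-level QC rejects them later.
    """
    pts = np.array([[s.row, s.col] for s in records]) if records else np.empty((0, 2))
    if len(pts) >= 2:
        tree = spatial.cKDTree(pts)
        pairs = tree.query_pairs(factor * psf_sigma)
        crowded = {i for pair in pairs for i in pair}
    else:
        crowded = set()
    for i, s in enumerate(records):
        s.isolated = i not in crowded
    return records


def detect_movie(movie: MovieStack, fit_frames=(0,), **kwargs) -> pd.DataFrame:
    """Run detection over every frame of a movie.

    Gaussian fits are performed only on ``fit_frames`` (default: the first
    frame, which carries the full complement of unbleached spots and is what
    density estimation uses); other frames use centroid refinement.
    """
    fit_frames = set(fit_frames)
    all_records: list[SpotRecord] = []
    for f in range(movie.n_frames):
        recs = detect_frame(movie.data[f], fit=f in fit_frames, frame=f, **kwargs)
        recs = flag_isolation(recs, kwargs.get("expected_sigma", 1.3))
        all_records.extend(recs)
    return spots_to_dataframe(all_records)


def spots_to_dataframe(records: list[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": s.frame, "row": s.row, "col": s.col,
                "amplitude": s.amplitude, "background": s.background,
                "sigma": s.sigma, "fit_rss": s.fit_rss,
                "converged": s.converged, "isolated": s.isolated,
            }
            for s in records
        ],
        columns=["frame", "row", "col", "amplitude", "background", "sigma",
                 "fit_rss", "converged", "isolated"],
    )


def spot_density(records, fov_area: float) -> float:
    """Converged-spot count per um^2 of field of view.

    ``records`` may be a list of SpotRecord or a spot DataFrame; only
    converged records count.
    """
    if fov_area <= 0:
        raise ValueError("fov_area must be positive")
    if isinstance(records, pd.DataFrame):
        n = int(records["converged"].sum())
    else:
        n = sum(1 for s in records if s.converged)
    return n / fov_area
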