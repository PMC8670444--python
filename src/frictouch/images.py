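"""Contact-image processing for fingertip pressing trials.

A trial is a synchronized sequence of dual-illumination image pairs:
a grazing-light *ridge* channel showing the fingerprint topography
(used for feature tracking) and a coaxial-light *contact* channel in
which only the skin asperities in intimate contact with the plate are
bright (used to measure the real contact area and to time-stamp each
tracked point's contact onset).

The pipeline stages are:

1. :func:`correct_illumination` — remove large-scale shading;
2. :func:`otsu_threshold` / :func:`real_contact_area` — real contact
   area by between-class-variance thresholding, in mm^2;
3. :func:`track_features` — corner detection plus pyramidal
   Lucas-Kanade tracking of the most salient ridge features, each
   point's displacement referenced to its own contact-onset frame;
4. :func:`local_brightness` and
   :func:`displacement_brightness_correlation` — local real-contact
   density around tracked points and its rank correlation with the
   displacement magnitude;
5. :func:`filter_force` — zero-lag second-order low-pass conditioning
   of the force trace.

Intensity convention: contact is *bright* in the contact channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage, signal
from scipy.stats import spearmanr
from skimage.feature import corner_peaks, corner_shi_tomasi

from .errors import (
    DataError,
    DegenerateHistogramError,
    FeaturePoorInputError,
    ParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "ContactFrame",
    "TrialRecord",
    "TrackedPoints",
    "correct_illumination",
    "otsu_threshold",
    "real_contact_area",
    "local_brightness",
    "track_features",
    "filter_force",
    "displacement_brightness_correlation",
]

#: Maximum number of tracked fingerprint features.
MAX_TRACKED_FEATURES = 700
#: Radius of the local-brightness disk around a tracked point, px.
LOCAL_BRIGHTNESS_RADIUS_PX = 10
#: A point is "in contact" once its local brightness first exceeds this
#: fraction of its own maximum over the trial.
ONSET_BRIGHTNESS_FRACTION = 0.5
#: Tracking stops once the normal force reaches this level, N.
TRACKING_STOP_FORCE_N = 3.0


@dataclass
class ContactFrame:
    """One synchronized ridge/contact image pair with its force sample."""

    ridge_image: np.ndarray
    contact_image: np.ndarray
    timestamp: float
    normal_force: float
    pixel_resolution: float  # mm/pixel

    def __post_init__(self) -> None:
        self.ridge_image = np.asarray(self.ridge_image)
        self.contact_image = np.asarray(self.contact_image)
        if self.ridge_image.shape != self.contact_image.shape:
            raise ParameterError(
                "ridge and contact images must share a shape, got "
                f"{self.ridge_image.shape} vs {self.contact_image.shape}"
            )
        if self.ridge_image.ndim != 2 or self.ridge_image.size == 0:
            raise ParameterError("images must be nonempty 2-d grayscale arrays")
        if not self.pixel_resolution > 0:
            raise ParameterError("pixel_resolution must be positive")


@dataclass
class TrackedPoints:
    """Trajectories of tracked ridge features over a trial.

    ``positions[t, i]`` is the (x, y) pixel position of feature ``i``
    in frame ``t``; ``onset_index[i]`` the frame at which the feature
    was first detected in intimate contact; ``displacement_mm[i]`` its
    displacement between the final tracked frame and its onset frame,
    in mm.  Features whose track was lost are dropped; ``n_lost``
    records how many.
    """

    positions: np.ndarray  # (n_frames, n_points, 2) pixels, (x, y)
    onset_index: np.ndarray  # (n_points,)
    displacement_mm: np.ndarray  # (n_points, 2)
    brightness: np.ndarray  # (n_frames, n_points) contact-channel local mean
    final_index: int
    n_lost: int


@dataclass
class TrialRecord:
    """One press trial: frames, condition, and (optionally) tracks."""

    frames: list
    alpha_um: float = 0.0  # ultrasonic vibration amplitude, um
    mu: float | None = None  # nominal friction coefficient
    tracked_points: TrackedPoints | None = None
    excluded: bool = False
    exclusion_reason: str = ""
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        t = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ParameterError("frame timestamps must be strictly increasing")

    @property
    def pixel_resolution(self) -> float:
        return self.frames[0].pixel_resolution

    @property
    def force(self) -> np.ndarray:
        return np.array([f.normal_force for f in self.frames])

    @property
    def times(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])


# ---------------------------------------------------------------------------
# intensity processing
# ---------------------------------------------------------------------------


def correct_illumination(image: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Remove the large-scale illumination gradient from an image.

    A heavily smoothed copy (Gaussian, ``sigma`` defaulting to a
    quarter of the smaller image dimension) estimates the shading; it
    is subtracted and the global mean added back, then the result is
    clipped to the input's valid range.  A flat image is returned
    unchanged.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ParameterError("expected a nonempty 2-d grayscale image")
    if sigma is None:
        sigma = min(img.shape) / 4.0
    background = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest",
                                         truncate=2.0)
    corrected = img - background + img.mean()
    lo, hi = float(img.min()), float(img.max())
    return np.clip(corrected, lo, hi)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximise the between-class intensity variance.

    Deterministic exhaustive search over histogram bin edges; raises
    :class:`DegenerateHistogramError` for a constant image, where no
    threshold separates anything.
    """
    img = np.asarray(image)
    flat = img.ravel().astype(float)
    if flat.size == 0:
        raise ParameterError("empty image")
    if np.ptp(flat) == 0:
        raise DegenerateHistogramError(
            "image has a single intensity; Otsu threshold undefined"
        )
    counts, edges = np.histogram(flat, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    cand = between[:-1]  # last edge would leave class 1 empty
    best = cand.max()
    # histograms with an empty gap between modes have a plateau of
    # equivalent maximisers; take the middle one (canonical tie-break)
    ties = np.flatnonzero(cand >= best - 1e-12 * abs(best))
    k = int(ties[ties.size // 2])
    return float(edges[k + 1])


def real_contact_area(
    contact_image: np.ndarray,
    pixel_resolution: float,
    threshold: float | None = None,
) -> float:
    """Real contact area: bright pixels scaled by pixel resolution, mm^2.

    The contact-channel image is thresholded (Otsu by default) and the
    above-threshold pixel count is multiplied by the pixel area.
    """
    if not pixel_resolution > 0:
        raise ParameterError("pixel_resolution must be positive")
    img = np.asarray(contact_image, dtype=float)
    if threshold is None:
        threshold = otsu_threshold(img)
    return float(np.count_nonzero(img > threshold)) * pixel_resolution**2


def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(r, r)
    keep = dx**2 + dy**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep]])  # (m, 2) as (x, y)


def local_brightness(
    contact_image: np.ndarray,
    point: tuple[float, float],
    radius_px: int = LOCAL_BRIGHTNESS_RADIUS_PX,
) -> float:
    """Mean intensity over the discrete disk around ``point`` (x, y).

    Measures the local density of asperities in intimate contact.  The
    point must lie at least ``radius_px`` inside the image bounds.
    """
    img = np.asarray(contact_image, dtype=float)
    x, y = point
    h, w = img.shape
    if not (radius_px <= x <= w - 1 - radius_px and radius_px <= y <= h - 1 - radius_px):
        raise ParameterError(
            f"point {point} closer than {radius_px} px to the image border"
        )
    off = _disk_offsets(radius_px)
    cols = np.clip(np.round(x + off[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(y + off[:, 1]).astype(int), 0, h - 1)
    return float(img[rows, cols].mean())


def _local_brightness_many(
    img: np.ndarray, pts: np.ndarray, radius_px: int
) -> np.ndarray:
    """Vectorised local-brightness for an (n, 2) array of (x, y) points."""
    off = _disk_offsets(radius_px)
    h, w = img.shape
    cols = np.clip(np.round(pts[:, None, 0] + off[None, :, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(pts[:, None, 1] + off[None, :, 1]).astype(int), 0, h - 1)
    return np.asarray(img, dtype=float)[rows, cols].mean(axis=1)


# ---------------------------------------------------------------------------
# feature tracking
# ---------------------------------------------------------------------------


def detect_features(
    image: np.ndarray,
    max_features: int = MAX_TRACKED_FEATURES,
    min_distance: int = 5,
    border_margin: int = 12,
) -> np.ndarray:
    """The most salient corner features of a fingerprint image.

    Minimum-eigenvalue (Shi-Tomasi) corner strength with non-maximum
    suppression; returns up to ``max_features`` (x, y) positions sorted
    by decreasing corner response, excluding a border margin.
    """
    img = np.asarray(image, dtype=float)
    response = corner_shi_tomasi(img)
    peaks = corner_peaks(
        response,
        min_distance=min_distance,
        threshold_rel=0.01,
        num_peaks=4 * max_features,
    )
    if peaks.size == 0:
        raise FeaturePoorInputError("no trackable features detected")
    h, w = img.shape
    keep = (
        (peaks[:, 0] >= border_margin)
        & (peaks[:, 0] < h - border_margin)
        & (peaks[:, 1] >= border_margin)
        & (peaks[:, 1] < w - border_margin)
    )
    peaks = peaks[keep]
    if peaks.shape[0] == 0:
        raise FeaturePoorInputError("all detected features sit on the border")
    strengths = response[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(strengths)[::-1][:max_features]
    sel = peaks[order]
    return np.column_stack([sel[:, 1], sel[:, 0]]).astype(float)  # (x, y)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(pyr[-1], 1.0, mode="nearest")
        pyr.append(smoothed[::2, ::2])
    return pyr


def _lk_refine(
    prev: np.ndarray,
    curr: np.ndarray,
    pts: np.ndarray,
    guess: np.ndarray,
    window: int,
    iters: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One-level Lucas-Kanade refinement, vectorised over points.

    Solves, per point, the 2x2 normal equations of the window-summed
    optical-flow residual, iterating a few times with bilinear patch
    sampling.  Returns updated displacements and a validity flag.
    """
    h, w = prev.shape
    r = np.arange(-window, window + 1)
    ox, oy = np.meshgrid(r, r)
    off = np.stack([ox.ravel(), oy.ravel()])  # (2, m)
    gy, gx = np.gradient(prev)
    px = pts[:, 0][:, None] + off[0][None, :]
    py = pts[:, 1][:, None] + off[1][None, :]
    coords = np.stack([py.ravel(), px.ravel()])
    T = ndimage.map_coordinates(prev, coords, order=1, mode="nearest").reshape(px.shape)
    Ix = ndimage.map_coordinates(gx, coords, order=1, mode="nearest").reshape(px.shape)
    Iy = ndimage.map_coordinates(gy, coords, order=1, mode="nearest").reshape(px.shape)
    a = (Ix * Ix).sum(1)
    b = (Ix * Iy).sum(1)
    c = (Iy * Iy).sum(1)
    det = a * c - b * b
    ok = det > 1e-9 * (a + c + 1e-12) ** 2
    d = guess.copy()
    for _ in range(iters):
        qx = px + d[:, 0][:, None]
        qy = py + d[:, 1][:, None]
        coords = np.stack([qy.ravel(), qx.ravel()])
        I = ndimage.map_coordinates(curr, coords, order=1, mode="nearest").reshape(px.shape)
        e = T - I
        g1 = (Ix * e).sum(1)
        g2 = (Iy * e).sum(1)
        with np.errstate(divide="ignore", invalid="ignore"):
            du = np.where(ok, (c * g1 - b * g2) / det, 0.0)
            dv = np.where(ok, (a * g2 - b * g1) / det, 0.0)
        d = d + np.column_stack([du, dv])
    inside = (
        (pts[:, 0] + d[:, 0] >= window)
        & (pts[:, 0] + d[:, 0] < w - window)
        & (pts[:, 1] + d[:, 1] >= window)
        & (pts[:, 1] + d[:, 1] < h - window)
    )
    return d, ok & inside


def _lk_track(
    prev: np.ndarray,
    curr: np.ndarray,
    pts: np.ndarray,
    window: int = 10,
    levels: int = 3,
    iters: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Pyramidal Lucas-Kanade: displacement of each point prev->curr."""
    pyr_prev = _pyramid(prev, levels)
    pyr_curr = _pyramid(curr, levels)
    scale = 2 ** (levels - 1)
    d = np.zeros_like(pts)
    alive = np.ones(pts.shape[0], dtype=bool)
    for lvl in range(levels - 1, -1, -1):
        s = 2**lvl
        d_lvl, ok = _lk_refine(
            pyr_prev[lvl], pyr_curr[lvl], pts / s, d / s, window, iters
        )
        d = d_lvl * s
        alive &= ok
    return d, alive


def track_features(
    trial: TrialRecord,
    max_features: int = MAX_TRACKED_FEATURES,
    stop_force: float = TRACKING_STOP_FORCE_N,
    onset_fraction: float = ONSET_BRIGHTNESS_FRACTION,
    window: int = 10,
    levels: int = 3,
) -> TrackedPoints:
    """Track the most salient ridge features through a press trial.

    Corners are detected on the illumination-corrected first ridge
    frame and followed frame-to-frame with pyramidal Lucas-Kanade flow
    until the normal force first reaches ``stop_force`` (or its peak if
    it never does).  Each point's displacement is the difference
    between its position in the final tracked frame and its position in
    its *own* contact-onset frame — the first frame in which the local
    contact brightness exceeds ``onset_fraction`` of that point's
    maximum over the trial.  Points never detected in contact, or whose
    track is lost, are dropped.
    """
    if len(trial.frames) < 2:
        raise ParameterError("need at least 2 frames to track")
    force = trial.force
    reached = np.flatnonzero(force >= stop_force)
    final = int(reached[0]) if reached.size else int(np.argmax(force))
    final = max(final, 1)
    frames = trial.frames[: final + 1]
    ridge = [correct_illumination(f.ridge_image) for f in frames]
    pts0 = detect_features(ridge[0], max_features=max_features)
    n = pts0.shape[0]
    positions = np.full((len(frames), n, 2), np.nan)
    positions[0] = pts0
    alive = np.ones(n, dtype=bool)
    for t in range(1, len(frames)):
        d, ok = _lk_track(ridge[t - 1], ridge[t], positions[t - 1], window, levels)
        positions[t] = positions[t - 1] + d
        alive &= ok
    brightness = np.stack(
        [
            _local_brightness_many(
                frames[t].contact_image,
                np.nan_to_num(positions[t], nan=window),
                LOCAL_BRIGHTNESS_RADIUS_PX,
            )
            for t in range(len(frames))
        ]
    )
    peak = brightness.max(axis=0)
    in_contact_ever = peak > 0
    onset = np.zeros(n, dtype=int)
    for i in range(n):
        above = np.flatnonzero(brightness[:, i] >= onset_fraction * peak[i])
        onset[i] = int(above[0]) if above.size else 0
    keep = alive & in_contact_ever
    n_lost = int(n - keep.sum())
    res = trial.pixel_resolution
    disp = (
        positions[final, keep] - positions[onset[keep], keep, :]
    ) * res
    return TrackedPoints(
        positions=positions[:, keep],
        onset_index=onset[keep],
        displacement_mm=disp,
        brightness=brightness[:, keep],
        final_index=final,
        n_lost=n_lost,
    )


# ---------------------------------------------------------------------------
# force conditioning and correlation
# ---------------------------------------------------------------------------


def filter_force(
    force: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = 50.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-lag second-order low-pass filtering of a force trace.

    A Butterworth filter of the given order and cutoff is applied
    forward and backward (``filtfilt``), cancelling the phase lag; the
    DC gain is exactly 1, so a constant trace is unchanged.
    """
    x = np.asarray(force, dtype=float)
    if sample_rate <= 100.0:
        raise ParameterError("sample_rate must exceed 100 Hz")
    if not 0 < cutoff_hz < sample_rate / 2:
        raise ParameterError("cutoff must lie below the Nyquist frequency")
    b, a = signal.butter(order, cutoff_hz, fs=sample_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise DataError(
            f"force trace of length {x.size} too short for zero-lag "
            f"filtering (needs > {padlen} samples)"
        )
    return signal.filtfilt(b, a, x)


def displacement_brightness_correlation(
    tracked: TrackedPoints,
    contact_image: np.ndarray,
) -> tuple[float, float]:
    """Spearman correlation of displacement magnitude vs local brightness.

    Brightness is measured in the given contact-channel image (usually
    the final tracked frame) within a 10-px disk around each point's
    final position; ties are mid-ranked.  Returns ``(rho, p_value)``.
    """
    pts = tracked.positions[tracked.final_index]
    if pts.shape[0] < 10:
        raise DataError("need at least 10 tracked points for a rank correlation")
    mag = np.hypot(*tracked.displacement_mm.T)
    bright = _local_brightness_many(
        np.asarray(contact_image, dtype=float), pts, LOCAL_BRIGHTNESS_RADIUS_PX
    )
    if np.ptp(mag) == 0 or np.ptp(bright) == 0:
        raise UndefinedCorrelationError(
            "rank correlation undefined for a constant vector"
        )
    rho, p = spearmanr(mag, bright)
    return float(rho), float(p)
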