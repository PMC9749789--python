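"""Surface tension from contour-fluctuation (flicker) spectroscopy.

A liquid condensate at thermal equilibrium exhibits shape fluctuations
whose mean-square amplitude is set by its interfacial tension.  Averaging
the deviation of the droplet contour from its mean shape over both time
and polar angle gives a mean-square fluctuation u2, and the tension
follows from

    gamma = kB * T / u2.

The estimator here is deliberately simple and robust: per frame the
condensate boundary is expressed as radius versus polar angle about the
intensity-weighted centroid; the reference contour is the per-angle time
mean; angular Fourier modes 0 (area/segmentation drift) and 1 (residual
translation) are removed before averaging, since neither reflects
interfacial fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import gaussian, threshold_otsu

from nucleoquant.constants import K_BOLTZMANN
from nucleoquant.io import ImageStack


@dataclass
class ContourSeries:
    """Polar contour samples r(theta_i, t_j) of one condensate.

    Attributes
    ----------
    radii : ndarray, shape (n_frames, n_angles)
        Contour radius in metres at ``n_angles`` equally spaced polar
        angles ``theta_i = 2 pi i / n_angles``.
    centroids : ndarray, shape (n_frames, 2)
        Per-frame (row, col) centroid about which radii were measured.
    pixel_size : float
        Metres per pixel of the source image (advisory for synthetic
        series whose radii are generated directly in metres).
    frame_interval : float
        Seconds between frames.
    """

    radii: np.ndarray
    centroids: np.ndarray
    pixel_size: float
    frame_interval: float = 0.0

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 2:
            raise ValueError("radii must be (n_frames, n_angles)")
        if self.radii.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.radii.shape[1] < 32:
            raise ValueError("need at least 32 polar angles")
        if not (self.radii > 0).all():
            raise ValueError("all radii must be > 0")

    @property
    def n_frames(self) -> int:
        return self.radii.shape[0]

    @property
    def n_angles(self) -> int:
        return self.radii.shape[1]

    @property
    def angles(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.n_angles) / self.n_angles


@dataclass
class TensionEstimate:
    """Result of a flicker-spectroscopy measurement.

    ``gamma = kB * temperature / u2`` with u2 the filtered mean-square
    contour fluctuation in square metres.
    """

    u2: float
    gamma: float
    temperature: float
    n_frames: int
    modes_used: list = field(default_factory=list)


def extract_contours(
    stack: ImageStack,
    channel,
    target_label: int = 1,
    n_angles: int = 256,
    labels: np.ndarray | None = None,
    max_lost_fraction: float = 0.1,
    smoothing_sigma: float = 1.0,
) -> ContourSeries:
    """Trace one condensate's boundary through a time-lapse stack.

    Each frame is re-segmented independently (Otsu threshold on the chosen
    channel, connected components); the component tracked is the one
    whose pixels overlap the previous frame's mask (the first frame uses
    ``target_label`` of ``labels`` if given, else the largest component).
    The boundary is the sub-pixel iso-intensity contour at the threshold,
    converted to radius versus polar angle about the frame's
    intensity-weighted centroid and resampled at ``n_angles`` equal angles
    by periodic linear interpolation.  Radii are returned in metres via
    the stack's pixel size.  A light Gaussian pre-smoothing
    (``smoothing_sigma`` pixels) suppresses pixel-locking of the
    sub-pixel boundary on sharp edges.

    Frames where segmentation fails are dropped; losing more than
    ``max_lost_fraction`` of frames raises an error ("unstable
    segmentation").  Non-star-shaped boundaries take the outermost
    crossing at each angle, with a warning.
    """
    ch = stack.channel_index(channel)
    n_frames = stack.n_frames
    radii_list = []
    centroids = []
    prev_mask = None
    if labels is not None:
        prev_mask = labels == target_label
        if not prev_mask.any():
            raise ValueError(f"target label {target_label} absent from label image")
    lost = 0
    nonstar_angles = 0
    for t in range(n_frames):
        plane = stack.pixels[t, ch].astype(float)
        if smoothing_sigma > 0:
            plane = gaussian(plane, sigma=smoothing_sigma, preserve_range=True)
        try:
            thr = threshold_otsu(plane)
        except ValueError:
            lost += 1
            continue
        mask = plane > thr
        lab = skmeasure.label(mask)
        if lab.max() == 0:
            lost += 1
            continue
        if prev_mask is not None and prev_mask.shape == lab.shape:
            overlap = np.bincount(lab[prev_mask].ravel(), minlength=lab.max() + 1)
            overlap[0] = 0
            target = int(overlap.argmax()) if overlap.any() else 0
        else:
            target = 0
        if target == 0:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            target = int(sizes.argmax())
        obj = lab == target
        if not obj.any():
            lost += 1
            continue
        prev_mask = obj
        # intensity-weighted centroid over the object
        w = plane * obj
        total = w.sum()
        rows, cols = np.nonzero(obj)
        cy = (rows * w[rows, cols]).sum() / total
        cx = (cols * w[rows, cols]).sum() / total
        # sub-pixel boundary of the tracked object at the half-max level
        # (midway between object and background intensity), evaluated on a
        # locally masked plane so neighbouring objects contribute nothing
        hi = float(np.median(plane[obj]))
        lo = float(np.median(plane[~mask])) if (~mask).any() else 0.0
        level = 0.5 * (hi + lo)
        nearby = ndi.binary_dilation(obj, iterations=3)
        work = np.where(nearby, plane, lo)
        contours = skmeasure.find_contours(work, level)
        if not contours:
            lost += 1
            continue
        contour = max(contours, key=len)  # (row, col) polyline
        r, ns = _resample_polar(contour, (cy, cx), n_angles)
        nonstar_angles += ns
        radii_list.append(r * stack.pixel_size * 1e-6)  # um -> m
        centroids.append((cy, cx))
    if n_frames - len(radii_list) > max_lost_fraction * n_frames:
        raise RuntimeError(
            f"unstable segmentation: target lost in {n_frames - len(radii_list)} "
            f"of {n_frames} frames"
        )
    if nonstar_angles:
        warnings.warn(
            f"non-star-shaped boundary at {nonstar_angles} angle samples; "
            "took the outermost crossing",
            stacklevel=2,
        )
    return ContourSeries(
        radii=np.asarray(radii_list),
        centroids=np.asarray(centroids),
        pixel_size=stack.pixel_size * 1e-6,
        frame_interval=stack.frame_interval,
    )


def _resample_polar(contour: np.ndarray, center: tuple, n_angles: int):
    """Resample a closed (row, col) polyline as r(theta) on a uniform grid.

    Returns (radii, n_nonstar): radii at theta_i = 2 pi i / n_angles, and
    the number of grid angles where the boundary crossed more than once
    (outermost crossing kept).
    """
    dy = contour[:, 0] - center[0]
    dx = contour[:, 1] - center[1]
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    r = np.hypot(dy, dx)
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # collapse multiple crossings per angle bin to the outermost
    grid = 2 * np.pi * np.arange(n_angles) / n_angles
    bins = np.floor(theta / (2 * np.pi) * n_angles).astype(int) % n_angles
    n_nonstar = int(np.sum(np.bincount(bins, minlength=n_angles) > np.ceil(len(theta) / n_angles) * 3)) if len(theta) else 0
    # periodic linear interpolation (keep max radius at duplicate angles)
    uniq, inv = np.unique(theta, return_inverse=True)
    rmax = np.full(uniq.shape, -np.inf)
    np.maximum.at(rmax, inv, r)
    theta_ext = np.concatenate([uniq - 2 * np.pi, uniq, uniq + 2 * np.pi])
    r_ext = np.concatenate([rmax, rmax, rmax])
    return np.interp(grid, theta_ext, r_ext), n_nonstar


def fluctuation_amplitude(contours: ContourSeries, exclude_modes=(0, 1)) -> float:
    """Mean-square contour fluctuation u2 in square metres.

    The deviation ``h(theta, t) = r(theta, t) - rbar(theta)`` from the
    per-angle time-mean contour is Fourier-decomposed in the angle per
    frame; excluded modes (default 0 and 1) are zeroed; u2 is the mean of
    the filtered ``h**2`` over frames and angles, with an ``N/(N-1)``
    correction for the variance absorbed by the time-mean reference.
    """
    r = contours.radii
    N, M = r.shape
    if N < 2:
        raise ValueError("need at least 2 frames")
    h = r - r.mean(axis=0, keepdims=True)
    spec = np.fft.rfft(h, axis=1)
    for q in exclude_modes:
        if 0 <= q < spec.shape[1]:
            spec[:, q] = 0.0
    # Parseval: mean over angles of |h|^2 from the one-sided spectrum
    power = np.abs(spec) ** 2
    weights = np.full(spec.shape[1], 2.0)
    weights[0] = 1.0
    if M % 2 == 0:
        weights[-1] = 1.0
    mean_sq_per_frame = (power * weights).sum(axis=1) / M**2
    return float(mean_sq_per_frame.mean() * N / (N - 1))


def surface_tension(u2: float, temperature: float) -> TensionEstimate:
    """Interfacial tension gamma = kB T / u2 from a mean-square fluctuation.

    Raises on ``u2 = 0``: a perfectly static contour carries no
    information about tension (it only bounds it from below).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if u2 < 0:
        raise ValueError("u2 must be >= 0")
    if u2 == 0:
        raise ValueError("zero fluctuation - tension unresolvable")
    gamma = K_BOLTZMANN * temperature / u2
    return TensionEstimate(u2=float(u2), gamma=float(gamma), temperature=float(temperature), n_frames=0)


def estimate_tension(
    contours: ContourSeries, temperature: float, exclude_modes=(0, 1)
) -> TensionEstimate:
    """Full flicker estimate: u2 from a contour series, then gamma."""
    u2 = fluctuation_amplitude(contours, exclude_modes=exclude_modes)
    est = surface_tension(u2, temperature)
    est.n_frames = contours.n_frames
    est.modes_used = [q for q in range(contours.n_angles // 2 + 1) if q not in exclude_modes]
    return est
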