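"""Bidimensional empirical mode decomposition (BEMD) of grayscale images.

An image is decomposed into intrinsic mode functions (IMFs) plus a residual
trend by iterative *sifting*: at each step the mean of the upper (maxima) and
lower (minima) envelopes is subtracted until the component oscillates around
a locally-zero mean.  Earlier IMFs carry higher spatial frequencies; the
residual carries the overall intensity trend.  The identity

    image = sum(IMFs) + residual

holds to floating-point precision and is enforced by construction.

Envelopes are smooth scattered-data surfaces interpolated through the local
extrema with a thin-plate-spline radial basis function (the standard choice
for bidimensional EMD, where the 1D cubic-spline construction has no direct
analogue).  The interpolant includes a linear polynomial tail, so planar
data are reproduced exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import maximum_filter, minimum_filter
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

MIN_IMAGE_SIZE = 8
#: switch from a global RBF solve to a local (nearest-neighbour) solve above
#: this many extrema; the local solve is still exact at the data points
_RBF_NEIGHBOR_LIMIT = 1500
_RBF_NEIGHBORS = 96


class DegenerateEnvelopeError(ValueError):
    """Fewer than 3 extrema, or all extrema collinear: no surface exists."""


class MonotoneComponentError(RuntimeError):
    """The component has too few extrema to sift; decomposition terminates."""


@dataclass(frozen=True)
class SiftConfig:
    """Parameters of the sifting loop.

    max_imfs : number of IMFs to extract; with the residual this yields
        ``max_imfs + 1`` components (default 4 -> five components).
    max_sift_iterations : hard cap on envelope-mean subtractions per IMF.
    sd_threshold : Cauchy-type stop criterion
        ``SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold``.
    extrema_connectivity : 4 or 8 neighbourhood for strict local extrema.
    boundary_margin : mirror-extension width (pixels) applied before extrema
        detection and envelope construction to suppress edge artifacts.
    """

    max_imfs: int = 4
    max_sift_iterations: int = 10
    sd_threshold: float = 0.2
    extrema_connectivity: int = 8
    boundary_margin: int = 8

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.max_sift_iterations < 1:
            raise ValueError("max_sift_iterations must be >= 1")
        if not self.sd_threshold > 0:
            raise ValueError("sd_threshold must be > 0")
        if self.extrema_connectivity not in (4, 8):
            raise ValueError("extrema_connectivity must be 4 or 8")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be >= 0")


@dataclass
class IMFStack:
    """Ordered IMFs plus residual for one image; sums back to the source."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_shape: tuple[int, int]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


@dataclass
class ChannelStack:
    """The four network input channels: original, IMF2, IMF3, IMF4."""

    channels: np.ndarray  # (H, W, 4)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape


def as_image(image, *, min_size: int = MIN_IMAGE_SIZE) -> np.ndarray:
    """Validate and return a finite 2D float64 intensity grid."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(
            f"image of shape {arr.shape} is smaller than the minimum "
            f"{min_size}x{min_size} required for decomposition"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def _footprint(connectivity: int) -> np.ndarray:
    foot = np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        foot[0, 0] = foot[0, 2] = foot[2, 0] = foot[2, 2] = False
    foot[1, 1] = False  # exclude centre: strict comparison against neighbours
    return foot


def _extrema_masks(padded: np.ndarray, connectivity: int):
    foot = _footprint(connectivity)
    mx = padded > maximum_filter(padded, footprint=foot, mode="mirror")
    mn = padded < minimum_filter(padded, footprint=foot, mode="mirror")
    return mx, mn


def find_local_extrema(image, config: SiftConfig = SiftConfig()):
    """Strict local maxima and minima after mirror extension.

    A pixel is a maximum iff strictly greater than every neighbour under the
    configured connectivity, neighbourhoods at the border being completed by
    mirror extension of width ``boundary_margin``.  Returns two sets of
    ``(row, col, value)`` tuples in original image coordinates.
    """
    arr = as_image(image, min_size=3)  # the size floor applies to decomposition
    m = min(config.boundary_margin, arr.shape[0] - 1, arr.shape[1] - 1)
    padded = np.pad(arr, m, mode="reflect") if m > 0 else arr
    mx, mn = _extrema_masks(padded, config.extrema_connectivity)
    h, w = arr.shape
    maxima = set()
    minima = set()
    for r, c in np.argwhere(mx):
        if m <= r < m + h and m <= c < m + w:
            maxima.add((int(r - m), int(c - m), float(padded[r, c])))
    for r, c in np.argwhere(mn):
        if m <= r < m + h and m <= c < m + w:
            minima.add((int(r - m), int(c - m), float(padded[r, c])))
    return maxima, minima


def build_envelope(points, shape: tuple[int, int]) -> np.ndarray:
    """Thin-plate-spline surface through scattered ``(row, col, value)`` points.

    The surface passes through every supplied point and, because a degree-1
    polynomial tail is included, reproduces affine data exactly.  Fewer than
    3 points or collinear points raise :class:`DegenerateEnvelopeError`.
    """
    pts = np.asarray(sorted(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateEnvelopeError("need at least 3 extrema to build an envelope")
    coords, values = pts[:, :2], pts[:, 2]
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateEnvelopeError("extrema are collinear; surface is underdetermined")
    neighbors = None if len(coords) <= _RBF_NEIGHBOR_LIMIT else _RBF_NEIGHBORS
    interp = RBFInterpolator(
        coords, values, kernel="thin_plate_spline", degree=1, neighbors=neighbors
    )
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    surface = interp(grid).reshape(shape)
    if not np.all(np.isfinite(surface)):
        raise DegenerateEnvelopeError("envelope interpolation produced non-finite values")
    return surface


def _padded_extrema_points(h: np.ndarray, config: SiftConfig):
    """Extrema of the mirror-extended component, in padded coordinates.

    Margin-region extrema (mirror copies) are kept so the envelopes stay
    supported beyond the original border.
    """
    m = min(config.boundary_margin, h.shape[0] - 1, h.shape[1] - 1)
    padded = np.pad(h, m, mode="reflect") if m > 0 else h
    mx, mn = _extrema_masks(padded, config.extrema_connectivity)
    max_pts = [(int(r), int(c), float(padded[r, c])) for r, c in np.argwhere(mx)]
    min_pts = [(int(r), int(c), float(padded[r, c])) for r, c in np.argwhere(mn)]
    return max_pts, min_pts, padded.shape, m


def mean_envelope(h: np.ndarray, config: SiftConfig = SiftConfig()) -> np.ndarray:
    """(upper envelope + lower envelope) / 2 of the mirror-extended component."""
    max_pts, min_pts, padded_shape, m = _padded_extrema_points(h, config)
    if len(max_pts) < 3 or len(min_pts) < 3:
        raise DegenerateEnvelopeError(
            f"too few extrema ({len(max_pts)} maxima, {len(min_pts)} minima)"
        )
    upper = build_envelope(max_pts, padded_shape)
    lower = build_envelope(min_pts, padded_shape)
    mean = (upper + lower) / 2.0
    if m > 0:
        mean = mean[m : m + h.shape[0], m : m + h.shape[1]]
    return mean


def sift_imf(image, config: SiftConfig = SiftConfig()):
    """Extract one IMF by repeated envelope-mean subtraction.

    Iterates ``h <- h - mean_envelope(h)`` until the standard-deviation
    criterion ``SD = sum((h_prev - h)^2) / sum(h_prev^2)`` drops below
    ``config.sd_threshold`` or ``max_sift_iterations`` is reached.

    Returns ``(imf, converged)``.  Raises :class:`MonotoneComponentError`
    when the input has too few extrema to sift at all (callers terminate the
    decomposition and keep the input as the residual trend).
    """
    h = as_image(image).copy()
    converged = False
    for iteration in range(config.max_sift_iterations):
        try:
            m = mean_envelope(h, config)
        except DegenerateEnvelopeError as exc:
            if iteration == 0:
                raise MonotoneComponentError(str(exc)) from exc
            break
        denom = float(np.sum(h * h))
        if denom == 0.0:
            break
        h_new = h - m
        sd = float(np.sum(m * m)) / denom  # h - h_new == m
        h = h_new
        if sd < config.sd_threshold:
            converged = True
            break
    return h, converged


def decompose(image, config: SiftConfig = SiftConfig()) -> IMFStack:
    """Full BEMD: repeatedly sift the running residual.

    Stops after ``config.max_imfs`` IMFs or when the residual is monotone
    (too few extrema).  The returned stack satisfies
    ``sum(imfs) + residual == image`` to floating-point precision.
    """
    arr = as_image(image)
    residual = arr.copy()
    imfs: list[np.ndarray] = []
    for _ in range(config.max_imfs):
        try:
            imf, _ = sift_imf(residual, config)
        except MonotoneComponentError:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFStack(imfs=imfs, residual=residual, source_shape=arr.shape)


def standardize_channel(channel: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Zero-mean unit-variance scaling; constant channels become all-zero."""
    sd = channel.std()
    if sd <= eps:
        return np.zeros_like(channel)
    return (channel - channel.mean()) / sd


def select_channels(image, stack: IMFStack, normalize: bool = True) -> ChannelStack:
    """Stack the network input channels: [original, IMF2, IMF3, IMF4].

    IMF1 (mostly high-frequency noise) and the residual trend are dropped.
    If fewer than 4 IMFs were extracted the missing channels are zero-filled
    with a logged warning.  With ``normalize`` each channel is independently
    standardized to zero mean and unit standard deviation.
    """
    arr = as_image(image)
    if stack.source_shape != arr.shape:
        raise ValueError(
            f"stack shape {stack.source_shape} does not match image shape {arr.shape}"
        )
    channels = [arr]
    for idx in (1, 2, 3):  # IMF2..IMF4 (0-based)
        if idx < stack.n_imfs:
            channels.append(stack.imfs[idx])
        else:
            logger.warning(
                "only %d IMFs available; zero-filling channel IMF%d",
                stack.n_imfs, idx + 1,
            )
            channels.append(np.zeros_like(arr))
    if normalize:
        channels = [standardize_channel(c) for c in channels]
    return ChannelStack(channels=np.stack(channels, axis=-1))


class EMDChannelStacker(BaseEstimator, TransformerMixin):
    """Transformer turning grayscale images into 4-channel EMD input stacks.

    A stateless scikit-learn transformer: ``fit`` only validates, and
    ``transform`` maps an ``(n, H, W)`` array (or a list of 2D arrays) to an
    ``(n, H, W, 4)`` array of [original, IMF2, IMF3, IMF4] channels.
    """

    def __init__(
        self,
        max_imfs: int = 4,
        max_sift_iterations: int = 10,
        sd_threshold: float = 0.2,
        extrema_connectivity: int = 8,
        boundary_margin: int = 8,
        normalize: bool = True,
    ):
        self.max_imfs = max_imfs
        self.max_sift_iterations = max_sift_iterations
        self.sd_threshold = sd_threshold
        self.extrema_connectivity = extrema_connectivity
        self.boundary_margin = boundary_margin
        self.normalize = normalize

    def _config(self) -> SiftConfig:
        return SiftConfig(
            max_imfs=self.max_imfs,
            max_sift_iterations=self.max_sift_iterations,
            sd_threshold=self.sd_threshold,
            extrema_connectivity=self.extrema_connectivity,
            boundary_margin=self.boundary_margin,
        )

    def fit(self, X, y=None):
        self._config()  # parameter validation
        self.n_features_in_ = None
        return self

    def transform(self, X) -> np.ndarray:
        config = self._config()
        stacks = []
        for img in X:
            arr = as_image(img)
            stack = decompose(arr, config)
            stacks.append(select_channels(arr, stack, normalize=self.normalize).channels)
        return np.stack(stacks, axis=0)
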