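"""Gabor lifting of planar images to SIM(2).

A grayscale image I(x, y) >= 0 is probed with a two-parameter bank of
receptive profiles obtained from the even "mother" Gabor

    G_(0,0)(x, y) = exp(-(x^2 + y^2)) cos(2 y)

by rotation through theta and dilation by e^sigma,

    G_(theta,sigma)(x, y) = e^{-2 sigma} exp(-(xt^2 + yt^2)) cos(2 yt),
    xt = e^{-sigma}( x cos theta + y sin theta),
    yt = e^{-sigma}(-x sin theta + y cos theta).

The lifted image is the response stack O(x, y, theta, sigma) =
(I * G_(theta,sigma))(x, y); at each retinal point the engrafted
variables (theta, sigma) are read off by maximum response.

The cosine profile is even, so responses are pi-periodic in theta: the
bank samples theta in [0, pi) and the direction of travel along a
contour (theta vs theta + pi) is resolved downstream, when endpoints
are oriented toward a damaged region.  The argmax is taken over |O|
because the even filter flips sign with contrast polarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .group import GroupElement

__all__ = [
    "ImageGrid",
    "GaborBank",
    "LiftedImage",
    "SelectionResult",
    "gabor_profile",
    "gabor_kernel",
    "lift_image",
    "fiber_response",
    "select_orientation_scale",
    "extract_boundary_configurations",
]


@dataclass
class ImageGrid:
    """A raster image with a pixel -> retinal-plane mapping.

    Retinal axes: x to the right, y up.  ``origin`` is the retinal
    coordinate of pixel (row 0, col 0); by default the image center
    maps to (0, 0).
    """

    intensities: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a nonempty 2-D array")
        if np.any(self.intensities < 0):
            raise ValueError("image intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.origin is None:
            h, w = self.intensities.shape
            self.origin = (
                -0.5 * (w - 1) * self.pixel_size,
                0.5 * (h - 1) * self.pixel_size,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def pixel_to_retinal(self, row: float, col: float) -> tuple[float, float]:
        return (
            self.origin[0] + col * self.pixel_size,
            self.origin[1] - row * self.pixel_size,
        )

    def retinal_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        return (
            (self.origin[1] - y) / self.pixel_size,
            (x - self.origin[0]) / self.pixel_size,
        )

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.intensities.copy(), self.pixel_size, self.origin)


@dataclass
class GaborBank:
    """Discrete orientation/log-scale sampling of the Gabor family.

    ``support_radius`` truncates each profile at that many dilated
    units (e^sigma) from its center; at the default 3 the Gaussian
    envelope has decayed below 1.3e-4.  ``sigma_offset`` is the
    calibration constant relating the argmax log-scale to physical
    log-thickness (measured on a reference bar, see
    :func:`sim2sr.synthetic.calibrate_sigma_offset`).
    """

    theta_grid: np.ndarray
    sigma_grid: np.ndarray
    support_radius: float = 3.0
    sigma_offset: float = 0.0

    def __post_init__(self):
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        for g, name in ((self.theta_grid, "theta"), (self.sigma_grid, "sigma")):
            if g.size < 2 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name}_grid must be strictly increasing, >= 2 samples")
        if np.any(self.theta_grid < 0) or np.any(self.theta_grid >= math.pi):
            raise ValueError("theta_grid must lie in [0, pi)")

    @classmethod
    def default(cls, n_theta: int = 16, n_sigma: int = 8,
                sigma_range: tuple[float, float] = (-1.0, 1.8)) -> "GaborBank":
        return cls(
            theta_grid=np.arange(n_theta) * math.pi / n_theta,
            sigma_grid=np.linspace(*sigma_range, n_sigma),
        )

    def with_offset(self, offset: float) -> "GaborBank":
        return replace(self, sigma_offset=offset)


@dataclass
class LiftedImage:
    """4-D response stack O indexed (row, col, theta, sigma)."""

    responses: np.ndarray
    image: ImageGrid
    bank: GaborBank

    def __post_init__(self):
        expected = self.image.shape + (len(self.bank.theta_grid), len(self.bank.sigma_grid))
        if self.responses.shape != expected:
            raise ValueError("response shape inconsistent with grids")

    def fiber(self, row: int, col: int) -> np.ndarray:
        return self.responses[row, col]


def gabor_profile(theta: float, sigma: float, x, y):
    """Rotated/dilated receptive profile, including the e^{-2 sigma} factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ems = math.exp(-sigma)
    c, s = math.cos(theta), math.sin(theta)
    xt = ems * (x * c + y * s)
    yt = ems * (-x * s + y * c)
    return math.exp(-2.0 * sigma) * np.exp(-(xt**2 + yt**2)) * np.cos(2.0 * yt)


def gabor_kernel(theta: float, sigma: float, pixel_size: float,
                 support_radius: float = 3.0) -> np.ndarray:
    """Profile integrated over pixel footprints, scaled by pixel area.

    Row offsets point down, so the retinal y offset is the negated row
    offset.  When the pixel pitch is coarse relative to the dilated
    envelope e^sigma the profile is supersampled and averaged per pixel
    so that fine-scale kernels do not alias.  Correlating an image with
    this kernel realizes the convolution I * G (the profile is even).
    """
    es = math.exp(sigma)
    half = max(1, math.ceil(support_radius * es / pixel_size))
    sub = max(1, math.ceil(4.0 * pixel_size / es))
    n = 2 * half + 1
    fine = (np.arange(n * sub) - (n * sub - 1) / 2.0) * (pixel_size / sub)
    dx, dy = np.meshgrid(fine, -fine)  # dy: row down -> y down
    vals = gabor_profile(theta, sigma, dx, dy)
    if sub > 1:
        vals = vals.reshape(n, sub, n, sub).mean(axis=(1, 3))
    return vals * pixel_size**2


def lift_image(img: ImageGrid, bank: GaborBank, method: str = "auto") -> LiftedImage:
    """Convolve the image with every bank profile (reflective padding).

    ``method``: 'direct' (ndimage correlation), 'fft' (reflect-pad +
    FFT convolution) or 'auto' (FFT for large kernels).  Both routes
    evaluate the same truncated-kernel convolution.
    """
    if method not in ("auto", "direct", "fft"):
        raise ValueError(f"unknown method {method!r}")
    h, w = img.shape
    out = np.empty((h, w, len(bank.theta_grid), len(bank.sigma_grid)))
    for si, sigma in enumerate(bank.sigma_grid):
        for ti, theta in enumerate(bank.theta_grid):
            k = gabor_kernel(theta, sigma, img.pixel_size, bank.support_radius)
            use_fft = method == "fft" or (method == "auto" and k.shape[0] > 17)
            if use_fft:
                half = k.shape[0] // 2
                # edge-inclusive reflection, matching ndimage's 'reflect'
                padded = np.pad(img.intensities, half, mode="symmetric")
                # even kernel: convolution == correlation
                full = signal.fftconvolve(padded, k, mode="same")
                out[:, :, ti, si] = full[half:half + h, half:half + w]
            else:
                out[:, :, ti, si] = ndimage.correlate(
                    img.intensities, k, mode="reflect"
                )
    return LiftedImage(out, img, bank)


def fiber_response(img: ImageGrid, bank: GaborBank, row: int, col: int) -> np.ndarray:
    """Responses O(row, col, :, :) at a single pixel (no full lift)."""
    out = np.empty((len(bank.theta_grid), len(bank.sigma_grid)))
    for si, sigma in enumerate(bank.sigma_grid):
        for ti, theta in enumerate(bank.theta_grid):
            k = gabor_kernel(theta, sigma, img.pixel_size, bank.support_radius)
            half = k.shape[0] // 2
            # edge-inclusive reflective boundary, matching the full lift
            padded = np.pad(img.intensities, half, mode="symmetric")
            patch = padded[row:row + 2 * half + 1, col:col + 2 * half + 1]
            out[ti, si] = float((patch * k).sum())
    return out


@dataclass(frozen=True)
class SelectionResult:
    """Engrafted variables selected at one retinal point."""

    theta: float
    sigma: float
    theta_index: int
    sigma_index: int
    flag: str  # 'ok' | 'tie' | 'no_response'


def _select_from_fiber(fiber: np.ndarray, bank: GaborBank) -> SelectionResult:
    mag = np.abs(fiber)
    peak = mag.max()
    if peak == 0.0:
        return SelectionResult(bank.theta_grid[0], bank.sigma_grid[0], 0, 0, "no_response")
    hits = np.argwhere(mag >= peak * (1.0 - 1e-12))
    ti, si = min(map(tuple, hits))  # lexicographic tie-break
    flag = "tie" if len(hits) > 1 else "ok"
    return SelectionResult(bank.theta_grid[ti], bank.sigma_grid[si], int(ti), int(si), flag)


def select_orientation_scale(L: LiftedImage, row: int, col: int) -> SelectionResult:
    """Argmax of |O| over the (theta, sigma) fiber at a pixel.

    Ties are broken toward the smallest (theta, sigma) grid pair; an
    all-zero fiber is flagged 'no_response'.
    """
    h, w = L.image.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError("pixel outside the image grid")
    return _select_from_fiber(L.fiber(row, col), L.bank)


def extract_boundary_configurations(
    img: ImageGrid,
    mask: np.ndarray,
    bank: GaborBank | None = None,
    intensity_threshold: float = 0.5,
    probe_factor: float = 1.25,
    probe_iters: int = 2,
) -> list[GroupElement]:
    """Contour configurations q = (x, y, theta, sigma) at a mask boundary.

    Pixels just outside the damaged region that carry sufficient image
    intensity (>= ``intensity_threshold`` times the off-mask maximum)
    are clustered into connected endpoint components; each yields one
    configuration anchored at the component centroid.  The engrafted
    variables (theta, sigma) are read a little away from the cut, where
    the contour is intact: the probe steps outward (away from the mask
    centroid) by ``probe_factor`` times the currently estimated
    thickness, iterated ``probe_iters`` times, because a filter sitting
    on the cut itself responds to the void's edge rather than to the
    contour.  sigma is returned calibrated to physical log-thickness
    via the bank's ``sigma_offset``.
    """
    from skimage.measure import label
    from skimage.morphology import dilation

    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match the image")
    if mask.all():
        raise ValueError("mask covers the whole image; no contours to anchor")
    if not mask.any():
        return []
    bank = bank or GaborBank.default()

    outside = img.intensities[~mask]
    peak = outside.max() if outside.size else 0.0
    if peak <= 0.0:
        return []
    ring = dilation(mask, footprint=np.ones((3, 3))) & ~mask
    candidates = ring & (img.intensities >= intensity_threshold * peak)
    if not candidates.any():
        return []

    h, w = img.shape
    mrows, mcols = np.nonzero(mask)
    mask_center = (mrows.mean(), mcols.mean())

    labels = label(candidates, connectivity=2)
    configs: list[GroupElement] = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        r0, c0 = rows.mean(), cols.mean()
        dr, dc = r0 - mask_center[0], c0 - mask_center[1]
        nrm = math.hypot(dr, dc) or 1.0
        dr, dc = dr / nrm, dc / nrm

        def probe(rr, cc):
            rr = int(min(max(round(rr), 0), h - 1))
            cc = int(min(max(round(cc), 0), w - 1))
            return _select_from_fiber(fiber_response(img, bank, rr, cc), bank)

        sel = probe(r0, c0)
        if sel.flag == "no_response":
            continue
        for _ in range(probe_iters):
            width = math.exp(sel.sigma - bank.sigma_offset)
            off = probe_factor * width / img.pixel_size
            nxt = probe(r0 + dr * off, c0 + dc * off)
            if nxt.flag == "no_response":
                break
            sel = nxt
        x, y = img.pixel_to_retinal(r0, c0)
        configs.append(GroupElement(x, y, sel.theta, sel.sigma - bank.sigma_offset))
    return configs
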