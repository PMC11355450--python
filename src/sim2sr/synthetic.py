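"""Synthetic curve images and corruption fixtures.

These generators stand in for real imagery (vessel photographs and the
like): they rasterize polylines with a prescribed, possibly varying,
stroke width and record the exact centerline ground truth (position,
tangent angle, log-width), so lifting and completion can be scored
against a known answer.  All randomness flows through an explicit
seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lifting import GaborBank, ImageGrid, fiber_response

__all__ = [
    "CurveSpec",
    "make_curve_image",
    "corrupt_with_disc",
    "calibrate_sigma_offset",
]


@dataclass(frozen=True)
class CurveSpec:
    """A polyline stroke: waypoints with per-waypoint width and gray level."""

    waypoints: tuple
    width_profile: tuple
    intensity: float = 1.0

    def __post_init__(self):
        wp = tuple((float(x), float(y)) for x, y in self.waypoints)
        wd = tuple(float(w) for w in self.width_profile)
        object.__setattr__(self, "waypoints", wp)
        object.__setattr__(self, "width_profile", wd)
        if len(wp) < 2:
            raise ValueError("a curve needs at least 2 waypoints")
        if len(wd) != len(wp):
            raise ValueError("width_profile must match waypoints")
        if any(w <= 0 for w in wd):
            raise ValueError("stroke widths must be positive")
        if not (0.0 < self.intensity <= 1.0):
            raise ValueError("intensity must be in (0, 1]")
        for (x0, y0), (x1, y1) in zip(wp[:-1], wp[1:]):
            if math.hypot(x1 - x0, y1 - y0) == 0.0:
                raise ValueError("degenerate zero-length segment in spec")


def make_curve_image(
    spec: CurveSpec,
    shape: tuple[int, int] = (96, 96),
    pixel_size: float = 1.0,
    origin: tuple[float, float] | None = None,
    seed: int | None = None,
    noise: float = 0.0,
    truth_spacing: float | None = None,
) -> tuple[ImageGrid, list[dict]]:
    """Rasterize a polyline stroke and return (image, centerline truth).

    The stroke width is interpolated linearly along each segment; a
    pixel is lit when its distance to the centerline is within half the
    local width.  The truth list holds samples of
    ``{x, y, theta, log_width}`` along each arc (theta = tangent angle).
    Optional zero-mean Gaussian noise (std ``noise``) is seeded and
    clipped to keep intensities nonnegative.
    """
    canvas = ImageGrid(np.zeros(shape), pixel_size, origin)
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    px = canvas.origin[0] + cols * pixel_size
    py = canvas.origin[1] - rows * pixel_size

    img = np.zeros(shape)
    truth: list[dict] = []
    step = truth_spacing if truth_spacing is not None else pixel_size
    for (x0, y0), (x1, y1), w0, w1 in zip(
        spec.waypoints[:-1], spec.waypoints[1:],
        spec.width_profile[:-1], spec.width_profile[1:],
    ):
        dx, dy = x1 - x0, y1 - y0
        seg_len = math.hypot(dx, dy)
        t = np.clip(((px - x0) * dx + (py - y0) * dy) / seg_len**2, 0.0, 1.0)
        cxp = x0 + t * dx
        cyp = y0 + t * dy
        dist = np.hypot(px - cxp, py - cyp)
        width = w0 + t * (w1 - w0)
        img = np.maximum(img, np.where(dist <= 0.5 * width, spec.intensity, 0.0))

        theta = math.atan2(dy, dx)
        n = max(2, int(seg_len / step) + 1)
        for tt in np.linspace(0.0, 1.0, n):
            truth.append({
                "x": x0 + tt * dx,
                "y": y0 + tt * dy,
                "theta": theta,
                "log_width": math.log(w0 + tt * (w1 - w0)),
            })

    if noise > 0.0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(scale=noise, size=shape), 0.0, None)
    canvas.intensities = img
    return canvas, truth


def corrupt_with_disc(
    img: ImageGrid, center: tuple[float, float], radius: float
) -> tuple[ImageGrid, np.ndarray]:
    """Blank a disc (retinal coordinates) out of the image; return the mask.

    Pixels inside the disc are set to the background level 0; the
    boolean mask marks exactly those pixels.  Idempotent for a fixed
    disc.
    """
    if radius <= 0:
        raise ValueError("disc radius must be positive")
    rows, cols = np.meshgrid(
        np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij"
    )
    px = img.origin[0] + cols * img.pixel_size
    py = img.origin[1] - rows * img.pixel_size
    mask = (px - center[0]) ** 2 + (py - center[1]) ** 2 <= radius**2
    if not mask.any():
        raise ValueError("disc does not intersect the canvas")
    out = img.copy()
    out.intensities[mask] = 0.0
    return out, mask


def calibrate_sigma_offset(
    bank: GaborBank,
    width_ref: float = 1.0,
    pixel_size: float = 0.05,
    shape: tuple[int, int] = (96, 96),
) -> GaborBank:
    """Measure the bank's log-scale calibration on a reference bar.

    The argmax log-scale of the bank fixes thickness only up to the
    profile's internal normalization, so the constant
    ``sigma_offset = argmax_sigma(bar of width w) - ln w`` is measured
    once on a horizontal reference bar and stored with the bank;
    downstream code reports physical log-width ``sigma_bank - offset``.
    """
    half_w = 0.5 * (shape[1] - 1) * pixel_size
    spec = CurveSpec(
        waypoints=((-half_w, 0.0), (half_w, 0.0)),
        width_profile=(width_ref, width_ref),
    )
    img, _ = make_curve_image(spec, shape=shape, pixel_size=pixel_size)
    r, c = shape[0] // 2, shape[1] // 2
    fiber = fiber_response(img, bank, r, c)
    si = int(np.argmax(np.abs(fiber).max(axis=0)))
    offset = float(bank.sigma_grid[si]) - math.log(width_ref)
    return bank.with_offset(offset)
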