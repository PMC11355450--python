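"""File formats: images, trajectories, covectors, configurations, lifts.

Images move through PNG (8-bit) or TIFF (16-bit) grayscale, normalized
to [0, 1] on read.  Trajectories are CSV with columns
t, x, y, theta, sigma, h1..h4, H, g1, g2; configuration lists are CSV
with x, y, theta, sigma (theta in radians); covectors are JSON; a
lifted image persists as a dense ``.npy`` next to a JSON sidecar
describing its grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .flow import Covector, ExtremalTrajectory
from .group import GroupElement
from .lifting import GaborBank, ImageGrid, LiftedImage

__all__ = [
    "read_image",
    "write_image",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "configurations_to_csv",
    "configurations_from_csv",
    "covector_to_json",
    "covector_from_json",
    "save_lifted_image",
    "load_lifted_image",
]


def read_image(path: str | Path, pixel_size: float = 1.0,
               origin: tuple[float, float] | None = None) -> ImageGrid:
    """Read a grayscale PNG/TIFF, normalized to [0, 1]."""
    raw = np.asarray(iio.imread(path))
    arr = raw.astype(float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    elif arr.max() > 1.0:
        arr = arr / arr.max()
    return ImageGrid(arr, pixel_size=pixel_size, origin=origin)


def write_image(img: ImageGrid, path: str | Path, bits: int = 8) -> None:
    """Write intensities (clipped to [0, 1]) as 8-bit PNG or 16-bit TIFF."""
    data = np.clip(img.intensities, 0.0, 1.0)
    path = Path(path)
    if bits == 8:
        iio.imwrite(path, (data * 255).round().astype(np.uint8))
    elif bits == 16:
        iio.imwrite(path, (data * 65535).round().astype(np.uint16))
    else:
        raise ValueError("bits must be 8 or 16")


def trajectory_to_csv(traj: ExtremalTrajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def trajectory_from_csv(path: str | Path) -> ExtremalTrajectory:
    df = pd.read_csv(path)
    return ExtremalTrajectory(
        times=df["t"].to_numpy(),
        q=df[["x", "y", "theta", "sigma"]].to_numpy(),
        h=df[["h1", "h2", "h3", "h4"]].to_numpy(),
    )


def configurations_to_csv(configs: list[GroupElement], path: str | Path) -> None:
    pd.DataFrame([q.to_dict() for q in configs]).to_csv(path, index=False)


def configurations_from_csv(path: str | Path) -> list[GroupElement]:
    df = pd.read_csv(path)
    return [GroupElement.from_dict(row) for row in df.to_dict("records")]


def covector_to_json(h: Covector, path: str | Path) -> None:
    Path(path).write_text(json.dumps(h.to_dict(), indent=2))


def covector_from_json(path: str | Path) -> Covector:
    d = json.loads(Path(path).read_text())
    return Covector(d["h1"], d["h2"], d["h3"], d["h4"])


def save_lifted_image(L: LiftedImage, stem: str | Path) -> None:
    """Persist responses to ``<stem>.npy`` plus ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), L.responses)
    sidecar = {
        "theta_grid": L.bank.theta_grid.tolist(),
        "sigma_grid": L.bank.sigma_grid.tolist(),
        "support_radius": L.bank.support_radius,
        "sigma_offset": L.bank.sigma_offset,
        "pixel_size": L.image.pixel_size,
        "origin": list(L.image.origin),
        "shape": list(L.image.shape),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_lifted_image(stem: str | Path, image: ImageGrid | None = None) -> LiftedImage:
    stem = Path(stem)
    responses = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    bank = GaborBank(
        theta_grid=np.array(meta["theta_grid"]),
        sigma_grid=np.array(meta["sigma_grid"]),
        support_radius=meta["support_radius"],
        sigma_offset=meta["sigma_offset"],
    )
    if image is None:
        image = ImageGrid(
            np.zeros(meta["shape"]), pixel_size=meta["pixel_size"],
            origin=tuple(meta["origin"]),
        )
    return LiftedImage(responses, image, bank)
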