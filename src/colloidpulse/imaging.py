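"""Cluster-size statistics from bright-field-style micrographs.

The pipeline mirrors standard aggregate quantification: threshold the
grayscale frame to a binary mask (clusters are darker than background in
bright field), label connected components, discard specks below a minimum
area, and report the count, the mean component area in pixels (the "a.U."
cluster-size statistic) and the mean equivalent-circle diameter in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "GrayImage",
    "ClusterStats",
    "binarize",
    "label_clusters",
    "cluster_stats",
    "timeseries_stats",
    "read_image",
]

DEFAULT_MIN_SIZE = 5  # px; about half a 1-um bead at the default pixel size
DEFAULT_CONNECTIVITY = 8


@dataclass
class GrayImage:
    """A 2-D grayscale frame with physical pixel size and cluster polarity."""

    data: np.ndarray
    pixel_size: float = 1.0  # um per pixel
    polarity: str = "dark"  # clusters "dark" on light background, or "light"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.polarity not in ("dark", "light"):
            raise ValueError("polarity must be 'dark' or 'light'")


@dataclass(frozen=True)
class ClusterStats:
    """Connected-component statistics of one binarised frame.

    ``mean_size_au`` is the mean component area in pixels (the arbitrary-unit
    cluster-size statistic); ``mean_diameter_um`` averages the equivalent
    circle diameter 2*sqrt(area/pi)*pixel_size.  Means are NaN when no
    cluster survives the size filter.
    """

    n_clusters: int
    sizes: np.ndarray
    mean_size_au: float
    mean_diameter_um: float
    total_mask_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "mean_size_au": self.mean_size_au,
            "mean_diameter_um": self.mean_diameter_um,
            "total_mask_fraction": self.total_mask_fraction,
        }


def binarize(img: GrayImage, threshold: Union[float, str] = "otsu") -> np.ndarray:
    """Threshold a frame into a boolean cluster mask.

    With polarity 'dark' the mask is intensity < threshold, else > threshold.
    ``threshold='otsu'`` picks the value automatically; a constant image makes
    Otsu undefined and raises.  The operation is idempotent: re-binarising the
    resulting mask (as a 'light'-polarity {0,1} image with any threshold
    strictly inside (0, 1)) reproduces it exactly.
    """
    data = img.data
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(data) == 0:
            raise ValueError("cannot apply Otsu threshold to a constant image")
        thr = float(threshold_otsu(data))
    else:
        thr = float(threshold)
    return data < thr if img.polarity == "dark" else data > thr


def label_clusters(
    mask: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_size: int = DEFAULT_MIN_SIZE,
) -> np.ndarray:
    """Label connected components, discarding those below ``min_size`` pixels.

    ``connectivity`` is 4 (edge neighbours) or 8 (edges + diagonals).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = sk_label(np.asarray(mask, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    if min_size > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        too_small = counts < min_size
        too_small[0] = False
        labels[too_small[labels]] = 0
        labels = sk_label(labels > 0, connectivity=1 if connectivity == 4 else 2)
    return labels


def cluster_stats(labels: np.ndarray, pixel_size: float = 1.0) -> ClusterStats:
    """Sizes, mean area (a.U.) and mean equivalent diameter of labelled clusters."""
    n = int(labels.max())
    if n == 0:
        return ClusterStats(0, np.array([]), float("nan"), float("nan"), 0.0)
    sizes = np.bincount(labels.ravel())[1:].astype(float)
    diameters = 2.0 * np.sqrt(sizes / np.pi) * pixel_size
    return ClusterStats(
        n_clusters=n,
        sizes=sizes,
        mean_size_au=float(sizes.mean()),
        mean_diameter_um=float(diameters.mean()),
        total_mask_fraction=float(sizes.sum() / labels.size),
    )


def timeseries_stats(
    images: Sequence[GrayImage],
    threshold: Union[float, str] = "otsu",
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """Per-frame cluster statistics of an ordered image series.

    All frames must share one shape; constant (featureless) frames under Otsu
    are reported as zero clusters rather than failing the run.
    """
    shapes = {im.data.shape for im in images}
    if len(shapes) > 1:
        raise ValueError("heterogeneous image shapes in series")
    rows = []
    for i, im in enumerate(images):
        try:
            mask = binarize(im, threshold)
        except ValueError:
            mask = np.zeros(im.data.shape, dtype=bool)
        stats = cluster_stats(label_clusters(mask, connectivity, min_size), im.pixel_size)
        rows.append({"frame": i, **stats.to_dict()})
    return pd.DataFrame(rows)


def read_image(path, pixel_size: float = 1.0, polarity: str = "dark") -> GrayImage:
    """Read a TIFF/PNG grayscale frame from disk."""
    import imageio.v3 as iio

    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3:  # collapse identical RGB channels
        data = data.mean(axis=-1)
    return GrayImage(data=data, pixel_size=pixel_size, polarity=polarity)
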