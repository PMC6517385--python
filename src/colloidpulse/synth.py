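"""Synthetic-data generators with known ground truth.

Two raw-data modalities of the study are emulated so that every pipeline
stage is testable without real recordings:

* intercalator-dye fluorescence time series — a linear signal response on top
  of the template baseline, an optional early "heating dip" (the dye is more
  fluorescent at room temperature, so the signal sags while the chamber warms
  up), partially fluorescent degradation fragments, and Gaussian noise;
* bright-field-like grayscale frames of dispersed singlet colloids and
  planted clusters (discs or lattice-grown aggregates) with exact planted
  cluster statistics.

Every generator is deterministic per seed and returns machine-readable ground
truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .fitting import FluorescenceTrace
from .imaging import ClusterStats, GrayImage
from .kinetics import KineticParams, RnaTrajectory, closed_form_ntp, closed_form_rna

__all__ = [
    "TraceSynthConfig",
    "ImageSynthConfig",
    "synth_trace",
    "synth_cluster_image",
    "synth_pulse_frames",
]


@dataclass
class TraceSynthConfig:
    """Settings of the fluorescence-trace generator.

    ``noise_sd`` is the Gaussian noise level as a fraction of the clean
    signal; ``phi`` is the residual fluorescence of degradation fragments
    relative to intact RNA (small, degraded pieces intercalate less dye).
    """

    params: KineticParams = field(default_factory=KineticParams)
    slope: float = 10.0  # a.U. per nM
    noise_sd: float = 0.0
    dip_amplitude: float = 0.0  # a.U.
    dip_tau: float = 8.0  # min
    phi: float = 0.3
    t_end: float = 240.0
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


def synth_trace(cfg: TraceSynthConfig) -> Tuple[FluorescenceTrace, Dict]:
    """Generate a dye trace plus ground truth.

    signal(t) = slope * (template + rna(t) + phi*fragments(t)) - dip(t) + noise,
    with fragments(t) the cumulative degraded RNA, integral of mu*rna dt.
    Returns the trace and a dict with the generating parameters, the clean
    signal and the clean RNA course.
    """
    p = cfg.params
    t = np.arange(0.0, cfg.t_end + 0.5 * cfg.dt, cfg.dt)
    rna = np.asarray(closed_form_rna(p, t))
    fragments = cumulative_trapezoid(p.degradation * rna, t, initial=0.0)
    clean = cfg.slope * (p.temp + rna + cfg.phi * fragments)
    dip = cfg.dip_amplitude * np.exp(-t / cfg.dip_tau)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(0.0, 1.0, t.size) * cfg.noise_sd * clean
    signal = clean - dip + noise
    trace = FluorescenceTrace(
        times=t,
        signal=signal,
        template_nM=p.temp,
        metadata={"t7": p.t7, "temp": p.temp, "ntp0": p.ntp0, "rnaseh": p.rnaseh},
    )
    truth = {
        "params": p,
        "slope": cfg.slope,
        "rna": rna,
        "ntp": np.asarray(closed_form_ntp(p, t)),
        "fragments": fragments,
        "clean_signal": clean,
        "lumped": {"A": p.production_rate, "lam": p.fuel_decay, "mu": p.degradation},
    }
    return trace, truth


@dataclass
class ImageSynthConfig:
    """Settings of the cluster-micrograph generator (bright-field polarity)."""

    shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.5  # um per px
    cluster_areas: Tuple[int, ...] = (100, 200, 300)  # px per planted cluster
    morphology: str = "disc"  # "disc" | "aggregate"
    singlet_density: float = 0.0  # singlet beads per px
    background_level: float = 200.0
    cluster_level: float = 50.0
    noise_sd: float = 5.0
    margin: int = 4  # empty px kept around planted clusters
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphology not in ("disc", "aggregate"):
            raise ValueError("morphology must be 'disc' or 'aggregate'")
        if self.singlet_density < 0 or self.noise_sd < 0:
            raise ValueError("densities and noise must be >= 0")


def _disc_offsets(area: int) -> np.ndarray:
    """Pixel offsets of a rasterised disc with approximately ``area`` pixels."""
    r = max(np.sqrt(area / np.pi), 0.5)
    # adjust radius so the rasterised pixel count matches the target area
    for radius in np.linspace(0.8 * r, 1.3 * r, 60):
        n = int(radius) + 1
        yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
        inside = yy**2 + xx**2 <= radius**2
        if inside.sum() >= area:
            offs = np.argwhere(inside) - n
            d2 = (offs**2).sum(axis=1)
            return offs[np.argsort(d2, kind="stable")][:area]
    raise RuntimeError("disc rasterisation failed")  # pragma: no cover


def _aggregate_offsets(area: int, rng: np.random.Generator) -> np.ndarray:
    """Eden-like lattice aggregate: grow by attaching pixels to the boundary."""
    cells = {(0, 0)}
    frontier = [(0, 0)]
    while len(cells) < area:
        i = rng.integers(0, len(frontier))
        cy, cx = frontier[i]
        nbrs = [
            (cy + dy, cx + dx)
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if (cy + dy, cx + dx) not in cells
        ]
        if not nbrs:
            frontier.pop(i)
            continue
        new = nbrs[rng.integers(0, len(nbrs))]
        cells.add(new)
        frontier.append(new)
    offs = np.array(sorted(cells))
    return offs - offs.mean(axis=0).round().astype(int)


def synth_cluster_image(cfg: ImageSynthConfig) -> Tuple[GrayImage, ClusterStats, np.ndarray]:
    """Generate one frame with planted clusters and exact ground-truth stats.

    Clusters are placed without overlap (a ``margin``-px moat keeps them
    separate components); isolated single-pixel beads model the dispersed
    singlet background.  Returns the image, the planted ClusterStats and the
    exact planted mask.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    mask = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)  # mask dilated by the moat
    sizes: List[float] = []
    for area in cfg.cluster_areas:
        offs = (
            _disc_offsets(int(area))
            if cfg.morphology == "disc"
            else _aggregate_offsets(int(area), rng)
        )
        placed = False
        for _ in range(cfg.max_retries):
            ext = int(np.abs(offs).max()) + cfg.margin
            if 2 * ext + 1 > min(h, w):
                break
            cy = rng.integers(ext, h - ext)
            cx = rng.integers(ext, w - ext)
            ys, xs = offs[:, 0] + cy, offs[:, 1] + cx
            lo_y, hi_y = ys.min() - cfg.margin, ys.max() + cfg.margin + 1
            lo_x, hi_x = xs.min() - cfg.margin, xs.max() + cfg.margin + 1
            if blocked[lo_y:hi_y, lo_x:hi_x].any():
                continue
            mask[ys, xs] = True
            blocked[lo_y:hi_y, lo_x:hi_x] = True
            sizes.append(float(len(offs)))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a cluster of {area} px after {cfg.max_retries} retries"
            )
    # dispersed singlets: isolated dark pixels, kept off the cluster moats
    n_singlets = rng.poisson(cfg.singlet_density * h * w)
    singlet_mask = np.zeros_like(mask)
    for _ in range(n_singlets):
        y, x = rng.integers(0, h), rng.integers(0, w)
        if not blocked[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2].any():
            singlet_mask[y, x] = True

    img = np.full((h, w), cfg.background_level)
    img[mask | singlet_mask] = cfg.cluster_level
    img += rng.normal(0.0, cfg.noise_sd, (h, w))

    sizes_arr = np.array(sizes)
    if sizes_arr.size:
        diam = 2.0 * np.sqrt(sizes_arr / np.pi) * cfg.pixel_size
        stats = ClusterStats(
            n_clusters=len(sizes),
            sizes=sizes_arr,
            mean_size_au=float(sizes_arr.mean()),
            mean_diameter_um=float(diam.mean()),
            total_mask_fraction=float(sizes_arr.sum() / (h * w)),
        )
    else:
        stats = ClusterStats(0, sizes_arr, float("nan"), float("nan"), 0.0)
    return GrayImage(img, cfg.pixel_size, "dark"), stats, mask


def synth_pulse_frames(
    traj: RnaTrajectory,
    mapping: Callable[[float], float],
    cfg: ImageSynthConfig,
    n_clusters: int = 6,
    singlet_area: int = 1,
) -> Tuple[List[GrayImage], np.ndarray]:
    """One frame per trajectory point with planted mean area mapping(rna(t)).

    ``mapping`` must be monotone with mapping(0) equal to the singlet area;
    mapped areas at or below the singlet area plant no clusters (the frame
    shows only dispersed beads).  Returns the frames and the planted
    mean-area series (the ground truth for end-to-end lifetime recovery).
    """
    frames: List[GrayImage] = []
    truth = np.empty(traj.rna.size)
    for i, r in enumerate(traj.rna):
        area = float(mapping(float(r)))
        truth[i] = area
        if area <= singlet_area:
            areas: Tuple[int, ...] = ()
        else:
            areas = tuple([int(round(area))] * n_clusters)
        frame_cfg = ImageSynthConfig(
            shape=cfg.shape,
            pixel_size=cfg.pixel_size,
            cluster_areas=areas,
            morphology=cfg.morphology,
            singlet_density=cfg.singlet_density,
            background_level=cfg.background_level,
            cluster_level=cfg.cluster_level,
            noise_sd=cfg.noise_sd,
            margin=cfg.margin,
            max_retries=cfg.max_retries,
            seed=cfg.seed + i,
        )
        img, _, _ = synth_cluster_image(frame_cfg)
        frames.append(img)
    return frames, truth
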