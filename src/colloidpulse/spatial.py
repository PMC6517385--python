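"""Lattice simulation of the diffusion-chamber experiment.

RNA linker is produced only inside a reservoir region (immobilised templates),
diffuses into the channel, and is degraded everywhere.  Colloids random-walk
on the same lattice and bind into aggregates where the local linker
concentration exceeds a threshold; they unbind when it falls below a lower
threshold (hysteresis).  A per-colloid "history" variable h accumulates while
bound, in proportion to the local degradation flux (RNaseH only cuts linker
hybridised to the colloidal DNA, leaving blocking fragments on the surface),
and raises both thresholds by a factor (1 + beta*h).

With beta = 0, the concentration field decreases monotonically away from the
source at all times, so during the fuel-limited decay the far positions fall
below the unbinding threshold first: the disintegration front travels
backward, toward the source.  With beta > 0 the near colloids — exposed to
the largest degradation flux for the longest time — lose affinity fastest and
unbind first: the disintegration front travels forward, away from the source,
as observed experimentally.

Numerics: diffusion is applied as a Gaussian blur of the field with
sigma = sqrt(2*D*dt)/dx cells per step (the exact propagator of the heat
equation), with reflecting walls for the RNA; colloids wrap periodically
along the channel axis and reflect at the side walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

#: documented history gain at which the disintegration front runs forward
#: (away from the source) in the default chamber; beta = 0 gives the naive
#: backward front
DEFAULT_HISTORY_BETA = 0.02

__all__ = [
    "DEFAULT_HISTORY_BETA",
    "SpatialConfig",
    "SpatialState",
    "SpaceTimeRecord",
    "FrontReport",
    "default_chamber_config",
    "initial_state",
    "diffuse",
    "react",
    "update_colloids",
    "run",
    "front_direction",
]


@dataclass
class SpatialConfig:
    """Geometry, transport, kinetic and binding parameters of the chamber run.

    Distances in um, time in min, concentrations in nM.  ``reservoir_cols``
    marks the leftmost columns where templates are immobilised (production).
    Stability guards: the per-step blur must span at least 0.3 cells (unless
    D == 0) and mu*dt must stay below 0.2.
    """

    nx: int = 200
    ny: int = 20
    dx: float = 10.0  # um per cell
    dt: float = 0.5  # min per step
    D: float = 4000.0  # um^2/min
    reservoir_cols: int = 10
    prod_rate: float = 150.0  # nM/min in reservoir cells
    mu: float = 0.015  # 1/min, global degradation
    lam: float = 0.02  # 1/min, fuel depletion of production (0 = unlimited)
    theta_on: float = 50.0  # nM binding threshold
    theta_off: float = 30.0  # nM unbinding threshold
    beta: float = 0.0  # history gain (dimensionless)
    n_colloids: int = 2000
    move_prob: float = 1.0
    t_end: float = 300.0  # min
    record_every: int = 10  # steps between records
    seed: int = 0
    snapshots: bool = False

    def __post_init__(self) -> None:
        if self.theta_off > self.theta_on:
            raise ValueError("theta_off must be <= theta_on")
        if self.mu * self.dt >= 0.2:
            raise ValueError("stability guard: mu*dt must be < 0.2")
        if self.D > 0 and self.sigma < 0.3:
            raise ValueError(
                "stability guard: per-step blur sigma = sqrt(2*D*dt)/dx must be >= 0.3 cells"
            )
        if not (0 <= self.reservoir_cols <= self.nx):
            raise ValueError("reservoir_cols out of range")

    @property
    def sigma(self) -> float:
        """Per-step Gaussian blur width in cells."""
        return float(np.sqrt(2.0 * self.D * self.dt) / self.dx)

    @property
    def reservoir_mask(self) -> np.ndarray:
        m = np.zeros((self.ny, self.nx), dtype=bool)
        m[:, : self.reservoir_cols] = True
        return m

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


def default_chamber_config(**overrides) -> SpatialConfig:
    """The default transient-pulse chamber (fuel-limited local production)."""
    return SpatialConfig(**overrides)


@dataclass
class SpatialState:
    """RNA field plus colloid ensemble (positions, bound flags, history h)."""

    rna: np.ndarray  # (ny, nx), nM
    rows: np.ndarray  # (n,) int
    cols: np.ndarray  # (n,) int
    bound: np.ndarray  # (n,) bool
    h: np.ndarray  # (n,) float, accumulated degradation exposure
    t: float = 0.0


def initial_state(config: SpatialConfig, rng: np.random.Generator) -> SpatialState:
    """Uniform random colloid placement, zero RNA everywhere."""
    n = config.n_colloids
    return SpatialState(
        rna=np.zeros((config.ny, config.nx)),
        rows=rng.integers(0, config.ny, n),
        cols=rng.integers(0, config.nx, n),
        bound=np.zeros(n, dtype=bool),
        h=np.zeros(n),
        t=0.0,
    )


def diffuse(state: SpatialState, config: SpatialConfig) -> SpatialState:
    """One diffusion step: Gaussian blur with reflecting (no-flux) walls.

    A symmetric kernel with 'reflect' boundary conserves total mass exactly.
    """
    if config.D > 0:
        state.rna = gaussian_filter(state.rna, sigma=config.sigma, mode="reflect")
    return state


def react(state: SpatialState, config: SpatialConfig) -> SpatialState:
    """One reaction step: local (fuel-limited) production, global degradation."""
    fuel_factor = np.exp(-config.lam * state.t) if config.lam > 0 else 1.0
    if config.reservoir_cols > 0 and config.prod_rate > 0:
        state.rna[:, : config.reservoir_cols] += config.prod_rate * config.dt * fuel_factor
    if config.mu > 0:
        state.rna *= np.exp(-config.mu * config.dt)
    return state


def _neighbour_counts(state: SpatialState, config: SpatialConfig) -> np.ndarray:
    """Colloids within the 8-neighbourhood (or sharing a cell), per colloid."""
    occ = np.zeros((config.ny, config.nx))
    np.add.at(occ, (state.rows, state.cols), 1.0)
    # 3x3 box sum: periodic along x (channel), clipped (wall) along y
    acc = occ + np.roll(occ, 1, axis=1) + np.roll(occ, -1, axis=1)
    total = acc.copy()
    total[1:, :] += acc[:-1, :]
    total[:-1, :] += acc[1:, :]
    return total[state.rows, state.cols] - 1.0  # exclude self


def update_colloids(
    state: SpatialState, config: SpatialConfig, rng: np.random.Generator
) -> SpatialState:
    """Binding/unbinding with history-raised thresholds, then random-walk moves.

    Synchronous update: contacts are evaluated against the positions at the
    start of the step.  Bound colloids are frozen (aggregates are immobile);
    unbound ones take one 4-neighbour step with probability ``move_prob``,
    wrapping along the channel and reflecting at the side walls.
    """
    local = state.rna[state.rows, state.cols]
    factor = 1.0 + config.beta * state.h

    # exposure accrues for colloids bound at step start: RNaseH degrades
    # colloid-hybridised linker, depositing blocking fragments
    state.h[state.bound] += config.mu * local[state.bound] * config.dt

    # hysteresis thresholds, scaled by accumulated history
    unbind = state.bound & (local < config.theta_off * factor)
    contact = _neighbour_counts(state, config) >= 1.0
    bind = (~state.bound) & (local >= config.theta_on * factor) & contact
    state.bound = (state.bound & ~unbind) | bind

    free = ~state.bound
    n_free = int(free.sum())
    if n_free and config.move_prob > 0:
        moving = rng.random(n_free) < config.move_prob
        steps = rng.integers(0, 4, n_free)
        drow = np.where(steps == 0, -1, np.where(steps == 1, 1, 0)) * moving
        dcol = np.where(steps == 2, -1, np.where(steps == 3, 1, 0)) * moving
        rows = state.rows[free] + drow
        # reflect at the side walls
        rows = np.where(rows < 0, 1, rows)
        rows = np.where(rows >= config.ny, config.ny - 2, rows)
        state.rows[free] = rows
        state.cols[free] = (state.cols[free] + dcol) % config.nx
    return state


@dataclass
class SpaceTimeRecord:
    """Recorded per-column aggregation over time, plus optional field snapshots."""

    times: np.ndarray  # (T,)
    bound_counts: np.ndarray  # (T, nx)
    colloid_counts: np.ndarray  # (T, nx)
    config: SpatialConfig
    rna_snapshots: Optional[np.ndarray] = None  # (T, ny, nx)

    @property
    def agg_fraction(self) -> np.ndarray:
        """Bound fraction per column (0 where a column holds no colloids)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.bound_counts / self.colloid_counts
        return np.nan_to_num(f)

    def to_frame(self) -> pd.DataFrame:
        T, nx = self.bound_counts.shape
        t = np.repeat(self.times, nx)
        col = np.tile(np.arange(nx), T)
        return pd.DataFrame(
            {
                "t_min": t,
                "column": col,
                "aggregated_fraction": self.agg_fraction.ravel(),
                "n_colloids": self.colloid_counts.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class FrontReport:
    """Onset/offset of aggregation at probe columns and the front direction."""

    probe_columns: Tuple[int, ...]
    onsets: Tuple[float, ...]
    offsets: Tuple[float, ...]
    direction: str  # "forward" | "backward" | "simultaneous"

    def to_dict(self) -> dict:
        return {
            "probe_columns": list(self.probe_columns),
            "onsets": list(self.onsets),
            "offsets": list(self.offsets),
            "direction": self.direction,
        }


def run(config: SpatialConfig) -> SpaceTimeRecord:
    """Full chamber simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    state = initial_state(config, rng)
    times: List[float] = []
    bound_rows: List[np.ndarray] = []
    count_rows: List[np.ndarray] = []
    snaps: List[np.ndarray] = []

    def record() -> None:
        times.append(state.t)
        bc = np.zeros(config.nx)
        cc = np.zeros(config.nx)
        np.add.at(cc, state.cols, 1.0)
        np.add.at(bc, state.cols[state.bound], 1.0)
        bound_rows.append(bc)
        count_rows.append(cc)
        if config.snapshots:
            snaps.append(state.rna.copy())

    record()
    for step in range(config.n_steps):
        diffuse(state, config)
        react(state, config)
        update_colloids(state, config, rng)
        state.t = (step + 1) * config.dt
        if (step + 1) % config.record_every == 0:
            record()
    return SpaceTimeRecord(
        times=np.array(times),
        bound_counts=np.array(bound_rows),
        colloid_counts=np.array(count_rows),
        config=config,
        rna_snapshots=np.array(snaps) if snaps else None,
    )


def probe_series(
    record: SpaceTimeRecord, column: int, half_width: int = 5, smooth: int = 3
) -> np.ndarray:
    """Bound fraction around a probe column, lightly smoothed in time."""
    lo = max(column - half_width, 0)
    hi = min(column + half_width + 1, record.bound_counts.shape[1])
    bound = record.bound_counts[:, lo:hi].sum(axis=1)
    total = record.colloid_counts[:, lo:hi].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, bound / total, 0.0)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        frac = np.convolve(frac, kernel, mode="same")
    return frac


def front_direction(
    record: SpaceTimeRecord,
    probe_columns: Sequence[int],
    frac_threshold: float = 0.25,
    half_width: int = 5,
) -> FrontReport:
    """Classify the disintegration front from offset times at probe columns.

    Probes are ordered by distance from the source (left edge).  Offsets
    increasing with distance mean the disintegration travels forward, away
    from the source; decreasing offsets mean backward; differences within one
    recording interval are called simultaneous.
    """
    if len(probe_columns) < 2:
        raise ValueError("need at least 2 probe columns")
    cols = sorted(int(c) for c in probe_columns)
    onsets, offsets = [], []
    for c in cols:
        frac = probe_series(record, c, half_width=half_width)
        above = frac >= frac_threshold
        if not above.any():
            raise ValueError(f"probe column {c} never aggregates above {frac_threshold}")
        onsets.append(float(record.times[np.argmax(above)]))
        offsets.append(float(record.times[len(above) - 1 - np.argmax(above[::-1])]))
    cadence = float(np.median(np.diff(record.times)))
    delta = offsets[-1] - offsets[0]
    if delta > cadence:
        direction = "forward"
    elif delta < -cadence:
        direction = "backward"
    else:
        direction = "simultaneous"
    return FrontReport(tuple(cols), tuple(onsets), tuple(offsets), direction)
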