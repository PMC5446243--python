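"""Localization/trajectory tables and displacement extraction.

Trajectories are 2D localization time series (frame index, x, y in μm) as
produced by any single-molecule tracking algorithm and exported as a plain
long-format table with columns ``track_id, frame, x_um, y_um``. Tracking is
assumed to tolerate short detection gaps (dye blinking / axial excursions);
the gap tolerance in frames is carried as ``max_gap`` and enforced on input.

Displacements ("jumps") for kinetic modeling are pooled per time lag
k·Δτ, k = 1..n_lags, using only the first 8 localizations of each
trajectory: long trajectories are strongly enriched for chromatin-bound
molecules, so truncating every track to its first seven jumps limits that
bias at the cost of a small, quantifiable underestimate of the bound
fraction (see :mod:`smtk.simulate` for the machinery to quantify it).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "JumpData",
    "read_trajectories",
    "write_trajectories",
    "extract_jumps",
    "drift_correct",
]

#: Default number of lag multiples used for jump-distribution fitting.
DEFAULT_N_LAGS = 7

#: Localizations 1..8 of each track contribute (seven jumps).
MAX_LOCALIZATIONS = 8


@dataclass
class Trajectory:
    """One tracked molecule: ordered localizations at strictly increasing frames."""

    id: int
    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray  # μm
    y: np.ndarray  # μm
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.id}: non-finite coordinates")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames_spanned(self) -> int:
        """Number of observation frames the track spans, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing acquisition settings.

    Parameters
    ----------
    trajectories
        The tracks, sorted by id on construction.
    frame_interval
        Time between frames Δτ, s (fast modality default ≈ 4.4477 ms).
    mode
        ``"fast"`` (stroboscopic, ~225 Hz) or ``"slow"`` (motion-blur,
        0.3–0.8 s exposures used for residence-time measurement).
    exposure
        Camera exposure per frame, s. For slow tracking this equals the
        frame interval.
    sigma
        2D localization error per axis, μm (≈ 0.035 under stroboscopic
        conditions).
    max_gap
        Maximum tolerated detection gap, frames.
    """

    trajectories: list[Trajectory] = field(default_factory=list)
    frame_interval: float = 0.0044477
    mode: str = "fast"
    exposure: float | None = None
    sigma: float = 0.035
    max_gap: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for t in self.trajectories:
            if not np.isclose(t.frame_interval, self.frame_interval):
                raise ValueError("all trajectories must share frame_interval")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def mean_track_length(self) -> float:
        """Mean number of localizations per trajectory."""
        if not self.trajectories:
            return float("nan")
        return float(np.mean([len(t) for t in self.trajectories]))


@dataclass
class JumpData:
    """Radial displacements pooled per lag multiple of the frame interval."""

    frame_interval: float
    displacements: dict[int, np.ndarray]  # lag multiple -> r (μm), r >= 0

    def __post_init__(self) -> None:
        self.displacements = {
            int(k): np.asarray(v, dtype=float) for k, v in self.displacements.items()
        }
        for k, v in self.displacements.items():
            if k < 1:
                raise ValueError("lag multiples must be >= 1")
            if np.any(v < 0):
                raise ValueError("jump lengths must be non-negative")

    @property
    def counts(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.displacements.items()}

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.displacements.values())

    def lags(self) -> list[int]:
        return sorted(k for k, v in self.displacements.items() if len(v))


def _split_on_gaps(frames: np.ndarray, max_gap: int) -> list[slice]:
    """Slices of runs where consecutive frame differences are <= max_gap+1."""
    if len(frames) == 0:
        return []
    breaks = np.flatnonzero(np.diff(frames) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [len(frames)]))
    return [slice(a, b) for a, b in zip(starts, stops)]


def read_trajectories(
    path,
    dialect: str = "long_table",
    frame_interval: float = 0.0044477,
    mode: str = "fast",
    exposure: float | None = None,
    sigma: float = 0.035,
    max_gap: int = 1,
) -> TrajectorySet:
    """Read a trajectory table from a delimited text file.

    ``long_table`` is the interchange format: a header plus columns
    ``track_id, frame, x_um, y_um`` (comma- or tab-delimited). ``per_track``
    accepts the same columns grouped arbitrarily; rows are sorted by
    (track_id, frame) before validation.

    Tracks whose frame sequence contains a gap larger than ``max_gap`` frames
    are split into separate trajectories (suffix ids are minted past the
    maximum input id); non-monotone frames within a track raise.
    """
    if dialect not in ("long_table", "per_track"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing keeps the writer's repr-formatted floats bit-exact
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse trajectory table {path}: {exc}") from exc
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)} in {path}")
    bad = df[["x_um", "y_um"]].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based line numbering
        raise ValueError(f"malformed row at line {int(bad.idxmax()) + 2} of {path}")
    if dialect == "per_track":
        df = df.sort_values(["track_id", "frame"], kind="stable")

    trajectories: list[Trajectory] = []
    next_id = int(df["track_id"].max()) + 1 if len(df) else 0
    for tid, g in df.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid}: frames not strictly increasing")
        x = g["x_um"].to_numpy(dtype=float)
        y = g["y_um"].to_numpy(dtype=float)
        pieces = _split_on_gaps(frames, max_gap)
        for i, sl in enumerate(pieces):
            new_id = int(tid) if i == 0 else next_id
            if i > 0:
                next_id += 1
            trajectories.append(
                Trajectory(new_id, frames[sl], x[sl], y[sl], frame_interval)
            )
    trajectories.sort(key=lambda t: t.id)
    return TrajectorySet(
        trajectories,
        frame_interval=frame_interval,
        mode=mode,
        exposure=exposure,
        sigma=sigma,
        max_gap=max_gap,
    )


def write_trajectories(ts: TrajectorySet, path) -> None:
    """Write the long-table interchange format (lossless for coordinates)."""
    rows = []
    for t in ts:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((t.id, int(f), x, y))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    # repr round-trips float64 exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def extract_jumps(
    ts: TrajectorySet,
    n_lags: int = DEFAULT_N_LAGS,
    max_localizations: int | None = MAX_LOCALIZATIONS,
) -> JumpData:
    """Pool radial displacements per lag multiple of Δτ.

    Only the first ``max_localizations`` (default 8, i.e. seven jumps) of each
    trajectory contribute, the anti-bias truncation discussed in the module
    docstring; pass ``None`` to use entire trajectories. A displacement
    between localizations at frames f_i < f_j contributes to lag f_j − f_i,
    so jumps spanning a tolerated detection gap land in the lag equal to the
    true time difference.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if len(ts) == 0:
        raise ValueError("empty TrajectorySet")
    pools: dict[int, list[np.ndarray]] = {k: [] for k in range(1, n_lags + 1)}
    for t in ts:
        m = len(t) if max_localizations is None else min(max_localizations, len(t))
        if m < 2:
            continue
        frames = t.frames[:m]
        x, y = t.x[:m], t.y[:m]
        for i in range(m - 1):
            for j in range(i + 1, m):
                lag = int(frames[j] - frames[i])
                if lag > n_lags:
                    break
                r = np.hypot(x[j] - x[i], y[j] - y[i])
                pools[lag].append(r)
    return JumpData(
        frame_interval=ts.frame_interval,
        displacements={k: np.asarray(v, dtype=float) for k, v in pools.items()},
    )


def drift_correct(ts: TrajectorySet, bin_frames: int) -> TrajectorySet:
    """Subtract sample drift estimated from the mean displacement of
    persisting particles, binned over ``bin_frames`` frames to average out
    localization noise.

    Frame-to-frame drift is the mean displacement of all particles localized
    in both of two consecutive frames; binned estimates are averaged, bins
    with no persisting particles are linearly interpolated from neighbors
    (with a warning), and the cumulative drift is subtracted from every
    localization.
    """
    import warnings

    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    if len(ts) == 0:
        raise ValueError("empty TrajectorySet")
    max_frame = max(int(t.frames[-1]) for t in ts)
    # per-frame sum of displacements of persisting particles
    sum_dx = np.zeros(max_frame + 1)
    sum_dy = np.zeros(max_frame + 1)
    n_pairs = np.zeros(max_frame + 1)
    for t in ts:
        df = np.diff(t.frames)
        ok = df == 1  # only strictly consecutive detections estimate drift
        idx = t.frames[1:][ok]
        np.add.at(sum_dx, idx, np.diff(t.x)[ok])
        np.add.at(sum_dy, idx, np.diff(t.y)[ok])
        np.add.at(n_pairs, idx, 1)

    n_bins = int(np.ceil((max_frame + 1) / bin_frames))
    rate_x = np.full(n_bins, np.nan)
    rate_y = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sl = slice(b * bin_frames, (b + 1) * bin_frames)
        n = n_pairs[sl].sum()
        if n > 0:
            rate_x[b] = sum_dx[sl].sum() / n
            rate_y[b] = sum_dy[sl].sum() / n
    if np.isnan(rate_x).any():
        warnings.warn("bins with no persisting particles; drift interpolated")
        for rate in (rate_x, rate_y):
            nans = np.isnan(rate)
            if nans.all():
                raise ValueError("no persisting particles in any bin")
            rate[nans] = np.interp(
                np.flatnonzero(nans), np.flatnonzero(~nans), rate[~nans]
            )

    per_frame_x = np.repeat(rate_x, bin_frames)[: max_frame + 1]
    per_frame_y = np.repeat(rate_y, bin_frames)[: max_frame + 1]
    per_frame_x[0] = per_frame_y[0] = 0.0  # no drift before the first frame
    cum_x = np.cumsum(per_frame_x)
    cum_y = np.cumsum(per_frame_y)

    corrected = [
        Trajectory(t.id, t.frames, t.x - cum_x[t.frames], t.y - cum_y[t.frames], t.frame_interval)
        for t in ts
    ]
    return TrajectorySet(
        corrected,
        frame_interval=ts.frame_interval,
        mode=ts.mode,
        exposure=ts.exposure,
        sigma=ts.sigma,
        max_gap=ts.max_gap,
    )
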