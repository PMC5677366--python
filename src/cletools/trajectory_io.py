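"""Trajectory tables: the CSV dialect, validation and motility pre-filtering.

A trajectory is one cell's uniformly sampled 2D track. On disk a cohort is a
single CSV with columns ``cell_id,frame,time_s,x_um,y_um`` (UTF-8, comma
separator, ``.`` decimal, header mandatory). Floats are written with 6
significant digits so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParameterError

#: Column order of the trajectory CSV dialect.
COLUMNS = ["cell_id", "frame", "time_s", "x_um", "y_um"]

#: Tolerance (s) for uniform frame spacing.
DT_TOL = 1e-6

#: Significant digits used when formatting floats on write.
FLOAT_DIGITS = 6


@dataclass
class Trajectory:
    """One cell's track: times (s) and positions (µm), uniformly sampled.

    Attributes
    ----------
    cell_id :
        Identifier, unique within a cohort.
    times :
        Strictly increasing sample times in seconds, constant spacing ``dt``.
    xy :
        ``(n, 2)`` array of positions in µm, same length as ``times``.
    frames :
        Integer frame indices; consecutive within the cell.
    """

    cell_id: str
    times: np.ndarray
    xy: np.ndarray
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ParameterError(
                f"trajectory {self.cell_id!r} needs >= 2 samples"
            )
        if self.xy.shape != (self.times.size, 2):
            raise ParameterError(
                f"trajectory {self.cell_id!r}: positions shape "
                f"{self.xy.shape} does not match {self.times.size} times"
            )
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ParameterError(f"trajectory {self.cell_id!r}: times not increasing")
        if np.ptp(steps) > DT_TOL:
            raise DataError(
                f"trajectory {self.cell_id!r}: non-uniform frame interval "
                f"(spread {np.ptp(steps):.3g} s exceeds {DT_TOL} s)"
            )
        if self.frames is None:
            self.frames = np.arange(self.times.size)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
            if np.any(np.diff(self.frames) != 1):
                raise DataError(
                    f"trajectory {self.cell_id!r}: frames not consecutive"
                )

    @property
    def dt(self) -> float:
        """Frame interval in seconds (mean of the uniform spacing)."""
        return float(np.mean(np.diff(self.times)))

    @property
    def duration(self) -> float:
        """Elapsed time t_last - t_first in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def mean_frame_speed(self) -> float:
        """Mean per-step speed |Δr|/dt in µm/s, reversals included."""
        disp = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        return float(np.mean(disp) / self.dt)


@dataclass
class FilterConfig:
    """Pre-analysis trajectory filter.

    ``min_duration`` implements the rule that only cells tracked longer than
    10 s enter reversal analysis; ``min_mean_speed`` operationalizes
    "motile" as a mean frame speed of at least 10 µm/s (the source studies
    leave the motility cutoff implicit, so it is exposed here).
    """

    min_duration: float = 10.0
    min_mean_speed: float = 10.0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.min_duration < 0 or self.min_mean_speed < 0:
            raise ParameterError("filter thresholds must be >= 0")


@dataclass
class FilterReport:
    """Bookkeeping from :func:`filter_trajectories`."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_duration: int = 0
    n_dropped_speed: int = 0


def _format_float(x: float) -> str:
    return f"{x:.{FLOAT_DIGITS}g}"


def write_trajectories(trajs: list[Trajectory], path: str | os.PathLike) -> None:
    """Write a cohort to the trajectory CSV dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for traj in trajs:
            for f, t, (x, y) in zip(traj.frames, traj.times, traj.xy):
                fh.write(
                    f"{traj.cell_id},{int(f)},{_format_float(t)},"
                    f"{_format_float(x)},{_format_float(y)}\n"
                )


def read_trajectories(path: str | os.PathLike | io.TextIOBase) -> list[Trajectory]:
    """Read a cohort CSV, one :class:`Trajectory` per ``cell_id``.

    Samples are sorted by frame within each cell; the frame interval is
    validated as uniform to :data:`DT_TOL`. Cells appear in file order.

    Raises
    ------
    FormatError
        Missing columns or empty file.
    DataError
        Frame gaps, duplicate frames, or non-uniform sampling, with the
        offending ``cell_id`` named.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty trajectory file") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory file missing columns: {missing}")
    if df.empty:
        raise FormatError("trajectory file has a header but no rows")

    trajs: list[Trajectory] = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) == 0):
            raise DataError(f"cell {cell_id!r}: duplicate frames")
        if np.any(np.diff(frames) != 1):
            raise DataError(f"cell {cell_id!r}: gap in frame numbering")
        try:
            trajs.append(
                Trajectory(
                    cell_id=str(cell_id),
                    times=grp["time_s"].to_numpy(dtype=float),
                    xy=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                    frames=frames,
                )
            )
        except DataError as exc:
            raise DataError(f"cell {cell_id!r}: {exc}") from exc
    return trajs


def filter_trajectories(
    trajs: list[Trajectory],
    cfg: FilterConfig | None = None,
) -> tuple[list[Trajectory], FilterReport]:
    """Keep motile trajectories long enough for reversal analysis.

    A trajectory is kept when its duration exceeds ``cfg.min_duration``
    (strictly, unless ``cfg.strict`` is False, then >=) AND its mean frame
    speed is at least ``cfg.min_mean_speed``. Order is preserved.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(trajs))
    kept: list[Trajectory] = []
    for traj in trajs:
        long_enough = (
            traj.duration > cfg.min_duration
            if cfg.strict
            else traj.duration >= cfg.min_duration
        )
        if not long_enough:
            report.n_dropped_duration += 1
            continue
        if traj.mean_frame_speed() < cfg.min_mean_speed:
            report.n_dropped_speed += 1
            continue
        kept.append(traj)
    report.n_kept = len(kept)
    return kept, report
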