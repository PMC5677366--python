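"""Turn-angle kinematics and angular-acceleration reversal detection.

The detector reproduces the published single-cell criterion: with velocity
vectors v_i = (r_{i+1} - r_i)/dt, θ_i the signed angle between v_i and
v_{i+1}, and the angular acceleration Δθ_i = θ_{i+1} - θ_i, a reversal event
is called wherever the angular acceleration changes sign over two consecutive
frames, Δθ_i · Δθ_{i+1} < 0, with both magnitudes above 45°. A single-frame
heading change of magnitude φ produces the Δθ pair (+φ, -φ) (or its mirror),
so both 180° reversals and ~90° flicks above threshold trigger; symmetric
two-frame reversals (90° + 90°) produce a zero product and are, by design of
the printed criterion, invisible.

Per-cell summaries are the two quantities plotted in cohort histograms:
reversal frequency (events per second of track) and mean run speed (mean step
speed excluding the two velocity steps that form each event's large turn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError, TooShortError
from .trajectory_io import Trajectory

__all__ = [
    "DetectorConfig",
    "Kinematics",
    "ReversalEvent",
    "CellSummary",
    "CohortDistribution",
    "compute_kinematics",
    "detect_reversals",
    "summarize_cell",
    "analyze_trajectory",
    "summarize_cohort",
    "compare_cohorts",
    "DEFAULT_FREQ_EDGES",
    "DEFAULT_SPEED_EDGES",
]

#: Default histogram binning (the published figures do not state theirs).
DEFAULT_FREQ_EDGES = np.arange(0.0, 1.0 + 1e-9, 0.05)
DEFAULT_SPEED_EDGES = np.arange(0.0, 80.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class DetectorConfig:
    """Detection thresholds.

    ``angle_threshold`` is the published 45° magnitude cut (strict ``>``).
    ``suppression_window`` merges a second trigger whose large-turn frame lies
    within this many frames of the previous event (reversals occupy under two
    frames, so overlapping triggers are one physical event).
    ``min_step_speed`` marks headings built from near-stationary steps as
    undefined rather than letting them produce arbitrary angles.
    """

    angle_threshold: float = 45.0
    suppression_window: int = 2
    min_step_speed: float = 1.0

    def __post_init__(self) -> None:
        if self.angle_threshold <= 0:
            raise ParameterError("angle_threshold must be > 0")
        if self.suppression_window < 0:
            raise ParameterError("suppression_window must be >= 0")


@dataclass
class Kinematics:
    """Velocity-derived per-frame quantities of one trajectory.

    ``speed[i] = |v_i|`` for i = 0..N-2; ``theta[i]`` is the signed turn (deg,
    counter-clockwise positive, range (-180, +180], exact ±180 mapped to
    +180) between v_i and v_{i+1}; ``dtheta[i] = theta[i+1] - theta[i]``.
    ``theta_defined[i]`` is False when either contributing step is slower
    than the detector's ``min_step_speed``.
    """

    dt: float
    speed: np.ndarray
    theta: np.ndarray
    dtheta: np.ndarray
    theta_defined: np.ndarray

    @property
    def dtheta_defined(self) -> np.ndarray:
        return self.theta_defined[:-1] & self.theta_defined[1:]


@dataclass(frozen=True)
class ReversalEvent:
    """One detected directional change.

    ``index`` is i of the triggering pair (Δθ_i, Δθ_{i+1}); ``turn_frame`` the
    index of the large turn θ_{i+1} (the angle between v_{i+1} and v_{i+2});
    ``magnitudes`` the pair (|Δθ_i|, |Δθ_{i+1}|) in degrees.
    """

    index: int
    turn_frame: int
    magnitudes: tuple[float, float]


@dataclass
class CellSummary:
    """Per-cell reversal statistics."""

    cell_id: str
    duration: float
    n_reversals: int
    reversal_frequency: float
    mean_run_speed: float
    n_excluded_steps: int
    run_speed_defined: bool = True


@dataclass
class CohortDistribution:
    """Fraction-of-cells histogram of one per-cell variable."""

    variable: str
    bin_edges: np.ndarray
    fraction_of_cells: np.ndarray
    n_cells: int
    n_underflow: int
    n_overflow: int
    mean: float
    median: float


def _signed_angles_deg(v: np.ndarray) -> np.ndarray:
    """Signed angle (deg) between consecutive 2D vectors, CCW positive.

    Exact antiparallel pairs map to +180 (convention; detection is
    sign-convention independent).
    """
    a, b = v[:-1], v[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    theta = np.degrees(np.arctan2(cross, dot))
    theta[theta <= -180.0] = 180.0  # atan2(-0.0, -x) returns -pi
    return theta


def compute_kinematics(traj: Trajectory, cfg: DetectorConfig | None = None) -> Kinematics:
    """Velocities, signed turn angles and angular accelerations.

    Requires at least 5 samples (the minimum yielding one Δθ pair).
    """
    cfg = cfg or DetectorConfig()
    if traj.n_samples < 5:
        raise TooShortError(
            f"trajectory {traj.cell_id!r} has {traj.n_samples} samples; "
            "kinematics needs >= 5"
        )
    dt = traj.dt
    v = np.diff(traj.xy, axis=0) / dt
    speed = np.linalg.norm(v, axis=1)
    theta = _signed_angles_deg(v)
    theta_defined = (speed[:-1] >= cfg.min_step_speed) & (speed[1:] >= cfg.min_step_speed)
    dtheta = np.diff(theta)
    return Kinematics(dt=dt, speed=speed, theta=theta, dtheta=dtheta, theta_defined=theta_defined)


def detect_reversals(kin: Kinematics, cfg: DetectorConfig | None = None) -> list[ReversalEvent]:
    """Apply the sign-change / 45° angular-acceleration criterion.

    Scans trigger indices in increasing order; a trigger whose large-turn
    frame falls within ``cfg.suppression_window`` frames of the previous
    event's is merged into it (first trigger kept). Ties (|Δθ| equal to the
    threshold, or a zero product) are non-events.
    """
    cfg = cfg or DetectorConfig()
    d = kin.dtheta
    ok = kin.dtheta_defined
    events: list[ReversalEvent] = []
    last_turn_frame = None
    for i in range(len(d) - 1):
        if not (ok[i] and ok[i + 1]):
            continue
        if d[i] * d[i + 1] < 0 and abs(d[i]) > cfg.angle_threshold and abs(d[i + 1]) > cfg.angle_threshold:
            turn_frame = i + 1
            if last_turn_frame is not None and turn_frame - last_turn_frame <= cfg.suppression_window:
                continue
            events.append(ReversalEvent(index=i, turn_frame=turn_frame, magnitudes=(abs(d[i]), abs(d[i + 1]))))
            last_turn_frame = turn_frame
    return events


def summarize_cell(
    traj: Trajectory,
    events: list[ReversalEvent],
    kin: Kinematics,
) -> CellSummary:
    """Reversal frequency and mean run speed for one cell.

    The frequency denominator is the full track duration. Run speed averages
    |v_j| over steps outside every event's exclusion window — the two
    velocity steps v_{i+1}, v_{i+2} flanking the large turn — so that the
    transient reversal frames do not bias the swimming speed. If every step
    is excluded the run speed is flagged undefined (NaN).
    """
    include = np.ones(len(kin.speed), dtype=bool)
    for ev in events:
        include[ev.index + 1 : ev.index + 3] = False
    n_excluded = int(np.sum(~include))
    if include.any():
        mean_run_speed = float(np.mean(kin.speed[include]))
        defined = True
    else:
        mean_run_speed = float("nan")
        defined = False
    duration = traj.duration
    return CellSummary(
        cell_id=traj.cell_id,
        duration=duration,
        n_reversals=len(events),
        reversal_frequency=len(events) / duration,
        mean_run_speed=mean_run_speed,
        n_excluded_steps=n_excluded,
        run_speed_defined=defined,
    )


def analyze_trajectory(
    traj: Trajectory, cfg: DetectorConfig | None = None
) -> tuple[CellSummary, list[ReversalEvent]]:
    """Convenience wrapper: kinematics → detection → summary."""
    cfg = cfg or DetectorConfig()
    kin = compute_kinematics(traj, cfg)
    events = detect_reversals(kin, cfg)
    return summarize_cell(traj, events, kin), events


def summarize_cohort(
    summaries: list[CellSummary],
    variable: str,
    bin_edges: np.ndarray | None = None,
) -> CohortDistribution:
    """Fraction-of-cells histogram of a per-cell variable.

    Bins are left-closed right-open, last bin closed (numpy convention).
    Cells outside the bin range are counted in under/overflow and included in
    the normalization, so reported fractions plus overflow fractions sum to 1.
    """
    if not summaries:
        raise ParameterError("need >= 1 cell summary")
    if variable not in ("reversal_frequency", "mean_run_speed"):
        raise ParameterError(f"unknown variable {variable!r}")
    if bin_edges is None:
        bin_edges = DEFAULT_FREQ_EDGES if variable == "reversal_frequency" else DEFAULT_SPEED_EDGES
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ParameterError("bin_edges must be monotone increasing, length >= 2")
    values = np.array([getattr(s, variable) for s in summaries], dtype=float)
    counts, _ = np.histogram(values, bins=bin_edges)
    n_under = int(np.sum(values < bin_edges[0]))
    n_over = int(np.sum(values > bin_edges[-1]))
    return CohortDistribution(
        variable=variable,
        bin_edges=bin_edges,
        fraction_of_cells=counts / len(values),
        n_cells=len(values),
        n_underflow=n_under,
        n_overflow=n_over,
        mean=float(np.mean(values)),
        median=float(np.median(values)),
    )


@dataclass
class CohortComparison:
    """Welch two-sample comparison of a per-cell variable."""

    variable: str
    mean_a: float
    mean_b: float
    difference: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def compare_cohorts(
    a: list[CellSummary], b: list[CellSummary], variable: str
) -> CohortComparison:
    """Two-sided Welch (unequal-variance) t comparison of two cohorts.

    With zero variance in both cohorts the t statistic is undefined; equal
    means then give p = 1 by convention (flagged), unequal means p = 0.
    """
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each cohort needs >= 2 cells")
    va = np.array([getattr(s, variable) for s in a], dtype=float)
    vb = np.array([getattr(s, variable) for s in b], dtype=float)
    diff = float(np.mean(va) - np.mean(vb))
    if np.var(va) == 0 and np.var(vb) == 0:
        p = 1.0 if diff == 0 else 0.0
        return CohortComparison(variable, float(np.mean(va)), float(np.mean(vb)),
                                diff, float("nan"), p, degenerate=True)
    t, p = stats.ttest_ind(va, vb, equal_var=False)
    return CohortComparison(variable, float(np.mean(va)), float(np.mean(vb)),
                            diff, float(t), float(p))


def summaries_to_frame(summaries: list[CellSummary]):
    """Per-cell summaries as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "duration_s": [s.duration for s in summaries],
            "n_reversals": [s.n_reversals for s in summaries],
            "reversal_frequency_per_s": [s.reversal_frequency for s in summaries],
            "mean_run_speed_um_s": [s.mean_run_speed for s in summaries],
        }
    )
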