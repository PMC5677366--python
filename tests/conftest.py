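"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's kinematics/scan code paths: they
recompute everything from raw positions or raw sequences with plain Python
loops, so that agreement tests are two-route checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cletools.trajectory_io import Trajectory

# ---------------------------------------------------------------------------
# trajectory construction helpers


def traj_from_headings(headings_deg, dt=1.0, speed=1.0, cell_id="c"):
    """Unit-speed trajectory whose step j follows heading ``headings_deg[j]``."""
    h = np.radians(np.asarray(headings_deg, dtype=float))
    steps = speed * dt * np.column_stack([np.cos(h), np.sin(h)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    times = np.arange(len(headings_deg) + 1) * dt
    return Trajectory(cell_id=cell_id, times=times, xy=xy)


def random_trajectory(rng, n_samples, dt=1.0 / 16, step_scale=2.5):
    """A rough random track: correlated random-walk headings, variable speed."""
    headings = np.cumsum(rng.uniform(-60, 60, size=n_samples - 1))
    # occasional large turns so the 45° branch is exercised
    kicks = rng.random(n_samples - 1) < 0.15
    headings[kicks] += rng.choice([-1, 1], size=kicks.sum()) * rng.uniform(90, 180, size=kicks.sum())
    speeds = step_scale * rng.uniform(0.0, 2.0, size=n_samples - 1) / dt
    h = np.radians(headings)
    steps = (speeds * dt)[:, None] * np.column_stack([np.cos(h), np.sin(h)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Trajectory(cell_id="r", times=np.arange(n_samples) * dt, xy=xy)


# ---------------------------------------------------------------------------
# brute-force reversal-detection oracle


def _wrap180(a):
    a = a % 360.0
    if a > 180.0:
        a -= 360.0
    return 180.0 if a == -180.0 else a


def oracle_detect(traj, angle_threshold=45.0, suppression_window=2, min_step_speed=1.0):
    """Re-evaluate the printed criterion directly from positions.

    Independent route: absolute step headings via atan2, turn angles by
    modular wrapping, plain-loop scan over all Δθ index pairs.
    Returns the list of triggering indices i (matching ReversalEvent.index).
    """
    xy = traj.xy
    dt = traj.dt
    n_steps = len(xy) - 1
    psi = []
    spd = []
    for j in range(n_steps):
        dx = xy[j + 1, 0] - xy[j, 0]
        dy = xy[j + 1, 1] - xy[j, 1]
        psi.append(math.degrees(math.atan2(dy, dx)))
        spd.append(math.hypot(dx, dy) / dt)
    theta = [_wrap180(psi[i + 1] - psi[i]) for i in range(n_steps - 1)]
    defined = [
        spd[i] >= min_step_speed and spd[i + 1] >= min_step_speed
        for i in range(n_steps - 1)
    ]
    hits = []
    last_turn = None
    for i in range(n_steps - 3):
        if not (defined[i] and defined[i + 1] and defined[i + 2]):
            continue
        d1 = theta[i + 1] - theta[i]
        d2 = theta[i + 2] - theta[i + 1]
        if d1 * d2 < 0 and abs(d1) > angle_threshold and abs(d2) > angle_threshold:
            if last_turn is not None and (i + 1) - last_turn <= suppression_window:
                continue
            hits.append(i)
            last_turn = i + 1
    return hits


# ---------------------------------------------------------------------------
# brute-force ITC equilibrium oracle


def oracle_itc_heats(exp, n_sites, kd, dh):
    """Per-injection heats from a numerical equilibrium solve per composition.

    Solves the single-site binding quadratic for bound ligand B with brentq
    at each post-injection composition, converts to cumulative heat, then
    applies the same displacement correction as the instrument convention.
    """
    from scipy.optimize import brentq

    dv = [v / 1000.0 for v in exp.inj_vols]  # mL
    f = 1.0
    Q = []
    for d in dv:
        f *= 1.0 - d / exp.V0
        S = n_sites * exp.M0 * f  # total sites, µM
        L = exp.Xs * (1.0 - f)    # total ligand, µM

        def g(B):
            return (S - B) * (L - B) - kd * B

        hi = min(S, L)
        B = 0.0 if hi == 0 else brentq(g, 0.0, hi, xtol=1e-15, rtol=1e-15)
        Q.append(B * dh * exp.V0 * 1e-3)  # µcal
    heats = []
    qprev = 0.0
    for d, q in zip(dv, Q):
        heats.append(q - qprev + (d / exp.V0) * (q + qprev) / 2.0)
        qprev = q
    return np.array(heats)


# ---------------------------------------------------------------------------
# brute-force motif oracle

_CLASSES = ("YF", "X", "G", "P", "DE", "RK", "R")


def _class_ok(res, cls):
    return cls == "X" or res == "X" or res in cls


def oracle_scan(seq, max_gap=8, flank_window=6):
    """Character-by-character enumeration of tandem placements.

    Finds every unit start by direct checking, then applies the greedy
    leftmost-first pairing rule with its own loop. Returns 0-based
    (unit1_start, unit2_start) pairs and leftover single-unit starts.
    """
    L = len(_CLASSES)
    starts = [
        s
        for s in range(len(seq) - L + 1)
        if all(_class_ok(seq[s + k], _CLASSES[k]) for k in range(L))
    ]
    pairs = []
    partials = []
    i = 0
    while i < len(starts):
        u1 = starts[i]
        u1_end = u1 + L - 1
        partner = None
        for j in range(i + 1, len(starts)):
            gap = starts[j] - u1_end - 1
            if gap < 0:
                continue
            if gap > max_gap:
                break
            partner = j
            break
        if partner is None:
            partials.append(u1)
            i += 1
            continue
        u2 = starts[partner]
        pairs.append((u1, u2))
        u2_end = u2 + L - 1
        i = partner + 1
        while i < len(starts) and starts[i] <= u2_end:
            i += 1
    return pairs, partials


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
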