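"""Equilibrium binding models: forward evaluation, simulation and fitting.

Three assay families are covered, each with the fitting model its instrument
software conventionally applies:

* **Saturation binding with a nonspecific component** ("one site — total
  binding"): ``y = Bmax·x/(Kd + x) + NS·x + B0``. Used for radioligand
  UV-crosslink titrations.
* **Hill dose–response**: ``y = F0 + (F1 − F0)·xⁿ/(Kdⁿ + xⁿ)``. Used for
  microscale-thermophoresis (MST) dilution series.
* **ITC single set of identical sites** (Wiseman isotherm): cumulative heat
  after injection i, with cell concentration Mt and titrant Xt corrected for
  displacement dilution,

  ``Q = (n·Mt·ΔH·V0/2)·[1 + Xt/(n·Mt) + Kd/(n·Mt)
        − sqrt((1 + Xt/(n·Mt) + Kd/(n·Mt))² − 4·Xt/(n·Mt))]``

  and per-injection heat ``ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2``.

Throughout, the binding constant is parameterized as the dissociation
constant Kd (= 1/Ka) in the concentration unit of the curve, matching how
affinities are reported; ΔH is per mole of ligand bound.

Fitting is unweighted nonlinear least squares with multi-start
initialization: Kd starts on a log-spaced grid spanning [min(x)/10,
max(x)·10], with the linear-in-parameters part of each model (Bmax/NS/B0,
F0/F1, ΔH) initialized by an exact linear solve at each start, then a full
nonlinear polish; the best residual sum of squares wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "BindingCurve",
    "OneSiteTotalParams",
    "HillParams",
    "ItcExperiment",
    "ItcParams",
    "ItcData",
    "FitResult",
    "eval_one_site_total",
    "eval_hill",
    "eval_itc_isotherm",
    "dilution_series",
    "simulate_curve",
    "fit_model",
]

MODEL_TAGS = ("one_site_total", "hill", "itc")


@dataclass
class BindingCurve:
    """A concentration–response curve.

    ``x``: ligand/titrant concentrations (non-negative, strictly increasing,
    length ≥ 4); ``y``: responses (arbitrary units); ``unit`` records the
    concentration unit (e.g. "nM", "uM") for reporting only.
    """

    x: np.ndarray
    y: np.ndarray
    unit: str = ""
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size or self.x.size < 4:
            raise ParameterError("binding curve needs matching x/y, length >= 4")
        if np.any(self.x < 0):
            raise ParameterError("concentrations must be >= 0")
        if np.any(np.diff(self.x) <= 0):
            raise ParameterError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class OneSiteTotalParams:
    """Saturation-binding parameters: plateau, Kd, nonspecific slope, background."""

    Bmax: float
    Kd: float
    NS: float = 0.0
    B0: float = 0.0

    def __post_init__(self) -> None:
        if self.Bmax <= 0 or self.Kd <= 0 or self.NS < 0:
            raise ParameterError("require Bmax > 0, Kd > 0, NS >= 0")


@dataclass(frozen=True)
class HillParams:
    """Hill dose–response parameters: baseline, plateau, midpoint, coefficient."""

    F0: float
    F1: float
    Kd: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.n <= 0:
            raise ParameterError("require Kd > 0 and n > 0")


@dataclass(frozen=True)
class ItcExperiment:
    """Geometry of a titration: cell/syringe concentrations and injections.

    ``M0``: initial macromolecule concentration in the cell (µM); ``Xs``:
    syringe titrant concentration (µM); ``V0``: cell volume (mL; 1.4 mL is
    the VP-ITC class default); ``inj_vols``: per-injection volumes (µL);
    ``T``: temperature (K), recorded for reporting.
    """

    M0: float
    Xs: float
    V0: float = 1.4
    inj_vols: tuple = (10.0,) * 30
    T: float = 283.15

    def __post_init__(self) -> None:
        if min(self.M0, self.Xs, self.V0, self.T) <= 0 or min(self.inj_vols) <= 0:
            raise ParameterError("all ITC experiment quantities must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.inj_vols)

    def schedules(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-injection (Mt, Xt) in µM after displacement dilution."""
        dv = np.asarray(self.inj_vols, dtype=float) / 1000.0  # µL -> mL
        f = np.cumprod(1.0 - dv / self.V0)
        return self.M0 * f, self.Xs * (1.0 - f)


@dataclass(frozen=True)
class ItcParams:
    """Single-set-of-sites parameters: stoichiometry, Kd (µM), ΔH (cal/mol)."""

    n_sites: float
    Kd: float
    dH: float

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.Kd <= 0:
            raise ParameterError("require n_sites > 0 and Kd > 0")


@dataclass
class ItcData:
    """An ITC experiment with its integrated per-injection heats (µcal)."""

    experiment: ItcExperiment
    heats: np.ndarray
    model_tag: str = "itc"

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.size != self.experiment.n_injections:
            raise ParameterError("one heat per injection required")


@dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    model_tag: str
    estimates: dict
    stderr: dict
    rss: float
    converged: bool
    initial_guess: dict
    n_points: int = 0

    def __getitem__(self, key):
        return self.estimates[key]


def eval_one_site_total(x, p: OneSiteTotalParams) -> np.ndarray:
    """Total binding: specific hyperbola plus linear nonspecific plus background."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("concentrations must be >= 0")
    return p.Bmax * x / (p.Kd + x) + p.NS * x + p.B0


def eval_hill(x, p: HillParams) -> np.ndarray:
    """Hill curve; x = 0 maps to F0 for any n."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        xn = np.where(x > 0, np.exp(p.n * np.log(np.where(x > 0, x, 1.0))), 0.0)
    return p.F0 + (p.F1 - p.F0) * xn / (p.Kd**p.n + xn)


def _cumulative_heats(exp: ItcExperiment, p: ItcParams) -> np.ndarray:
    """Cumulative heat Q_i in µcal from the closed-form binding quadratic."""
    Mt, Xt = exp.schedules()  # µM
    r = Xt / (p.n_sites * Mt)
    kdterm = p.Kd / (p.n_sites * Mt)
    disc = (1.0 + r + kdterm) ** 2 - 4.0 * r
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in Wiseman isotherm")
    bracket = 1.0 + r + kdterm - np.sqrt(disc)
    # n·Mt[µM]·dH[cal/mol]·V0[mL] -> µcal carries a net 1e-3 factor
    return p.n_sites * Mt * p.dH * exp.V0 * 1e-3 * bracket / 2.0


def eval_itc_isotherm(exp: ItcExperiment, p: ItcParams) -> np.ndarray:
    """Per-injection heats ΔQ_i (µcal) with the displacement correction term."""
    Q = _cumulative_heats(exp, p)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dv = np.asarray(exp.inj_vols, dtype=float) / 1000.0
    return Q - Qprev + (dv / exp.V0) * (Q + Qprev) / 2.0


def dilution_series(top: float, n_points: int = 16) -> np.ndarray:
    """1:1 serial dilution design, ascending: top/2^k for k = n−1..0."""
    if top <= 0 or n_points < 2:
        raise ParameterError("need top > 0 and n_points >= 2")
    return top / 2.0 ** np.arange(n_points - 1, -1, -1, dtype=float)


def simulate_curve(model_tag, true_params, x_design, noise_sd=0.0, seed=None, unit=""):
    """Forward-model values plus i.i.d. Gaussian noise (seeded).

    For the curve models ``x_design`` is a concentration array and a
    :class:`BindingCurve` is returned; for ``"itc"`` it is an
    :class:`ItcExperiment` and an :class:`ItcData` (heats in µcal) is
    returned. ``noise_sd = 0`` gives exact forward-model values.
    """
    if model_tag not in MODEL_TAGS:
        raise ParameterError(f"unknown model {model_tag!r}")
    rng = np.random.default_rng(seed)
    if model_tag == "itc":
        if not isinstance(x_design, ItcExperiment):
            raise ParameterError("ITC simulation needs an ItcExperiment design")
        y = eval_itc_isotherm(x_design, true_params)
        y = y + rng.normal(0.0, noise_sd, size=y.size) if noise_sd > 0 else y
        return ItcData(experiment=x_design, heats=y)
    x = np.asarray(x_design, dtype=float)
    y = eval_one_site_total(x, true_params) if model_tag == "one_site_total" else eval_hill(x, true_params)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return BindingCurve(x=x, y=y, unit=unit, model_tag=model_tag)


# ---------------------------------------------------------------------------
# fitting


def _kd_grid(x: np.ndarray, n: int = 10) -> np.ndarray:
    lo = np.min(x[x > 0]) / 10.0
    hi = np.max(x) * 10.0
    return np.geomspace(lo, hi, n)


def _lstsq_cols(cols: list[np.ndarray], y: np.ndarray) -> np.ndarray:
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef

def _polish(residual_fn, p0, lb, ub):
    p0 = np.clip(p0, lb, ub)
    return least_squares(residual_fn, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)


def _stderr(res, names):
    """Standard errors from the jacobian at the solution (internal scale)."""
    m, k = res.jac.shape
    dof = max(m - k, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return dict(zip(names, se))


def _check_not_flat(y: np.ndarray) -> None:
    if np.ptp(y) == 0:
        raise DegenerateDataError("response has zero variance; model unidentifiable")


def _jitter(rng, values, scale=0.3):
    if rng is None:
        return np.asarray(values, float)
    return np.asarray(values, float) * np.exp(rng.normal(0.0, scale, size=len(values)))


def _fit_one_site_total(curve: BindingCurve, rng=None) -> FitResult:
    x, y = curve.x, curve.y
    _check_not_flat(y)
    lb = np.array([1e-12, np.log10(np.min(x[x > 0]) / 1e4), 0.0, -np.inf])
    ub = np.array([np.inf, np.log10(np.max(x) * 1e4), np.inf, np.inf])

    def resid(p):
        Bmax, lkd, NS, B0 = p
        return Bmax * x / (10.0**lkd + x) + NS * x + B0 - y

    best = None
    best_init = None
    for kd0 in _jitter(rng, _kd_grid(x)):
        hyper = x / (kd0 + x)
        Bmax0, NS0, B00 = _lstsq_cols([hyper, x, np.ones_like(x)], y)
        p0 = [max(Bmax0, 1e-9), math.log10(kd0), max(NS0, 0.0), B00]
        res = _polish(resid, p0, lb, ub)
        if best is None or res.cost < best.cost:
            best, best_init = res, {"Bmax": p0[0], "Kd": kd0, "NS": p0[2], "B0": p0[3]}
    Bmax, lkd, NS, B0 = best.x
    kd = 10.0**lkd
    se = _stderr(best, ["Bmax", "log10Kd", "NS", "B0"])
    se["Kd"] = math.log(10) * kd * se.pop("log10Kd")
    return FitResult(
        model_tag="one_site_total",
        estimates={"Bmax": Bmax, "Kd": kd, "NS": NS, "B0": B0},
        stderr=se,
        rss=2.0 * best.cost,
        converged=bool(best.success),
        initial_guess=best_init,
        n_points=x.size,
    )


def _fit_hill(curve: BindingCurve, rng=None) -> FitResult:
    x, y = curve.x, curve.y
    _check_not_flat(y)
    lb = np.array([-np.inf, -np.inf, np.log10(np.min(x[x > 0]) / 1e4), 0.3])
    ub = np.array([np.inf, np.inf, np.log10(np.max(x) * 1e4), 4.0])

    def resid(p):
        F0, F1, lkd, n = p
        return eval_hill(x, HillParams(F0=F0, F1=F1, Kd=10.0**lkd, n=n)) - y

    best = None
    best_init = None
    for kd0 in _jitter(rng, _kd_grid(x)):
        for n0 in (0.7, 1.0, 2.0):
            frac = x**n0 / (kd0**n0 + x**n0)
            F00, F10 = _lstsq_cols([1.0 - frac, frac], y)
            p0 = [F00, F10, math.log10(kd0), n0]
            res = _polish(resid, p0, lb, ub)
            if best is None or res.cost < best.cost:
                best, best_init = res, {"F0": F00, "F1": F10, "Kd": kd0, "n": n0}
    F0, F1, lkd, n = best.x
    kd = 10.0**lkd
    se = _stderr(best, ["F0", "F1", "log10Kd", "n"])
    se["Kd"] = math.log(10) * kd * se.pop("log10Kd")
    return FitResult(
        model_tag="hill",
        estimates={"F0": F0, "F1": F1, "Kd": kd, "n": n},
        stderr=se,
        rss=2.0 * best.cost,
        converged=bool(best.success),
        initial_guess=best_init,
        n_points=x.size,
    )


def _fit_itc(data: ItcData, rng=None) -> FitResult:
    exp, y = data.experiment, data.heats
    _check_not_flat(y)
    Mt, Xt = exp.schedules()
    lb = np.array([0.3, np.log10(exp.M0 / 1e6), -np.inf])
    ub = np.array([6.0, np.log10(exp.M0 * 1e4), np.inf])

    def resid(p):
        n, lkd, dH = p
        return eval_itc_isotherm(exp, ItcParams(n_sites=n, Kd=10.0**lkd, dH=dH)) - y

    # stoichiometry start from the molar-ratio position of the isotherm's
    # steepest descent; dH start from an exact linear solve at each (n, Kd)
    kd_starts = np.geomspace(exp.M0 / 1e3, exp.M0 * 10.0, 8)
    n_starts = (0.5, 1.0, 2.0, 4.0)
    best = None
    best_init = None
    for kd0 in _jitter(rng, kd_starts):
        for n0 in n_starts:
            shape = eval_itc_isotherm(exp, ItcParams(n_sites=n0, Kd=kd0, dH=1.0))
            denom = float(shape @ shape)
            dH0 = float(shape @ y) / denom if denom > 0 else -1e4
            if dH0 == 0:
                dH0 = -1e4
            p0 = [n0, math.log10(kd0), dH0]
            res = _polish(resid, p0, lb, ub)
            if best is None or res.cost < best.cost:
                best, best_init = res, {"n_sites": n0, "Kd": kd0, "dH": dH0}
    n, lkd, dH = best.x
    kd = 10.0**lkd
    se = _stderr(best, ["n_sites", "log10Kd", "dH"])
    se["Kd"] = math.log(10) * kd * se.pop("log10Kd")
    return FitResult(
        model_tag="itc",
        estimates={"n_sites": n, "Kd": kd, "dH": dH},
        stderr=se,
        rss=2.0 * best.cost,
        converged=bool(best.success),
        initial_guess=best_init,
        n_points=y.size,
    )


def fit_model(data, model_tag: str | None = None, rng=None) -> FitResult:
    """Multi-start least-squares fit of a binding data set.

    ``data`` is a :class:`BindingCurve` (one-site-total or Hill) or an
    :class:`ItcData`; ``model_tag`` overrides the tag carried by the data.
    ``rng`` (a numpy Generator) perturbs the multi-start grid — useful for
    checking that recovery does not depend on the default initialization.

    Never raises on non-convergence: the returned result carries
    ``converged=False``. Flat (zero-variance) responses raise
    :class:`~cletools.errors.DegenerateDataError`.
    """
    tag = model_tag or getattr(data, "model_tag", "")
    if tag not in MODEL_TAGS:
        raise ParameterError(f"unknown or missing model tag {tag!r}")
    if tag == "itc":
        if not isinstance(data, ItcData):
            raise ParameterError("ITC fitting needs an ItcData")
        return _fit_itc(data, rng=rng)
    if not isinstance(data, BindingCurve):
        raise ParameterError("curve fitting needs a BindingCurve")
    n_free = 4
    if data.x.size < n_free + 1:
        raise ParameterError("need at least n_free + 1 = 5 points")
    return _fit_one_site_total(data, rng=rng) if tag == "one_site_total" else _fit_hill(data, rng=rng)
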