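"""Least-squares fitting of the enzymology models used to characterize a
tRNA methyltransferase: single-exponential progress curves
f(t) = A + B e^(-k_obs t), apparent Michaelis–Menten saturation,
one-site IC50 inhibition, and exponential-growth doubling time.

All fits are deterministic damped least squares (scipy) seeded from a
log-spaced multi-start grid over the nonlinear parameter; the linear
parameters are profiled out exactly at each start.  Standard errors come
from the linearized covariance at the optimum.  Units: concentrations in
uM, time in minutes (hours for growth), rate constants in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeCourse",
    "SaturationSeries",
    "FitResult",
    "FitError",
    "fit_single_exponential",
    "initial_velocity",
    "fit_michaelis_menten",
    "fit_ic50",
    "doubling_time",
    "read_xy_table",
    "write_xy_table",
]

_RELATIVE_TOL = 1e-12
_MAX_ITER = 500


class FitError(RuntimeError):
    """Raised when a fit cannot be performed on the given data."""


@dataclass(frozen=True)
class TimeCourse:
    """(t, y) measurements: time plus signal (dpm, OD, ...)."""

    t: np.ndarray
    y: np.ndarray
    time_unit: str = "min"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise FitError("t and y must be 1-D arrays of equal length")
        if (t < 0).any():
            raise FitError("time points must be nonnegative")
        if (np.diff(t) < 0).any():
            raise FitError("time points must be ascending")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SaturationSeries:
    """Substrate concentration vs initial velocity."""

    s: np.ndarray
    v: np.ndarray
    substrate_kind: str = "tRNA"  # or "SAM"

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise FitError("s and v must be 1-D arrays of equal length")
        if (s <= 0).any():
            raise FitError("substrate concentrations must be positive")
        if (np.diff(s) <= 0).any():
            raise FitError("substrate concentrations must be strictly ascending")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return len(self.s)


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with units and residual diagnostics."""

    model: str
    parameters: dict[str, float]
    units: dict[str, str]
    stderr: dict[str, float]
    rss: float
    residuals: np.ndarray
    converged: bool
    status: str = "ok"  # ok | no_inhibition | no_saturation | no_convergence
    label: str | None = None  # e.g. "apparent" for conditional MM constants

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "label": self.label,
            "parameters": self.parameters,
            "units": self.units,
            "stderr": self.stderr,
            "rss": self.rss,
            "residuals": list(map(float, self.residuals)),
            "converged": self.converged,
            "status": self.status,
        }


def _stderr_from_jacobian(jac: np.ndarray, residuals: np.ndarray, n_params: int) -> np.ndarray:
    n = len(residuals)
    dof = max(n - n_params, 1)
    rss = float(residuals @ residuals)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def fit_single_exponential(tc: TimeCourse) -> FitResult:
    """Fit f(t) = A + B e^(-k_obs t) by least squares.

    A is the plateau (activity at completion), B the amplitude of the
    observable phase (f(0) = A + B), k_obs the observed first-order rate
    constant in 1/min.  k_obs is profiled on a log-spaced multi-start
    grid with A, B solved linearly at each start, then refined jointly.
    """
    if len(np.unique(tc.t)) < 4:
        raise FitError("at least 4 distinct time points are required")
    t, y = tc.t, tc.y
    t_span = t.max() - t.min()
    k_grid = np.logspace(np.log10(0.01 / t_span), np.log10(100.0 / t_span), 25)

    best = None
    for k in k_grid:
        X = np.column_stack([np.ones_like(t), np.exp(-k * t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = X @ coef - y
        rss = float(r @ r)
        if best is None or rss < best[0]:
            best = (rss, coef[0], coef[1], k)

    def resid(p):
        A, B, k = p
        return A + B * np.exp(-k * t) - y

    sol = least_squares(
        resid,
        x0=[best[1], best[2], best[3]],
        method="lm",
        xtol=_RELATIVE_TOL,
        ftol=_RELATIVE_TOL,
        gtol=_RELATIVE_TOL,
        max_nfev=_MAX_ITER * 3,
    )
    if not sol.success:
        return FitResult(
            "single_exponential",
            {},
            {},
            {},
            float("nan"),
            np.array([]),
            False,
            status="no_convergence",
        )
    A, B, k = sol.x
    se = _stderr_from_jacobian(sol.jac, sol.fun, 3)
    return FitResult(
        model="single_exponential",
        parameters={"A": float(A), "B": float(B), "k_obs": float(k)},
        units={"A": "signal", "B": "signal", "k_obs": "1/min"},
        stderr={"A": float(se[0]), "B": float(se[1]), "k_obs": float(se[2])},
        rss=float(sol.fun @ sol.fun),
        residuals=sol.fun,
        converged=bool(k > 0),
        status="ok" if k > 0 else "no_convergence",
    )


def initial_velocity(
    tc: TimeCourse, t_linear: float, method: str = "slope"
) -> float:
    """Initial velocity (signal/min) from the early linear phase.

    ``method="slope"`` (default): least-squares slope through the points
    with t <= t_linear, constrained through the measured t = 0 value.
    ``method="single_point"``: (f(t_linear) - f(0)) / t_linear using the
    measurement closest to t_linear.
    """
    if not (tc.t.min() <= t_linear <= tc.t.max()):
        raise FitError("t_linear must lie within the sampled time range")
    mask = tc.t <= t_linear
    if mask.sum() < 2:
        raise FitError("need at least 2 points in the linear window")
    if tc.t[0] != 0:
        raise FitError("a measured t = 0 point is required")
    y0 = tc.y[0]
    if method == "single_point":
        idx = int(np.argmin(np.abs(tc.t - t_linear)))
        if tc.t[idx] == 0:
            raise FitError("single-point velocity needs a nonzero time point")
        return float((tc.y[idx] - y0) / tc.t[idx])
    if method != "slope":
        raise FitError(f"unknown method {method!r}")
    t_w = tc.t[mask]
    y_w = tc.y[mask]
    nz = t_w > 0
    if not nz.any():
        raise FitError("linear window contains only t = 0")
    # constrained through (0, y0): slope = sum(t (y - y0)) / sum(t^2)
    return float(np.sum(t_w[nz] * (y_w[nz] - y0)) / np.sum(t_w[nz] ** 2))


def fit_michaelis_menten(series: SaturationSeries) -> FitResult:
    """Fit v = Vmax s / (Km + s); constants labeled "apparent".

    Under the assay conditions emulated here the enzyme concentration is
    comparable to the substrate, so the constants are conditional
    (apparent) rather than classical steady-state values.  Km is
    profiled on a log grid spanning the concentration range with Vmax
    solved linearly, then both are refined jointly.
    """
    if len(series) < 5:
        raise FitError("at least 5 substrate concentrations are required")
    s, v = series.s, series.v
    if s.max() / s.min() < 10.0:
        raise FitError("concentrations must span at least one order of magnitude")

    km_grid = np.logspace(np.log10(s.min() / 10), np.log10(s.max() * 10), 25)
    best = None
    for km in km_grid:
        x = s / (km + s)
        vmax = float(x @ v / (x @ x))
        r = vmax * x - v
        rss = float(r @ r)
        if best is None or rss < best[0]:
            best = (rss, km, vmax)

    def resid(p):
        km, vmax = p
        return vmax * s / (km + s) - v

    sol = least_squares(
        resid,
        x0=[best[1], best[2]],
        method="lm",
        xtol=_RELATIVE_TOL,
        ftol=_RELATIVE_TOL,
        gtol=_RELATIVE_TOL,
        max_nfev=_MAX_ITER * 2,
    )
    km, vmax = sol.x
    se = _stderr_from_jacobian(sol.jac, sol.fun, 2)
    status = "ok"
    if not sol.success or km <= 0 or vmax <= 0:
        status = "no_convergence"
    elif km > 10.0 * s.max():
        # data look linear in s: no saturation information
        status = "no_saturation"
    return FitResult(
        model="michaelis_menten",
        parameters={"Km": float(km), "Vmax": float(vmax)},
        units={"Km": "uM", "Vmax": "signal/min"},
        stderr={"Km": float(se[0]), "Vmax": float(se[1])},
        rss=float(sol.fun @ sol.fun),
        residuals=sol.fun,
        converged=status == "ok",
        status=status,
        label="apparent",
    )


def fit_ic50(
    inhibitor_conc: Sequence[float], activity: Sequence[float]
) -> FitResult:
    """Fit a = 1 / (1 + [I]/IC50), a one-site hyperbolic decay (Hill
    slope 1).

    The titration must include a zero-inhibitor point; activities are
    normalized to it.  On the fitted curve the activity at [I] = IC50 is
    exactly 0.5.  Non-decreasing activity yields the "no_inhibition"
    status instead of a forced parameter.
    """
    conc = np.asarray(inhibitor_conc, dtype=float)
    act = np.asarray(activity, dtype=float)
    if conc.shape != act.shape or conc.ndim != 1:
        raise FitError("inhibitor concentrations and activities must match")
    if conc[0] != 0:
        raise FitError("the titration must include a zero-inhibitor point first")
    act = act / act[0]

    pos = conc > 0
    slope = np.polyfit(conc, act, 1)[0]
    if slope >= 0 or act[pos].min() >= 1.0:
        return FitResult(
            model="ic50",
            parameters={},
            units={},
            stderr={},
            rss=float("nan"),
            residuals=np.array([]),
            converged=False,
            status="no_inhibition",
        )

    grid = np.logspace(
        np.log10(conc[pos].min() / 10), np.log10(conc[pos].max() * 10), 25
    )
    best = None
    for ic in grid:
        r = 1.0 / (1.0 + conc / ic) - act
        rss = float(r @ r)
        if best is None or rss < best[0]:
            best = (rss, ic)

    def resid(p):
        return 1.0 / (1.0 + conc / p[0]) - act

    sol = least_squares(
        resid,
        x0=[best[1]],
        method="lm",
        xtol=_RELATIVE_TOL,
        ftol=_RELATIVE_TOL,
        gtol=_RELATIVE_TOL,
        max_nfev=_MAX_ITER,
    )
    ic50 = float(sol.x[0])
    se = _stderr_from_jacobian(sol.jac, sol.fun, 1)
    return FitResult(
        model="ic50",
        parameters={"IC50": ic50},
        units={"IC50": "uM"},
        stderr={"IC50": float(se[0])},
        rss=float(sol.fun @ sol.fun),
        residuals=sol.fun,
        converged=bool(sol.success and ic50 > 0),
        status="ok" if sol.success and ic50 > 0 else "no_convergence",
    )


def _window_r2(logy: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, logy, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, r2


def doubling_time(
    tc: TimeCourse,
    window: tuple[int, int] | None = None,
    r2_threshold: float = 0.99,
) -> float:
    """Doubling time in hours from a log-linear fit of OD vs time.

    ``window`` selects point indices (inclusive) of the exponential
    phase; if omitted, the longest contiguous window (>= 3 points) with
    log-linear R^2 >= ``r2_threshold`` and positive slope is used, ties
    broken by higher R^2.  Time is interpreted per ``tc.time_unit``
    ("h" or "min"); the result is ln(2)/slope in hours.
    """
    if (tc.y <= 0).any():
        raise FitError("OD values must be positive for a log-linear fit")
    t = tc.t / 60.0 if tc.time_unit == "min" else tc.t
    logy = np.log(tc.y)
    n = len(t)
    if window is not None:
        lo, hi = window
        if hi - lo + 1 < 2:
            raise FitError("window must contain at least 2 points")
        slope, _ = _window_r2(logy[lo : hi + 1], t[lo : hi + 1])
    else:
        best = None  # (length, r2, slope)
        for lo in range(n - 2):
            for hi in range(lo + 2, n):
                s_, r2 = _window_r2(logy[lo : hi + 1], t[lo : hi + 1])
                if s_ <= 0 or r2 < r2_threshold:
                    continue
                key = (hi - lo + 1, r2)
                if best is None or key > (best[0], best[1]):
                    best = (hi - lo + 1, r2, s_)
        if best is None:
            raise FitError("no exponential-phase window with positive slope found")
        slope = best[2]
    if slope <= 0:
        raise FitError("growth slope must be positive")
    return float(np.log(2) / slope)


# ---------------------------------------------------------------------------
# Two-column data files with a header line: "x_name\ty_name"


def read_xy_table(source: Union[str, Path, TextIO]) -> tuple[str, str, np.ndarray, np.ndarray]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_xy_table(fh)
    header = None
    xs, ys = [], []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            if len(header) != 2:
                raise FitError(f"line {lineno}: header must have two tab-separated names")
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FitError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        try:
            xs.append(float(fields[0]))
            ys.append(float(fields[1]))
        except ValueError:
            raise FitError(f"line {lineno}: non-numeric value") from None
    if header is None:
        raise FitError("empty data file")
    return header[0], header[1], np.array(xs), np.array(ys)


def write_xy_table(
    x_name: str,
    y_name: str,
    x: Sequence[float],
    y: Sequence[float],
    dest: Union[str, Path, TextIO],
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_xy_table(x_name, y_name, x, y, fh)
        return
    dest.write(f"{x_name}\t{y_name}\n")
    for xi, yi in zip(x, y):
        dest.write(f"{xi:g}\t{yi:.8g}\n")
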