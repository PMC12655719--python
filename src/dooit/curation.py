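"""Thermodynamic standardization models for literature solubility data.

Published solubility tables for the same solute/solvent system frequently
disagree in the temperatures or compositions at which they were measured.
Before such data can anchor reference-solvent computations they must be
harmonized onto a common grid.  Three classical models serve that purpose:

* the Buchowski-Ksiazczak lambda-h equation,
  ``ln[1 + lam * (1 - x) / x] = lam * h * (1/T - 1/T_m)``,
  a two-parameter temperature correlation usable from three points up
  (the melting temperature T_m enters as a known constant);
* the three-parameter Van't Hoff form ``ln x = a + b/T + c ln T``, which
  needs no melting data but at least four points;
* the Jouyban-Acree cosolvency model
  ``ln x_m = w1 ln x_1 + w2 ln x_2 + (w1 w2 / T) * sum_i J_i (w1 - w2)^i``
  (i = 0..2, w2 = 1 - w1), which interpolates a binary-mixture isotherm
  between the neat-solvent endpoints.

Systems are also classified into four consistency categories that decide
which standardization (if any) a dataset needs.

All fitting is least squares on ln x: solubilities span several orders of
magnitude, so residuals on x itself would be dominated by the soluble end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "LambdaHFit",
    "VantHoff3Fit",
    "JouybanAcreeFit",
    "lambda_h_forward",
    "fit_lambda_h",
    "vanthoff3_forward",
    "fit_vanthoff3",
    "jouyban_acree_forward",
    "fit_jouyban_acree",
    "categorize",
    "average_neat_solubility",
]

#: Absolute tolerance for treating two x2_star compositions as equal.
X2_TOL = 1e-6
#: Absolute tolerance (kelvin) for treating two temperatures as equal.
T_TOL = 0.01


@dataclass(frozen=True)
class LambdaHFit:
    lam: float
    h: float
    t_m: float
    rmse_lnx: float


@dataclass(frozen=True)
class VantHoff3Fit:
    a: float
    b: float
    c: float
    rmse_lnx: float


@dataclass(frozen=True)
class JouybanAcreeFit:
    j0: float
    j1: float
    j2: float
    rmse_lnx: float


# ---------------------------------------------------------------------------
# Buchowski-Ksiazczak lambda-h
# ---------------------------------------------------------------------------


def lambda_h_forward(lam: float, h: float, t_m: float, T: float) -> float:
    """Mole-fraction solubility x(T) from the lambda-h equation.

    The implicit equation ln[1 + lam (1-x)/x] = lam h (1/T - 1/T_m) solves
    analytically to ``x = lam / (exp(lam h (1/T - 1/T_m)) + lam - 1)``.
    At T = T_m the exponent vanishes and x = 1 (ideal melt limit).
    """
    if lam <= 0:
        raise ValueError(f"lam={lam} must be > 0")
    if T > t_m:
        raise ValueError(f"T={T} K above melting temperature {t_m} K")
    denom = math.exp(lam * h * (1.0 / T - 1.0 / t_m)) + lam - 1.0
    if denom <= 0:
        raise ValueError(f"lambda-h denominator {denom} <= 0 (unphysical branch)")
    return lam / denom


def _lambda_h_root(lam: float, h: float, t_m: float, T: float) -> float:
    """Solve the implicit lambda-h equation numerically (cross-check path)."""
    rhs = lam * h * (1.0 / T - 1.0 / t_m)
    f = lambda x: math.log1p(lam * (1.0 - x) / x) - rhs  # noqa: E731
    return brentq(f, 1e-15, 1.0, xtol=1e-15, rtol=8.9e-16)


def fit_lambda_h(points: Sequence[tuple[float, float]], t_m: float) -> LambdaHFit:
    """Fit (lam, h) to (T, x) data by nonlinear least squares on ln x.

    Requires at least three measurements, all at or below the melting
    temperature.
    """
    pts = [(float(t), float(x)) for t, x in points]
    if len(pts) < 3:
        raise ValueError("at least 3 measurements required to fit the lambda-h model")
    T = np.array([p[0] for p in pts])
    x = np.array([p[1] for p in pts])
    if np.any(T > t_m):
        raise ValueError("all temperatures must satisfy T <= t_m")
    if np.any((x <= 0) | (x > 1)):
        raise ValueError("solubilities must lie in (0, 1]")
    lnx = np.log(x)
    dT = 1.0 / T - 1.0 / t_m

    def resid(theta):
        lam, h = np.exp(theta[0]), theta[1]
        return np.log(lam) - np.log(np.exp(lam * h * dT) + lam - 1.0) - lnx

    # Start from the ideal (lam = 1) van't Hoff slope.
    h0 = -np.polyfit(dT, lnx, 1)[0]
    sol = least_squares(resid, x0=[0.0, h0], method="lm", xtol=1e-15, ftol=1e-15)
    if not sol.success:
        raise RuntimeError(f"lambda-h fit failed: {sol.message}")
    lam, h = float(np.exp(sol.x[0])), float(sol.x[1])
    rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return LambdaHFit(lam=lam, h=h, t_m=float(t_m), rmse_lnx=rmse)


# ---------------------------------------------------------------------------
# Van't Hoff three-parameter
# ---------------------------------------------------------------------------


def vanthoff3_forward(a: float, b: float, c: float, T: float) -> float:
    """ln x at temperature T under the three-parameter Van't Hoff model."""
    return a + b / T + c * math.log(T)


def fit_vanthoff3(points: Sequence[tuple[float, float]]) -> VantHoff3Fit:
    """Ordinary least squares of ln x on (1, 1/T, ln T); needs >= 4 points."""
    pts = [(float(t), float(x)) for t, x in points]
    if len(pts) < 4:
        raise ValueError("at least four data points required to fit VH3")
    T = np.array([p[0] for p in pts])
    x = np.array([p[1] for p in pts])
    if np.any((x <= 0) | (x > 1)):
        raise ValueError("solubilities must lie in (0, 1]")
    if len(np.unique(np.round(T, 9))) < 3:
        raise ValueError("need at least three distinct temperatures")
    design = np.column_stack([np.ones_like(T), 1.0 / T, np.log(T)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: temperatures too collinear")
    coef, *_ = np.linalg.lstsq(design, np.log(x), rcond=None)
    rmse = float(np.sqrt(np.mean((design @ coef - np.log(x)) ** 2)))
    return VantHoff3Fit(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]), rmse_lnx=rmse)


# ---------------------------------------------------------------------------
# Jouyban-Acree
# ---------------------------------------------------------------------------


def jouyban_acree_forward(
    j: tuple[float, float, float],
    w1: float,
    ln_x1_T: float,
    ln_x2_T: float,
    T: float,
) -> float:
    """ln x of the mixture at solvent-1 fraction ``w1`` and temperature T."""
    if not 0.0 <= w1 <= 1.0:
        raise ValueError(f"w1={w1} outside [0, 1]")
    if T <= 0:
        raise ValueError(f"T={T} must be > 0")
    w2 = 1.0 - w1
    interaction = sum(ji * (w1 - w2) ** i for i, ji in enumerate(j))
    return w1 * ln_x1_T + w2 * ln_x2_T + (w1 * w2 / T) * interaction


def fit_jouyban_acree(
    curve: Sequence[tuple[float, float]],
    ln_x1_T: float,
    ln_x2_T: float,
    T: float,
) -> JouybanAcreeFit:
    """Fit (J0, J1, J2) to one isotherm by linear least squares.

    ``curve`` holds (w1, ln x_mix) pairs; the known log-linear blend of the
    neat endpoints moves to the left-hand side, leaving the J-polynomial
    basis.  Requires at least three interior compositions (0 < w1 < 1) —
    endpoint rows carry no information on the J's and are ignored.
    """
    interior = [(float(w), float(y)) for w, y in curve if 0.0 < float(w) < 1.0]
    if len(interior) < 3:
        raise ValueError("at least 3 interior compositions (0 < w1 < 1) required")
    w1 = np.array([p[0] for p in interior])
    y = np.array([p[1] for p in interior])
    w2 = 1.0 - w1
    lhs = y - w1 * ln_x1_T - w2 * ln_x2_T
    basis = np.column_stack([(w1 * w2 / T) * (w1 - w2) ** i for i in range(3)])
    coef, *_ = np.linalg.lstsq(basis, lhs, rcond=None)
    rmse = float(np.sqrt(np.mean((basis @ coef - lhs) ** 2)))
    return JouybanAcreeFit(j0=float(coef[0]), j1=float(coef[1]), j2=float(coef[2]), rmse_lnx=rmse)


# ---------------------------------------------------------------------------
# Category taxonomy
# ---------------------------------------------------------------------------


def average_neat_solubility(values: Sequence[float]) -> float:
    """Consensus neat-solvent solubility from multiple literature values.

    The arithmetic mean is taken on x itself (then logged by callers), the
    convention used when several reports exist for one neat solvent.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no values to average")
    return float(np.mean(vals))


def _uniq(values, tol):
    out: list[float] = []
    for v in sorted(values):
        if not out or v - out[-1] > tol:
            out.append(v)
    return out


def categorize(curve) -> dict:
    """Classify one system's raw data into consistency categories 1-4.

    Using the (T, x2_star, x1) points of a :class:`~dooit.data_io.SolubilityCurve`:

    * category 1 — pure-solvent measurements exist at every mixture
      temperature and every temperature shares one composition grid;
    * category 2 — composition grids agree but the pure-solvent temperatures
      do not match the mixture temperatures;
    * category 3 — temperatures agree but composition grids differ between
      temperatures;
    * category 4 — both kinds of inconsistency.

    Returns ``{"category": int, "incomplete": bool, "n_temperatures": int}``;
    ``incomplete`` flags systems lacking pure-solvent rows entirely (their
    endpoints must be supplied from averaged literature values before
    standardization).
    """
    points = curve.points
    pure_temps = _uniq(
        {t for t, x2, _ in points if x2 <= X2_TOL or x2 >= 1.0 - X2_TOL}, T_TOL
    )
    mix_pts = [(t, x2) for t, x2, _ in points if X2_TOL < x2 < 1.0 - X2_TOL]
    mix_temps = _uniq({t for t, _ in mix_pts}, T_TOL)

    incomplete = not pure_temps

    def same_temps():
        if len(pure_temps) != len(mix_temps):
            return False
        return all(abs(a - b) <= T_TOL for a, b in zip(pure_temps, mix_temps))

    def same_grids():
        grids = []
        for t in mix_temps:
            grid = _uniq([x2 for tt, x2 in mix_pts if abs(tt - t) <= T_TOL], X2_TOL)
            grids.append(grid)
        if not grids:
            return True
        first = grids[0]
        return all(
            len(g) == len(first) and all(abs(a - b) <= X2_TOL for a, b in zip(g, first))
            for g in grids[1:]
        )

    temps_ok = same_temps() and not incomplete
    grids_ok = same_grids()
    if temps_ok and grids_ok:
        category = 1
    elif grids_ok:
        category = 2
    elif temps_ok:
        category = 3
    else:
        category = 4
    return {
        "category": category,
        "incomplete": incomplete,
        "n_temperatures": len(mix_temps),
    }
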