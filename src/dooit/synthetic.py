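"""Seeded synthetic fixtures for every other module.

Three generators emulate the structure of the real inputs without any
external data:

* ``gen_qspr_table`` — a grouped QSPR table: a handful of informative
  features drive a scalar log-solubility-like target through a linear map
  or a mixture of Gaussian bumps, padded with pure-noise features and
  per-solute offsets (for leave-one-compound-out grouping).  The planted
  ground truth travels with the table so oracle errors and importances can
  be computed without fitting anything.
* ``gen_sigma_curve`` — a smooth parabola-plus-wings sigma-potential curve
  on the fixed 61-point charge-density grid.
* ``gen_solubility_curves`` — solubility-vs-temperature or vs-composition
  curves produced by the curation forward models with seeded noise on ln x.

Every generator is a pure function of its arguments and seed.

The default planted experiment mirrors the real descriptor pools: 16
features with 5 informative (set-1 scale) at n = 400, a desk-scale stand-in
for the full experimental table, with the target scaled so MAE values land
in the same 0.05-0.3 log-unit range as the real task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .curation import jouyban_acree_forward, lambda_h_forward, vanthoff3_forward
from .data_io import SIGMA_GRID, SolubilityCurve

__all__ = [
    "SyntheticSpec",
    "QsprTruth",
    "gen_qspr_table",
    "SigmaShape",
    "gen_sigma_curve",
    "GeneratedCurves",
    "gen_solubility_curves",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic QSPR table."""

    n_samples: int = 400
    n_informative: int = 5
    n_noise: int = 11
    n_solutes: int = 11
    nonlinearity: Literal["linear", "rbf-mixture"] = "rbf-mixture"
    noise_sd: float = 0.05
    solute_sd: float = 0.3
    target_scale: float = 1.0
    target_mean: float = -2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_solutes < 1:
            raise ValueError("n_solutes must be >= 1")
        if self.n_informative == 0:
            raise ValueError("n_informative must be >= 1 for any nonlinearity")
        if self.nonlinearity not in ("linear", "rbf-mixture"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise


@dataclass
class QsprTruth:
    """Planted ground truth accompanying a generated table."""

    informative: list[str]
    noise: list[str]
    oracle: Callable[[np.ndarray], np.ndarray]
    solute_offsets: dict[str, float]
    noise_sd: float
    params: dict = field(default_factory=dict)


def _rbf_mixture(rng: np.random.Generator, dim: int):
    """Three seeded Gaussian bumps over the informative subspace."""
    centers = rng.normal(size=(3, dim))
    amps = rng.uniform(1.0, 2.0, size=3) * rng.choice([-1.0, 1.0], size=3)
    ls2 = float(dim)  # length-scale^2 matched to the subspace dimension

    def f(xi: np.ndarray) -> np.ndarray:
        d2 = ((xi[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return (amps * np.exp(-d2 / (2.0 * ls2))).sum(axis=1)

    return f, {"centers": centers.tolist(), "amplitudes": amps.tolist(), "ls2": ls2}


def gen_qspr_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, QsprTruth]:
    """Generate one grouped feature table with a planted target.

    Returns ``(table, truth)``: the table holds ``solute_id``, the feature
    columns ``x00..`` and the target column ``log_x``; the truth names the
    informative subset and exposes a noise-free oracle on the full feature
    matrix (column order as in the table).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    names = [f"x{i:02d}" for i in range(p)]
    informative_idx = np.sort(rng.choice(p, size=spec.n_informative, replace=False))

    X = rng.normal(size=(spec.n_samples, p))
    if spec.nonlinearity == "linear":
        w = rng.uniform(0.5, 1.5, size=spec.n_informative) * rng.choice(
            [-1.0, 1.0], size=spec.n_informative
        )
        core = lambda xi: xi @ w  # noqa: E731
        params = {"weights": w.tolist()}
    else:
        core, params = _rbf_mixture(rng, spec.n_informative)

    raw = core(X[:, informative_idx])
    mu, sd = float(raw.mean()), float(raw.std())
    if sd == 0:
        raise ValueError("degenerate target: oracle is constant on the sample")
    scale = spec.target_scale / sd

    solutes = [f"S{k:02d}" for k in range(spec.n_solutes)]
    offsets = dict(zip(solutes, rng.normal(0.0, spec.solute_sd, size=spec.n_solutes)))
    assignment = rng.integers(spec.n_solutes, size=spec.n_samples)
    offset_col = np.array([offsets[solutes[k]] for k in assignment])

    y = (
        spec.target_mean
        + (raw - mu) * scale
        + offset_col
        + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    )

    table = pd.DataFrame(X, columns=names)
    table.insert(0, "solute_id", [solutes[k] for k in assignment])
    table["log_x"] = y

    def oracle(features: np.ndarray) -> np.ndarray:
        """Noise-free target surface (without solute offsets)."""
        arr = np.asarray(features, dtype=float)
        return spec.target_mean + (core(arr[:, informative_idx]) - mu) * scale

    truth = QsprTruth(
        informative=[names[i] for i in informative_idx],
        noise=[n for i, n in enumerate(names) if i not in set(informative_idx.tolist())],
        oracle=oracle,
        solute_offsets=offsets,
        noise_sd=spec.noise_sd,
        params=params,
    )
    return table, truth


@dataclass(frozen=True)
class SigmaShape:
    """Parabola-plus-wings shape of a synthetic sigma-potential curve."""

    base: float = 0.0
    slope: float = 0.0
    curvature: float = 1.0
    wing_neg: float = 0.0
    wing_pos: float = 0.0
    jitter_sd: float = 0.0


def gen_sigma_curve(shape: SigmaShape = SigmaShape(), seed: int = 0) -> np.ndarray:
    """Evaluate a smooth sigma-potential curve on the fixed 61-point grid.

    A central parabola (hydrophobic region) with Gaussian "wings" near
    +/-0.02 e/A^2 mimicking donor/acceptor affinity peaks, plus optional
    seeded jitter.
    """
    s = SIGMA_GRID / 0.03
    curve = (
        shape.base
        + shape.slope * s
        + shape.curvature * s**2
        + shape.wing_neg * np.exp(-(((SIGMA_GRID + 0.02) / 0.005) ** 2))
        + shape.wing_pos * np.exp(-(((SIGMA_GRID - 0.02) / 0.005) ** 2))
    )
    if shape.jitter_sd > 0:
        curve = curve + np.random.default_rng(seed).normal(0, shape.jitter_sd, size=61)
    return curve


@dataclass
class GeneratedCurves:
    curves: list[SolubilityCurve]
    truth: dict


def gen_solubility_curves(
    model: Literal["lh", "vh3", "ja"],
    params: dict,
    design: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    solute_id: str = "SYN",
) -> GeneratedCurves:
    """Forward-model solubility curves with seeded Gaussian noise on ln x.

    * ``lh``: params ``{lam, h, t_m}``, design = temperatures (K); the curve
      lives at x2_star = 0 (a neat solvent).
    * ``vh3``: params ``{a, b, c}``, design = temperatures (K).
    * ``ja``: params ``{j0, j1, j2, ln_x1, ln_x2, T}``, design = w1 grid
      (fraction of solvent 1); stored with x2_star = 1 - w1.
    """
    rng = np.random.default_rng(seed)
    pts = []
    if model == "lh":
        for T in design:
            x = lambda_h_forward(params["lam"], params["h"], params["t_m"], T)
            pts.append((float(T), 0.0, x))
    elif model == "vh3":
        for T in design:
            lnx = vanthoff3_forward(params["a"], params["b"], params["c"], T)
            if lnx > 0:
                raise ValueError(f"VH3 parameters give x > 1 at T={T}")
            pts.append((float(T), 0.0, math.exp(lnx)))
    elif model == "ja":
        j = (params["j0"], params["j1"], params["j2"])
        T = params["T"]
        for w1 in design:
            lnx = jouyban_acree_forward(j, w1, params["ln_x1"], params["ln_x2"], T)
            pts.append((float(T), 1.0 - float(w1), math.exp(lnx)))
    else:
        raise ValueError(f"unknown model {model!r}")

    noisy = []
    for t, x2, x in pts:
        lnx = math.log(x) + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        noisy.append((t, x2, min(math.exp(lnx), 1.0)))
    curve = SolubilityCurve(solute_id, "solv1", "solv2", tuple(noisy))
    return GeneratedCurves(curves=[curve], truth={"model": model, "params": dict(params)})
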