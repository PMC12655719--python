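"""Typed readers and writers for component, mixture and solubility-curve
tables and for JSON run artifacts.

All tabular interchange is plain CSV (comma separator, UTF-8, ``.`` decimal,
mandatory header).  Solubility is carried as the decadic logarithm of the
solute mole fraction; energies and chemical potentials are carried in the
units of the source tables (kcal/mol by convention) and never converted.

The sigma-potential charge-density grid is fixed and implicit: 61 points from
-0.03 to +0.03 e/A^2 in steps of 0.001.  Files store only the 61 values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of points of the fixed sigma-potential grid.
SIGMA_GRID_SIZE = 61

#: The implicit charge-density grid (e/A^2) the sigma-potential is sampled on.
SIGMA_GRID = np.round(-0.03 + 0.001 * np.arange(SIGMA_GRID_SIZE), 6)

ARTIFACT_VERSION = 1


class SchemaError(ValueError):
    """A table or artifact does not match its declared schema."""


class RowError(ValueError):
    """A single row failed validation; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

ENERGY_FIELDS = ("e_int", "e_misfit", "e_hb", "e_vdw", "mu")


@dataclass(frozen=True)
class ComponentDescriptors:
    """Per-molecule COSMO-RS energies and chemical potential.

    Parameters
    ----------
    molecule_id
        Identifier of the molecule (solute or solvent component).
    e_int, e_misfit, e_hb, e_vdw
        Total intermolecular interaction energy and its electrostatic-misfit,
        hydrogen-bonding and van der Waals components.
    mu
        Chemical potential of the molecule in solution.
    sigma_potential
        Optional 61-point sigma-potential curve on the fixed grid.
    """

    molecule_id: str
    e_int: float
    e_misfit: float
    e_hb: float
    e_vdw: float
    mu: float
    sigma_potential: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        for name in ENERGY_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{self.molecule_id}: non-finite {name}={v!r}")
        if self.sigma_potential is not None:
            sp = tuple(float(v) for v in self.sigma_potential)
            if len(sp) != SIGMA_GRID_SIZE:
                raise SchemaError(
                    f"{self.molecule_id}: sigma_potential has {len(sp)} points, "
                    f"expected {SIGMA_GRID_SIZE}"
                )
            if not all(math.isfinite(v) for v in sp):
                raise ValueError(f"{self.molecule_id}: non-finite sigma value")
            object.__setattr__(self, "sigma_potential", sp)

    def energies(self) -> np.ndarray:
        """The five energy/potential fields as an ordered vector."""
        return np.array([getattr(self, f) for f in ENERGY_FIELDS], dtype=float)


@dataclass(frozen=True)
class MixtureRecord:
    """One (solute, solvent pair, composition, temperature) observation.

    ``x2_star`` is the mole fraction of the second (organic) solvent in the
    solute-free binary mixture.  ``log_x_exp`` may be ``None`` for
    prediction-only rows.  Log-solubilities are decadic logs of the solute
    mole fraction and hence never positive.
    """

    solute_id: str
    solvent1_id: str
    solvent2_id: str
    x2_star: float
    temperature: float
    log_x_exp: Optional[float]
    log_x_cosmo: float
    category: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.x2_star <= 1.0:
            raise ValueError(f"x2_star={self.x2_star} outside [0, 1]")
        if not self.temperature > 0:
            raise ValueError(f"temperature={self.temperature} K must be > 0")
        for name in ("log_x_exp", "log_x_cosmo"):
            v = getattr(self, name)
            if v is not None and v > 0:
                raise ValueError(f"{name}={v} > 0 implies mole fraction > 1")
        if self.category is not None and self.category not in (1, 2, 3, 4):
            raise ValueError(f"category={self.category} not in 1..4")


@dataclass(frozen=True)
class SolubilityCurve:
    """Solubility of one solute in one binary solvent system.

    ``points`` are (temperature K, x2_star, x1) triples with x1 the solute
    mole-fraction solubility in (0, 1].
    """

    solute_id: str
    solvent1_id: str
    solvent2_id: str
    points: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.points:
            raise ValueError("curve has no points")
        seen = set()
        for t, x2, x1 in self.points:
            if not (0.0 < x1 <= 1.0):
                raise ValueError(f"x1={x1} outside (0, 1]")
            key = (round(t, 6), round(x2, 9))
            if key in seen:
                raise ValueError(f"duplicate (T, x2_star) point {key}")
            seen.add(key)
        object.__setattr__(
            self, "points", tuple((float(t), float(x2), float(x1)) for t, x2, x1 in self.points)
        )


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_COMPONENT_COLUMNS = ("molecule_id",) + ENERGY_FIELDS
_SIGMA_COLUMNS = tuple(f"sigma_{i:03d}" for i in range(SIGMA_GRID_SIZE))


def read_component_table(path) -> list[ComponentDescriptors]:
    """Read a per-molecule descriptor table.

    Expects columns ``molecule_id, e_int, e_misfit, e_hb, e_vdw, mu`` and
    optionally the full sigma block ``sigma_000 .. sigma_060``.  Sigma columns
    must be all present or all absent.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _COMPONENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    sigma_cols = [c for c in df.columns if c.startswith("sigma_")]
    if sigma_cols and len(sigma_cols) != SIGMA_GRID_SIZE:
        raise SchemaError(
            f"found {len(sigma_cols)} sigma columns, expected {SIGMA_GRID_SIZE}"
        )
    sigma_cols = list(_SIGMA_COLUMNS) if sigma_cols else []
    if sigma_cols:
        missing = [c for c in sigma_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"missing sigma column: {missing[0]}")

    records = []
    for i, row in df.iterrows():
        try:
            sigma = tuple(float(row[c]) for c in sigma_cols) if sigma_cols else None
            records.append(
                ComponentDescriptors(
                    molecule_id=str(row["molecule_id"]),
                    e_int=float(row["e_int"]),
                    e_misfit=float(row["e_misfit"]),
                    e_hb=float(row["e_hb"]),
                    e_vdw=float(row["e_vdw"]),
                    mu=float(row["mu"]),
                    sigma_potential=sigma,
                )
            )
        except SchemaError:
            raise
        except (ValueError, TypeError) as exc:
            raise RowError(int(i), str(exc)) from exc
    if not records:
        logger.warning("component table %s is empty", path)
    return records


_MIXTURE_COLUMNS = (
    "solute_id",
    "solvent1_id",
    "solvent2_id",
    "x2_star",
    "temperature_K",
    "log_x_exp",
    "log_x_cosmo",
    "category",
)


def read_mixture_table(path) -> list[MixtureRecord]:
    """Read a mixture observation table.

    Rows with an empty ``log_x_exp`` load as prediction-only records; empty
    ``category`` loads as absent.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _MIXTURE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    records = []
    for i, row in df.iterrows():
        try:
            log_x_exp = None if pd.isna(row["log_x_exp"]) else float(row["log_x_exp"])
            category = None if pd.isna(row["category"]) else int(row["category"])
            records.append(
                MixtureRecord(
                    solute_id=str(row["solute_id"]),
                    solvent1_id=str(row["solvent1_id"]),
                    solvent2_id=str(row["solvent2_id"]),
                    x2_star=float(row["x2_star"]),
                    temperature=float(row["temperature_K"]),
                    log_x_exp=log_x_exp,
                    log_x_cosmo=float(row["log_x_cosmo"]),
                    category=category,
                )
            )
        except (ValueError, TypeError) as exc:
            raise RowError(int(i), str(exc)) from exc
    if not records:
        logger.warning("mixture table %s has a header but no rows", path)
    return records


def read_solubility_curves(path) -> list[SolubilityCurve]:
    """Read raw solubility curves from a long-format CSV.

    Columns: ``solute_id, solvent1_id, solvent2_id, temperature_K, x2_star,
    x1``.  One curve is formed per (solute, solvent1, solvent2) system.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ("solute_id", "solvent1_id", "solvent2_id", "temperature_K", "x2_star", "x1")
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    curves = []
    for (sol, s1, s2), grp in df.groupby(
        ["solute_id", "solvent1_id", "solvent2_id"], sort=True
    ):
        pts = tuple(
            (float(r["temperature_K"]), float(r["x2_star"]), float(r["x1"]))
            for _, r in grp.iterrows()
        )
        curves.append(SolubilityCurve(str(sol), str(s1), str(s2), pts))
    return curves


# ---------------------------------------------------------------------------
# CSV writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def write_component_table(records: Sequence[ComponentDescriptors], path) -> None:
    rows = []
    has_sigma = [r.sigma_potential is not None for r in records]
    if any(has_sigma) and not all(has_sigma):
        raise SchemaError("sigma_potential must be present on all records or none")
    for r in records:
        row = {"molecule_id": r.molecule_id}
        row.update({f: getattr(r, f) for f in ENERGY_FIELDS})
        if r.sigma_potential is not None:
            row.update(dict(zip(_SIGMA_COLUMNS, r.sigma_potential)))
        rows.append(row)
    cols = list(_COMPONENT_COLUMNS) + (list(_SIGMA_COLUMNS) if all(has_sigma) and records else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_mixture_table(records: Sequence[MixtureRecord], path) -> None:
    rows = [
        {
            "solute_id": r.solute_id,
            "solvent1_id": r.solvent1_id,
            "solvent2_id": r.solvent2_id,
            "x2_star": r.x2_star,
            "temperature_K": r.temperature,
            "log_x_exp": r.log_x_exp,
            "log_x_cosmo": r.log_x_cosmo,
            "category": r.category,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_MIXTURE_COLUMNS)).to_csv(path, index=False)


def write_solubility_curves(curves: Sequence[SolubilityCurve], path) -> None:
    rows = []
    for c in curves:
        for t, x2, x1 in c.points:
            rows.append(
                {
                    "solute_id": c.solute_id,
                    "solvent1_id": c.solvent1_id,
                    "solvent2_id": c.solvent2_id,
                    "temperature_K": t,
                    "x2_star": x2,
                    "x1": x1,
                }
            )
    pd.DataFrame(
        rows,
        columns=["solute_id", "solvent1_id", "solvent2_id", "temperature_K", "x2_star", "x1"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run artifacts (JSON)
# ---------------------------------------------------------------------------


@dataclass
class RunArtifact:
    """Everything needed to reproduce and audit one optimisation run."""

    run_id: str
    seed: int
    pool_name: str
    config: dict
    trials: list = field(default_factory=list)
    pruning_trace: list = field(default_factory=list)
    train_indices: list = field(default_factory=list)
    test_indices: list = field(default_factory=list)


_ARTIFACT_FIELDS = (
    "run_id",
    "seed",
    "pool_name",
    "config",
    "trials",
    "pruning_trace",
    "train_indices",
    "test_indices",
)


def write_run_artifact(artifact: RunArtifact, path) -> None:
    """Serialize a run artifact to JSON.

    Floats go through ``repr`` (17 significant digits), so write->read is the
    identity on every field.
    """
    payload = {"version": ARTIFACT_VERSION}
    payload.update(asdict(artifact))
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_run_artifact(path) -> RunArtifact:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    version = payload.get("version")
    if version != ARTIFACT_VERSION:
        raise SchemaError(
            f"artifact version mismatch: file has {version!r}, "
            f"reader supports {ARTIFACT_VERSION}"
        )
    for name in _ARTIFACT_FIELDS:
        if name not in payload:
            raise SchemaError(f"missing field: {name}")
    return RunArtifact(**{k: payload[k] for k in _ARTIFACT_FIELDS})
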