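"""Descriptor construction for solutes in binary solvent mixtures.

Each mixture observation is turned into a fixed-order feature vector built
from per-molecule COSMO-RS quantities:

* set 1 (16 features): the COSMO-RS-predicted log-solubility, the solute's
  five energies/chemical potential, the mole-fraction-weighted solvent
  values, and the solute-minus-solvent differences;
* set 2 (28 features): set 1 plus twelve condensed sigma-potential bins.

The sigma-potential (61 points on -0.03..+0.03 e/A^2) is condensed by
averaging over 0.005 e/A^2 intervals into a 12-step function covering the
hydrogen-bond-donor (HBD1-4), hydrophobic (HH1-4) and hydrogen-bond-acceptor
(HBA1-4) regions of the sigma axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .data_io import (
    SIGMA_GRID_SIZE,
    ComponentDescriptors,
    ENERGY_FIELDS,
    MixtureRecord,
)

__all__ = [
    "SigmaBins",
    "SIGMA_BIN_NAMES",
    "weight_solvent_descriptors",
    "diff_descriptors",
    "bin_sigma_potential",
    "build_features",
    "build_feature_table",
    "set1_feature_names",
    "set2_feature_names",
]

#: Bin names in fixed order from sigma = -0.03 to +0.03 e/A^2.
SIGMA_BIN_NAMES = (
    "hbd1", "hbd2", "hbd3", "hbd4",
    "hh1", "hh2", "hh3", "hh4",
    "hba1", "hba2", "hba3", "hba4",
)

N_SIGMA_BINS = 12

# Grid point k (sigma = -0.03 + 0.001 k) belongs to half-open bin
# [-0.03 + 0.005 j, -0.03 + 0.005 (j+1)); the single point at exactly +0.03
# closes the last bin, which therefore holds 6 points instead of 5.
_BIN_OF_POINT = np.minimum(np.arange(SIGMA_GRID_SIZE) // 5, N_SIGMA_BINS - 1)

SigmaBlock = Literal["api", "solvent", "difference"]
DiffMode = Literal["difference", "ratio"]


@dataclass(frozen=True)
class SigmaBins:
    """Twelve condensed sigma-potential values (HBD1-4, HH1-4, HBA1-4)."""

    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != N_SIGMA_BINS:
            raise ValueError(f"expected {N_SIGMA_BINS} bins, got {len(self.values)}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SIGMA_BIN_NAMES, self.values))


def bin_sigma_potential(sigma: Sequence[float]) -> SigmaBins:
    """Condense a 61-point sigma-potential curve into 12 interval means."""
    arr = np.asarray(sigma, dtype=float)
    if arr.shape != (SIGMA_GRID_SIZE,):
        raise ValueError(
            f"sigma series has length {arr.size}, expected {SIGMA_GRID_SIZE}"
        )
    sums = np.bincount(_BIN_OF_POINT, weights=arr, minlength=N_SIGMA_BINS)
    counts = np.bincount(_BIN_OF_POINT, minlength=N_SIGMA_BINS)
    return SigmaBins(tuple(sums / counts))


def weight_solvent_descriptors(
    comp1: ComponentDescriptors,
    comp2: ComponentDescriptors,
    x2_star: float,
) -> ComponentDescriptors:
    """Mole-fraction-weighted average of two solvent components.

    Every field (and the sigma curve, element-wise, when present) is blended
    as ``(1 - x2_star) * comp1 + x2_star * comp2``.
    """
    if not 0.0 <= x2_star <= 1.0:
        raise ValueError(f"x2_star={x2_star} outside [0, 1]")
    has1, has2 = comp1.sigma_potential is not None, comp2.sigma_potential is not None
    if has1 != has2:
        raise ValueError(
            "sigma_potential present on only one solvent component "
            f"({comp1.molecule_id!r} vs {comp2.molecule_id!r})"
        )
    w1 = 1.0 - x2_star
    blend = lambda a, b: w1 * a + x2_star * b  # noqa: E731
    sigma = None
    if has1:
        sigma = tuple(
            blend(a, b) for a, b in zip(comp1.sigma_potential, comp2.sigma_potential)
        )
    return ComponentDescriptors(
        molecule_id=f"{comp1.molecule_id}+{comp2.molecule_id}@{x2_star:g}",
        **{f: blend(getattr(comp1, f), getattr(comp2, f)) for f in ENERGY_FIELDS},
        sigma_potential=sigma,
    )


def diff_descriptors(
    api: ComponentDescriptors,
    solvent_mix: ComponentDescriptors,
    mode: DiffMode = "difference",
) -> np.ndarray:
    """Solute-vs-solvent contrast of the five energy fields.

    The default is the arithmetic difference (solute minus solvent); ratio
    mode divides instead and is exploratory only (ill-defined near zero).
    """
    a = api.energies()
    s = solvent_mix.energies()
    if mode == "difference":
        return a - s
    if mode == "ratio":
        return a / s
    raise ValueError(f"unknown diff mode {mode!r}")


def set1_feature_names() -> list[str]:
    names = ["log_x_cosmo"]
    names += [f"{f}_api" for f in ENERGY_FIELDS]
    names += [f"{f}_solv" for f in ENERGY_FIELDS]
    names += [f"d_{f}" for f in ENERGY_FIELDS]
    return names


_SIGMA_PREFIX = {"api": "sigma_{}_api", "solvent": "sigma_{}_solv", "difference": "d_sigma_{}"}


def set2_feature_names(sigma_block: SigmaBlock = "difference") -> list[str]:
    fmt = _SIGMA_PREFIX[sigma_block]
    return set1_feature_names() + [fmt.format(b) for b in SIGMA_BIN_NAMES]


def build_features(
    record: MixtureRecord,
    components: Mapping[str, ComponentDescriptors],
    set_name: Literal["set1", "set2"],
    sigma_block: SigmaBlock = "difference",
    diff_mode: DiffMode = "difference",
) -> dict[str, float]:
    """Assemble the ordered feature vector for one mixture observation.

    Returns a name -> value mapping with deterministic insertion order:
    16 entries for ``set1`` and 28 for ``set2``.  For set 2 all 36 sigma-bin
    descriptors (solute, blended solvent, difference) are computed internally
    and ``sigma_block`` selects which 12 are appended.
    """
    try:
        api = components[record.solute_id]
        comp1 = components[record.solvent1_id]
        comp2 = components[record.solvent2_id]
    except KeyError as exc:
        raise KeyError(f"unknown molecule id {exc.args[0]!r}") from exc

    solvent = weight_solvent_descriptors(comp1, comp2, record.x2_star)
    diffs = diff_descriptors(api, solvent, mode=diff_mode)

    features: dict[str, float] = {"log_x_cosmo": record.log_x_cosmo}
    for f in ENERGY_FIELDS:
        features[f"{f}_api"] = getattr(api, f)
    for f in ENERGY_FIELDS:
        features[f"{f}_solv"] = getattr(solvent, f)
    for f, d in zip(ENERGY_FIELDS, diffs):
        features[f"d_{f}"] = float(d)

    if set_name == "set1":
        return features
    if set_name != "set2":
        raise ValueError(f"unknown descriptor set {set_name!r}")

    if api.sigma_potential is None or solvent.sigma_potential is None:
        raise ValueError(
            "set2 requires sigma_potential curves on the solute and both "
            "solvent components"
        )
    api_bins = np.array(bin_sigma_potential(api.sigma_potential).values)
    solv_bins = np.array(bin_sigma_potential(solvent.sigma_potential).values)
    blocks = {
        "api": api_bins,
        "solvent": solv_bins,
        "difference": api_bins - solv_bins,
    }
    fmt = _SIGMA_PREFIX[sigma_block]
    for name, value in zip(SIGMA_BIN_NAMES, blocks[sigma_block]):
        features[fmt.format(name)] = float(value)
    return features


def build_feature_table(
    records: Sequence[MixtureRecord],
    components: Mapping[str, ComponentDescriptors],
    set_name: Literal["set1", "set2"],
    sigma_block: SigmaBlock = "difference",
    diff_mode: DiffMode = "difference",
):
    """Vectorize ``build_features`` over records into a pandas DataFrame.

    The output carries the mixture key columns, the feature columns in their
    canonical order, and ``log_x_exp`` (NaN for prediction-only rows).
    """
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "solute_id": r.solute_id,
            "solvent1_id": r.solvent1_id,
            "solvent2_id": r.solvent2_id,
            "x2_star": r.x2_star,
            "temperature_K": r.temperature,
        }
        row.update(build_features(r, components, set_name, sigma_block, diff_mode))
        row["log_x_exp"] = np.nan if r.log_x_exp is None else r.log_x_exp
        rows.append(row)
    return pd.DataFrame(rows)
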