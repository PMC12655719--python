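"""Cross-run stability analysis and champion selection.

The pruning loop is deliberately repeated over many independent train/test
splits; a single run is too sensitive to the split to trust.  Aggregation
proceeds in two tiers:

1. *architecture*: each run votes for one feature count (the smallest count
   whose test MAE sits within one standard error of the run's best); counts
   that recur in at least 30% of runs and whose mean test MAE lies within
   one cross-run standard error of the global minimum are admissible, and
   the admissible count with the best mean test MAE (ties: smaller) becomes
   the architecture;
2. *champion*: among the voted candidates at that architecture, a composite
   score — 0.5 * accuracy + 0.3 * explanatory power (R^2) + 0.2 *
   generalization (negative train/test gap), each min-max normalized over
   the pool — picks the single deployed model.  Ties favour candidates
   whose descriptors recur most across runs, then lower test MAE.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .doo_core import CandidateModel, PruningTrace

__all__ = [
    "StabilityReport",
    "run_level_choice",
    "aggregate",
    "composite_score",
    "select_champion",
]

DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)


@dataclass
class StabilityReport:
    """Cross-run aggregation of pruning traces."""

    count_rows: list = field(default_factory=list)  # per-feature-count stats
    global_min_mae: float = float("nan")
    global_min_se: float = float("nan")
    admissible_counts: list = field(default_factory=list)
    architecture: int = -1
    descriptor_frequencies: dict = field(default_factory=dict)
    champion: CandidateModel | None = None
    champion_score: float = float("nan")


def run_level_choice(trace: PruningTrace) -> CandidateModel:
    """The feature count one run votes for.

    Within the run's trace, take the candidate with the minimal test MAE and
    its per-fold standard error; return the candidate with the fewest
    features whose test MAE is within that band (the parsimony-within-1-SE
    rule applied at run level).
    """
    cands = trace.candidates
    if not cands:
        raise ValueError("empty pruning trace")
    best = min(cands, key=lambda c: c.mae_test)
    threshold = best.mae_test + best.cv_mae_se
    band = [c for c in cands if c.mae_test <= threshold]
    return min(band, key=lambda c: (len(c.feature_names), c.mae_test))


def aggregate(
    choices: Sequence[CandidateModel],
    freq_threshold: float = 0.30,
) -> StabilityReport:
    """Stability analysis over the per-run choices.

    A count is admissible when its vote frequency reaches ``freq_threshold``
    and its mean test MAE is within one cross-run standard error of the
    global minimum mean.  The architecture is the admissible count with the
    best mean test MAE (ties -> smaller count).
    """
    choices = list(choices)
    if len(choices) < 2:
        raise ValueError("need >= 2 runs to form a cross-run standard error")
    n_runs = len(choices)
    counts = [len(c.feature_names) for c in choices]
    freq = Counter(counts)

    rows = []
    for count in sorted(freq):
        sub = [c for c in choices if len(c.feature_names) == count]
        maes = np.array([c.mae_test for c in sub])
        rows.append(
            {
                "count": count,
                "frequency": freq[count] / n_runs,
                "n_runs": len(sub),
                "mean_mae_test": float(maes.mean()),
                "sd_mae_test": float(maes.std(ddof=1)) if len(sub) > 1 else 0.0,
                "mean_mae_train": float(np.mean([c.mae_train for c in sub])),
            }
        )

    all_maes = np.array([c.mae_test for c in choices])
    global_min = min(r["mean_mae_test"] for r in rows)
    se = float(all_maes.std(ddof=1) / np.sqrt(n_runs))

    admissible = [
        r["count"]
        for r in rows
        if r["frequency"] >= freq_threshold
        and r["mean_mae_test"] <= global_min + se
    ]
    if not admissible:
        raise ValueError(
            "no feature count is both frequent and accurate enough; "
            f"consider relaxing freq_threshold={freq_threshold}"
        )
    by_count = {r["count"]: r for r in rows}
    architecture = min(admissible, key=lambda c: (by_count[c]["mean_mae_test"], c))

    at_arch = [c for c in choices if len(c.feature_names) == architecture]
    desc_freq = Counter(f for c in at_arch for f in c.feature_names)
    frequencies = {f: desc_freq[f] / len(at_arch) for f in sorted(desc_freq)}

    report = StabilityReport(
        count_rows=rows,
        global_min_mae=global_min,
        global_min_se=se,
        admissible_counts=sorted(admissible),
        architecture=architecture,
        descriptor_frequencies=frequencies,
    )
    champion, score = select_champion(at_arch, frequencies)
    report.champion = champion
    report.champion_score = score
    return report


def _normalize(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        # degenerate component: contributes its weight equally to everyone
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def composite_score(
    candidates: Sequence[CandidateModel],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> np.ndarray:
    """Composite deployment score for each candidate in a pool.

    ``score = w1*norm(-mae_test) + w2*norm(r2_test) + w3*norm(-|gap|)``
    with min-max normalization over the pool, so scores lie in [0, 1]
    (when weights sum to 1) and are only comparable within one pool.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need a pool of >= 2 candidates for normalization")
    acc = _normalize(-np.array([c.mae_test for c in candidates]))
    expl = _normalize(np.array([c.r2_test for c in candidates]))
    gap = _normalize(-np.abs([c.mae_train - c.mae_test for c in candidates]))
    w1, w2, w3 = weights
    return w1 * acc + w2 * expl + w3 * gap


def select_champion(
    candidates: Sequence[CandidateModel],
    descriptor_frequencies: dict[str, float],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> tuple[CandidateModel, float]:
    """Highest-composite-score candidate at the chosen architecture.

    Ties break toward the candidate whose descriptors recur most across
    runs (summed per-descriptor frequency), then toward lower test MAE.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates at the chosen architecture")
    if len(candidates) == 1:
        return candidates[0], 1.0
    scores = composite_score(candidates, weights)
    stab = [
        sum(descriptor_frequencies.get(f, 0.0) for f in c.feature_names)
        for c in candidates
    ]
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], -stab[i], candidates[i].mae_test),
    )
    best = order[0]
    return candidates[best], float(scores[best])
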