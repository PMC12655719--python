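"""Dual-objective nuSVR model search with iterative backward feature pruning.

One run works on a fixed 80/20 train/test split and proceeds level by level:

1. a dual-objective hyperparameter search over (nu, C, log10 gamma scale)
   scores each trial by 5-fold cross-validated MAE and by the mean
   support-vector ratio (support vectors / fold-training samples), the
   intrinsic complexity measure of a nuSVR model;
2. the Pareto front of non-dominated trials is extracted and the
   one-standard-error rule picks the simplest front member whose CV MAE is
   within one standard error of the best;
3. the chosen candidate is refit, its features are ranked by permutation
   importance (10 repeats, out-of-fold), and the least important feature is
   dropped; the cycle repeats on the reduced pool until ``min_features``.

The RBF kernel width is anchored per fold: ``gamma = gamma_base * 10**s``
with ``gamma_base = 1 / median(pairwise squared Euclidean distance)`` of the
standardized fold-training matrix, and the search tunes only the logarithmic
scale factor ``s``.  Standardization and the gamma anchor are always computed
on fold-training rows only — held-out rows never enter either computation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.model_selection import KFold
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVR

logger = logging.getLogger(__name__)

# Iteration cap for the libsvm solver.  Configurations worth keeping converge
# in ~1e3 iterations at these problem sizes; the cap only truncates
# pathological corners of the search box (huge C with a wide kernel), which
# would otherwise dominate wall time while yielding dominated trials anyway.
SVR_MAX_ITER = 5_000


def _make_svr(nu: float, c: float, gamma: float) -> NuSVR:
    return NuSVR(nu=nu, C=c, gamma=gamma, kernel="rbf", max_iter=SVR_MAX_ITER)


def _fit_svr(svr: NuSVR, X, y) -> NuSVR:
    # early termination at the iteration cap is deliberate policy, not a
    # user-actionable condition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return svr.fit(X, y)

__all__ = [
    "HyperBox",
    "TrialResult",
    "CandidateModel",
    "PruningTrace",
    "RunSeeds",
    "split_train_test",
    "Standardizer",
    "standardize",
    "gamma_base",
    "evaluate_trial",
    "run_doo",
    "pareto_front",
    "select_1se",
    "permutation_importance",
    "run_dooit",
    "execute_run",
    "trace_from_artifact",
    "loco_splits",
]

# Optional audit callback: called as audit_hook(kind, matrix) from inside
# standardize()/gamma_base() so tests can verify held-out rows never reach
# either computation.  Never set in production code.
audit_hook: Optional[Callable[[str, np.ndarray], None]] = None


@dataclass(frozen=True)
class HyperBox:
    """Search box for the three tuned hyperparameters.

    nu is uniform on [nu_lo, nu_hi); C is log-uniform on [c_lo, c_hi];
    the gamma scale is uniform on [scale_lo, scale_hi] in log10 units.
    """

    nu_lo: float = 0.01
    nu_hi: float = 1.0
    c_lo: float = 1e-2
    c_hi: float = 1e3
    scale_lo: float = -2.0
    scale_hi: float = 2.0


@dataclass
class TrialResult:
    """One evaluated hyperparameter triple with its two objectives."""

    trial_id: int
    nu: float
    c: float
    log10_gamma_scale: float
    gamma: float = math.nan
    cv_mae: float = math.nan
    cv_mae_se: float = math.nan
    sv_ratio: float = math.nan
    folds: list = field(default_factory=list)
    failed: bool = False
    error: Optional[str] = None


@dataclass
class CandidateModel:
    """The 1-SE-selected model at one feature count, with refit metrics."""

    feature_names: list
    nu: float
    c: float
    log10_gamma_scale: float
    cv_mae: float
    cv_mae_se: float
    sv_ratio: float
    trial_id: int
    importances: dict
    importance_repeats: dict
    mae_train: float
    mae_test: float
    r2_test: float
    eliminated: Optional[str] = None


@dataclass
class PruningTrace:
    """Per-run sequence of candidates from the full pool down to the floor."""

    candidates: list = field(default_factory=list)

    def as_dicts(self) -> list[dict]:
        return [asdict(c) for c in self.candidates]


@dataclass(frozen=True)
class RunSeeds:
    """The independent random streams of one run."""

    sampler: int
    folds: int
    permutation: int

    @classmethod
    def from_master(cls, seed: int) -> "RunSeeds":
        ss = np.random.SeedSequence(seed)
        s = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
        return cls(sampler=s[0], folds=s[1], permutation=s[2])


# ---------------------------------------------------------------------------
# Splitting, scaling, gamma anchor
# ---------------------------------------------------------------------------


def split_train_test(n: int, test_fraction: float = 0.2, seed: int = 0):
    """Random disjoint train/test partition with |test| = round(f * n)."""
    if n < 10:
        raise ValueError(f"n={n} too small to split (need >= 10)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return train, test


class Standardizer:
    """Frozen column-wise z-scoring (mean 0, unit population variance)."""

    def __init__(self, mean: np.ndarray, scale: np.ndarray, columns=None):
        self.mean_ = mean
        self.scale_ = scale
        self.columns = columns

    def transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        return (arr - self.mean_) / self.scale_


def standardize(X, columns=None) -> tuple[Standardizer, np.ndarray]:
    """Fit a z-scoring transform on the training matrix and apply it.

    Raises on zero-variance columns (naming the column) because they cannot
    be scaled to unit variance.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
    arr = np.asarray(X, dtype=float)
    if audit_hook is not None:
        audit_hook("standardize", arr)
    mean = arr.mean(axis=0)
    scale = arr.std(axis=0)  # population variance, as StandardScaler does
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        name = columns[zero[0]] if columns is not None else f"column {zero[0]}"
        raise ValueError(f"zero-variance column: {name}")
    tf = Standardizer(mean, scale, columns)
    return tf, tf.transform(arr)


def gamma_base(X) -> float:
    """Anchor for the RBF width: 1 / median pairwise squared distance."""
    arr = np.asarray(X, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if audit_hook is not None:
        audit_hook("gamma_base", arr)
    med = float(np.median(pdist(arr, metric="sqeuclidean")))
    if med == 0.0:
        raise ValueError("median pairwise distance is 0 (duplicate rows only)")
    return 1.0 / med


# ---------------------------------------------------------------------------
# Trial evaluation
# ---------------------------------------------------------------------------


def _as_matrix(table, features):
    if isinstance(table, pd.DataFrame):
        return table.loc[:, list(features)].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


class _FoldCache:
    """Per-level cross-validation folds with frozen scalers and gamma anchors.

    The folds, the fold-train standardization and the gamma_base anchor do
    not depend on the trial's hyperparameters, so within one search level
    they are computed once and shared by every trial.  Standardization and
    gamma_base see fold-train rows only.
    """

    def __init__(self, table, target, features, k_folds: int, fold_seed: int):
        if not list(features):
            raise ValueError("feature subset is empty")
        X = _as_matrix(table, features)
        y = np.asarray(target, dtype=float)
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=fold_seed)
        self.folds = []
        for tr, va in kf.split(X):
            tf, Xtr = standardize(X[tr], columns=list(features))
            self.folds.append(
                {
                    "X_train": Xtr,
                    "y_train": y[tr],
                    "X_val": tf.transform(X[va]),
                    "y_val": y[va],
                    "gamma_base": gamma_base(Xtr),
                    "n_train": int(len(tr)),
                    "n_val": int(len(va)),
                }
            )

    def evaluate(self, nu, c, log10_gamma_scale, trial_id: int = 0) -> TrialResult:
        result = TrialResult(
            trial_id=trial_id, nu=float(nu), c=float(c),
            log10_gamma_scale=float(log10_gamma_scale),
        )
        try:
            maes, ratios, gammas = [], [], []
            for fold in self.folds:
                gamma = fold["gamma_base"] * 10.0 ** log10_gamma_scale
                svr = _make_svr(nu, c, gamma)
                _fit_svr(svr, fold["X_train"], fold["y_train"])
                pred = svr.predict(fold["X_val"])
                mae = float(np.mean(np.abs(pred - fold["y_val"])))
                ratio = float(len(svr.support_) / fold["n_train"])
                maes.append(mae)
                ratios.append(ratio)
                gammas.append(gamma)
                result.folds.append(
                    {"mae": mae, "sv_ratio": ratio, "gamma": gamma,
                     "n_train": fold["n_train"], "n_val": fold["n_val"]}
                )
            result.cv_mae = float(np.mean(maes))
            result.cv_mae_se = float(np.std(maes, ddof=1) / math.sqrt(len(maes)))
            result.sv_ratio = float(np.mean(ratios))
            result.gamma = float(np.mean(gammas))
        except Exception as exc:  # failed trials are excluded from the front
            result.failed = True
            result.error = f"{type(exc).__name__}: {exc}"
            logger.info("trial %d failed: %s", trial_id, result.error)
        return result


def evaluate_trial(
    table,
    target,
    features: Sequence[str],
    nu: float,
    c: float,
    log10_gamma_scale: float,
    k_folds: int = 5,
    fold_seed: int = 0,
    trial_id: int = 0,
) -> TrialResult:
    """Cross-validate one nuSVR configuration on the training table.

    Per fold: standardize on the fold-train part, anchor gamma to that
    fold's ``gamma_base``, fit, and record fold MAE and the support-vector
    ratio.  Objectives are the fold means; the MAE standard error is
    sd(fold MAEs)/sqrt(k).
    """
    cache = _FoldCache(table, target, features, k_folds, fold_seed)
    return cache.evaluate(nu, c, log10_gamma_scale, trial_id=trial_id)


# ---------------------------------------------------------------------------
# Samplers and the dual-objective search
# ---------------------------------------------------------------------------


class RandomSampler:
    """Plain seeded random proposer over the hyperparameter box."""

    def __init__(self, box: HyperBox, seed: int):
        self.box = box
        self.rng = np.random.default_rng(seed)

    def propose(self) -> tuple[float, float, float]:
        b = self.box
        nu = self.rng.uniform(b.nu_lo, b.nu_hi)
        c = 10.0 ** self.rng.uniform(math.log10(b.c_lo), math.log10(b.c_hi))
        scale = self.rng.uniform(b.scale_lo, b.scale_hi)
        return nu, c, scale

    def tell(self, trial: TrialResult) -> None:  # random search ignores history
        pass


class ParetoPerturbSampler:
    """Multi-objective-aware sequential proposer with random fallback.

    After a random warmup, proposals perturb a uniformly chosen member of
    the current non-dominated set (Gaussian jitter in nu, log10 C and the
    gamma scale), falling back to a fresh random draw with fixed
    probability.  Seeded and fully sequential.
    """

    def __init__(self, box: HyperBox, seed: int, n_warmup: int = 20,
                 p_random: float = 0.3):
        self.box = box
        self.rng = np.random.default_rng(seed)
        self.n_warmup = n_warmup
        self.p_random = p_random
        self._random = RandomSampler(box, seed=int(self.rng.integers(2**31)))
        self._front: list[TrialResult] = []
        self._seen = 0

    def propose(self) -> tuple[float, float, float]:
        if (
            self._seen < self.n_warmup
            or not self._front
            or self.rng.uniform() < self.p_random
        ):
            return self._random.propose()
        b = self.box
        base = self._front[self.rng.integers(len(self._front))]
        nu = float(np.clip(base.nu + self.rng.normal(0, 0.05),
                           b.nu_lo, np.nextafter(b.nu_hi, -np.inf)))
        logc = np.clip(math.log10(base.c) + self.rng.normal(0, 0.25),
                       math.log10(b.c_lo), math.log10(b.c_hi))
        scale = float(np.clip(base.log10_gamma_scale + self.rng.normal(0, 0.2),
                              b.scale_lo, b.scale_hi))
        return nu, float(10.0 ** logc), scale

    def tell(self, trial: TrialResult) -> None:
        self._seen += 1
        if trial.failed:
            return
        keep = [
            t for t in self._front
            if not (
                (trial.cv_mae <= t.cv_mae and trial.sv_ratio <= t.sv_ratio)
                and (trial.cv_mae < t.cv_mae or trial.sv_ratio < t.sv_ratio)
            )
        ]
        dominated = any(
            (t.cv_mae <= trial.cv_mae and t.sv_ratio <= trial.sv_ratio)
            and (t.cv_mae < trial.cv_mae or t.sv_ratio < trial.sv_ratio)
            for t in keep
        )
        if not dominated:
            keep.append(trial)
        self._front = keep


def make_sampler(name: str, box: HyperBox, seed: int):
    if name == "random":
        return RandomSampler(box, seed)
    if name == "pareto":
        return ParetoPerturbSampler(box, seed)
    raise ValueError(f"unknown sampler {name!r}")


def run_doo(
    table,
    target,
    pool: Sequence[str],
    n_trials: int = 2000,
    sampler_seed: int = 0,
    fold_seed: int = 0,
    k_folds: int = 5,
    box: HyperBox = HyperBox(),
    sampler: str = "pareto",
) -> list[TrialResult]:
    """One full dual-objective search over the hyperparameter box."""
    if not list(pool):
        raise ValueError("feature pool is empty")
    cache = _FoldCache(table, target, pool, k_folds, fold_seed)
    prop = make_sampler(sampler, box, sampler_seed)
    trials = []
    for i in range(n_trials):
        nu, c, scale = prop.propose()
        t = cache.evaluate(nu, c, scale, trial_id=i)
        prop.tell(t)
        trials.append(t)
        logger.debug("trial %d: nu=%.4f C=%.3g scale=%.3f mae=%.4f sv=%.3f",
                     i, nu, c, scale, t.cv_mae, t.sv_ratio)
    return trials


# ---------------------------------------------------------------------------
# Front extraction and 1-SE selection
# ---------------------------------------------------------------------------


def pareto_front(trials: Sequence[TrialResult]) -> list[TrialResult]:
    """Non-dominated trials under joint minimization of (CV MAE, SV ratio).

    A trial is dominated if some other trial is at least as good in both
    objectives and strictly better in one; exact duplicates on both
    objectives are therefore all retained.  Failed trials are excluded.
    """
    ok = [t for t in trials if not t.failed]
    if not ok:
        raise ValueError("no successful trials")
    mae = np.array([t.cv_mae for t in ok])
    sv = np.array([t.sv_ratio for t in ok])
    keep = []
    for i, t in enumerate(ok):
        dominated = np.any(
            (mae <= mae[i]) & (sv <= sv[i]) & ((mae < mae[i]) | (sv < sv[i]))
        )
        if not dominated:
            keep.append(t)
    return keep


def select_1se(front: Sequence[TrialResult]) -> TrialResult:
    """One-standard-error pick from a Pareto front.

    The threshold is the minimal CV MAE plus that trial's standard error;
    among front members within the threshold the one with the lowest SV
    ratio wins (ties: lower CV MAE, then lower trial id).
    """
    if not front:
        raise ValueError("empty front")
    best = min(front, key=lambda t: (t.cv_mae, t.trial_id))
    threshold = best.cv_mae + best.cv_mae_se
    band = [t for t in front if t.cv_mae <= threshold]
    return min(band, key=lambda t: (t.sv_ratio, t.cv_mae, t.trial_id))


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model,
    X_val: pd.DataFrame,
    y_val,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, dict]:
    """Mean MAE increase when one feature column is shuffled.

    ``importance[f] = mean over repeats of (MAE with column f permuted -
    baseline MAE)`` on the supplied validation data.  Returns, per feature,
    the per-repeat values and their mean.
    """
    if len(X_val) < 2:
        raise ValueError("validation set needs at least 2 rows")
    y = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(seed)
    base_pred = model.predict(X_val.to_numpy(dtype=float))
    baseline = float(np.mean(np.abs(base_pred - y)))
    out = {}
    arr = X_val.to_numpy(dtype=float)
    for j, name in enumerate(X_val.columns):
        repeats = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            Xp = arr.copy()
            Xp[:, j] = arr[perm, j]
            mae = float(np.mean(np.abs(model.predict(Xp) - y)))
            repeats.append(mae - baseline)
        out[name] = {"repeats": repeats, "mean": float(np.mean(repeats))}
    return out


class _Pipeline:
    """Frozen standardizer + fitted nuSVR, predicting from raw features."""

    def __init__(self, tf: Standardizer, svr: NuSVR):
        self.tf = tf
        self.svr = svr

    def predict(self, X) -> np.ndarray:
        return self.svr.predict(self.tf.transform(X))


class _OutOfFoldModel:
    """Routes each training row to the fold model that never saw it.

    Rows keep their positions, so a column permutation of the full training
    matrix is still scored out-of-fold by construction.
    """

    def __init__(self, fold_models: list, val_indices: list):
        self.fold_models = fold_models
        self.val_indices = val_indices

    def predict(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        pred = np.empty(arr.shape[0])
        for model, va in zip(self.fold_models, self.val_indices):
            pred[va] = model.predict(arr[va])
        return pred


def _fit_pipeline(X: np.ndarray, y: np.ndarray, nu, c, scale, columns) -> _Pipeline:
    tf, Xs = standardize(X, columns=columns)
    gamma = gamma_base(Xs) * 10.0 ** scale
    svr = _make_svr(nu, c, gamma)
    _fit_svr(svr, Xs, y)
    return _Pipeline(tf, svr)


def _oof_model(X, y, nu, c, scale, k_folds, fold_seed, columns) -> _OutOfFoldModel:
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=fold_seed)
    models, vals = [], []
    for tr, va in kf.split(X):
        models.append(_fit_pipeline(X[tr], y[tr], nu, c, scale, columns))
        vals.append(va)
    return _OutOfFoldModel(models, vals)


# ---------------------------------------------------------------------------
# The full pruning loop
# ---------------------------------------------------------------------------


def run_dooit(
    train_table: pd.DataFrame,
    train_target,
    test_table: pd.DataFrame,
    test_target,
    pool: Sequence[str],
    min_features: int = 5,
    n_trials: int = 2000,
    seeds: RunSeeds = RunSeeds(0, 0, 0),
    k_folds: int = 5,
    box: HyperBox = HyperBox(),
    sampler: str = "pareto",
    n_importance_repeats: int = 10,
) -> PruningTrace:
    """Iterative backward pruning from the full pool down to ``min_features``.

    At each feature count: full dual-objective search, Pareto front, 1-SE
    candidate, refit on the whole training split (metrics on the test
    split), out-of-fold permutation importance, and elimination of the
    least important feature.  The trace holds one candidate per count.
    """
    features = list(pool)
    if not len(features) > min_features >= 1:
        raise ValueError(
            f"need |pool| > min_features >= 1, got {len(features)} and {min_features}"
        )
    y_tr = np.asarray(train_target, dtype=float)
    y_te = np.asarray(test_target, dtype=float)
    trace = PruningTrace()
    for level in range(len(features) - min_features + 1):
        # decorrelate levels deterministically from the run's streams
        lv = lambda s: int(  # noqa: E731
            np.random.SeedSequence([s, level]).generate_state(1)[0] % (2**31)
        )
        try:
            trials = run_doo(
                train_table, y_tr, features, n_trials=n_trials,
                sampler_seed=lv(seeds.sampler), fold_seed=lv(seeds.folds),
                k_folds=k_folds, box=box, sampler=sampler,
            )
            front = pareto_front(trials)
            chosen = select_1se(front)

            X_tr = train_table.loc[:, features].to_numpy(dtype=float)
            X_te = test_table.loc[:, features].to_numpy(dtype=float)
            pipe = _fit_pipeline(
                X_tr, y_tr, chosen.nu, chosen.c, chosen.log10_gamma_scale, features
            )
            mae_train = float(np.mean(np.abs(pipe.predict(X_tr) - y_tr)))
            pred_te = pipe.predict(X_te)
            mae_test = float(np.mean(np.abs(pred_te - y_te)))
            ss_res = float(np.sum((pred_te - y_te) ** 2))
            ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
            r2_test = 1.0 - ss_res / ss_tot

            oof = _oof_model(
                X_tr, y_tr, chosen.nu, chosen.c, chosen.log10_gamma_scale,
                k_folds, lv(seeds.folds), features,
            )
            imps = permutation_importance(
                oof, pd.DataFrame(X_tr, columns=features), y_tr,
                n_repeats=n_importance_repeats, seed=lv(seeds.permutation),
            )
        except Exception as exc:
            raise RuntimeError(f"pruning level {level} ({len(features)} features) failed") from exc

        cand = CandidateModel(
            feature_names=list(features),
            nu=chosen.nu, c=chosen.c, log10_gamma_scale=chosen.log10_gamma_scale,
            cv_mae=chosen.cv_mae, cv_mae_se=chosen.cv_mae_se,
            sv_ratio=chosen.sv_ratio, trial_id=chosen.trial_id,
            importances={k: v["mean"] for k, v in imps.items()},
            importance_repeats={k: v["repeats"] for k, v in imps.items()},
            mae_train=mae_train, mae_test=mae_test, r2_test=r2_test,
        )
        if len(features) > min_features:
            worst = min(features, key=lambda f: (imps[f]["mean"], features.index(f)))
            cand.eliminated = worst
            logger.info(
                "level %d (%d features): mae_test=%.4f, dropping %s",
                level, len(features), mae_test, worst,
            )
            features = [f for f in features if f != worst]
        else:
            logger.info("level %d (%d features): mae_test=%.4f (floor reached)",
                        level, len(features), mae_test)
        trace.candidates.append(cand)
    return trace


def execute_run(
    table: pd.DataFrame,
    target_col: str,
    pool: Sequence[str],
    run_id: str = "run",
    seed: int = 0,
    test_fraction: float = 0.2,
    min_features: int = 5,
    n_trials: int = 2000,
    k_folds: int = 5,
    sampler: str = "pareto",
    config: Optional[dict] = None,
):
    """One complete run: split, prune, and package the results.

    All randomness (split, sampler, folds, permutations) derives from the
    single ``seed``.  Returns ``(RunArtifact, PruningTrace)``; the artifact
    round-trips through :func:`dooit.data_io.write_run_artifact`.
    """
    from .data_io import RunArtifact

    sub = table.dropna(subset=[target_col])
    ss = np.random.SeedSequence(seed)
    split_seed, run_master = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    train_idx, test_idx = split_train_test(len(sub), test_fraction, split_seed)
    seeds = RunSeeds.from_master(run_master)
    train = sub.iloc[train_idx]
    test = sub.iloc[test_idx]
    trace = run_dooit(
        train.loc[:, list(pool)], train[target_col],
        test.loc[:, list(pool)], test[target_col],
        pool, min_features=min_features, n_trials=n_trials,
        seeds=seeds, k_folds=k_folds, sampler=sampler,
    )
    artifact = RunArtifact(
        run_id=run_id,
        seed=seed,
        pool_name=",".join(pool),
        config=dict(config or {}, test_fraction=test_fraction,
                    min_features=min_features, n_trials=n_trials,
                    k_folds=k_folds, sampler=sampler),
        trials=[],  # per-trial records are level-internal; trace carries candidates
        pruning_trace=trace.as_dicts(),
        train_indices=[int(i) for i in train_idx],
        test_indices=[int(i) for i in test_idx],
    )
    return artifact, trace


def trace_from_artifact(artifact) -> PruningTrace:
    """Rebuild a :class:`PruningTrace` from a stored run artifact."""
    return PruningTrace(
        candidates=[CandidateModel(**d) for d in artifact.pruning_trace]
    )


def loco_splits(solute_ids: Sequence[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-compound-out splits: each solute's rows form one test set."""
    ids = np.asarray(solute_ids)
    unique = sorted(set(ids.tolist()))
    if len(unique) < 2:
        raise ValueError("LOCO needs at least 2 solutes")
    splits = []
    for solute in unique:
        test = np.flatnonzero(ids == solute)
        train = np.flatnonzero(ids != solute)
        splits.append((train, test))
    return splits
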