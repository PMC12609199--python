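"""Per-target activity classifiers: scaffold/time-aware splits, a stacked
three-learner ensemble with a logistic meta-model fitted on out-of-fold
probabilities, isotonic calibration, evaluation metrics (including Brier and
the Hosmer-Lemeshow calibration test), and Tree-structured Parzen Estimator
hyperparameter search with a random-search fallback.

The default base learners span distinct bias-variance trade-offs: a
500-tree random forest and two gradient-boosted tree variants.  All handle
class imbalance via inverse-frequency weighting of the positive class.
Learners are pluggable: anything exposing fit(X, y) / predict_proba(X) can
be substituted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score, average_precision_score, balanced_accuracy_score,
    brier_score_loss, f1_score, matthews_corrcoef, precision_score,
    recall_score, roc_auc_score,
)

log = logging.getLogger(__name__)

# lightgbm round-trips numpy input through a named frame internally
warnings.filterwarnings("ignore",
                        message="X does not have valid feature names")


# ---------------------------------------------------------------------------
# splits

@dataclass
class SplitPlan:
    fold_of: np.ndarray            # fold id per compound
    kind: str                      # scaffold | time
    scaffold_keys: list | None = None

    @property
    def n_folds(self) -> int:
        return int(self.fold_of.max()) + 1

    def fold_indices(self, fold: int):
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test


def murcko_scaffold(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def make_splits(smiles_list, k: int, kind: str = "scaffold",
                timestamps=None) -> SplitPlan:
    """Build a leakage-safe fold plan.

    scaffold: compounds sharing a Bemis-Murcko scaffold are co-assigned;
    scaffold groups are packed greedily (largest first) into the currently
    smallest fold.  time: fold boundaries are timestamp quantiles with ties
    broken by stable record order, so train folds are strictly earlier.
    """
    n = len(smiles_list)
    if k < 2:
        raise ValueError("k must be >= 2")
    if kind == "scaffold":
        keys = [murcko_scaffold(s) for s in smiles_list]
        groups: dict[str, list[int]] = {}
        for i, key in enumerate(keys):
            groups.setdefault(key, []).append(i)
        if len(groups) < k:
            raise ValueError(
                f"only {len(groups)} Murcko scaffolds for {k} folds; "
                "use a smaller k")
        fold_of = np.empty(n, dtype=int)
        sizes = np.zeros(k, dtype=int)
        order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        for _, members in order:
            fold = int(np.argmin(sizes))
            fold_of[members] = fold
            sizes[fold] += len(members)
        return SplitPlan(fold_of=fold_of, kind="scaffold", scaffold_keys=keys)
    if kind == "time":
        if timestamps is None:
            raise ValueError("time splits need timestamps")
        ts = np.asarray(timestamps)
        order = np.argsort(ts, kind="stable")
        fold_of = np.empty(n, dtype=int)
        for fold, chunk in enumerate(np.array_split(order, k)):
            fold_of[chunk] = fold
        return SplitPlan(fold_of=fold_of, kind="time")
    raise ValueError(f"unknown split kind {kind!r}")


def assert_scaffold_disjoint(plan: SplitPlan):
    """Leakage guard: no scaffold key may appear in two folds."""
    seen: dict[str, int] = {}
    for key, fold in zip(plan.scaffold_keys, plan.fold_of):
        if key in seen and seen[key] != fold:
            raise AssertionError(f"scaffold {key!r} spans folds")
        seen[key] = fold


# ---------------------------------------------------------------------------
# base learners

def default_base_learners(rf_trees: int = 500, seed: int = 0,
                          pos_weight: float = 1.0) -> dict:
    """RF + two gradient-boosted variants, positive class upweighted."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return {
        "rf": RandomForestClassifier(
            n_estimators=rf_trees, class_weight={0: 1.0, 1: pos_weight},
            random_state=seed, n_jobs=1),
        "xgb": XGBClassifier(
            n_estimators=200, max_depth=5, learning_rate=0.1,
            scale_pos_weight=pos_weight, random_state=seed,
            n_jobs=1, verbosity=0, eval_metric="logloss"),
        "lgbm": LGBMClassifier(
            n_estimators=200, max_depth=-1, learning_rate=0.1,
            scale_pos_weight=pos_weight, random_state=seed,
            n_jobs=1, verbose=-1),
    }


# ---------------------------------------------------------------------------
# calibration

def calibrate_isotonic(scores, labels) -> IsotonicRegression:
    """Monotone step map from scores to empirical frequencies.

    Degenerate single-class input yields an identity map with a warning
    (there is nothing to calibrate against).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    if np.unique(labels).size < 2 or np.unique(scores).size < 2:
        warnings.warn("degenerate calibration input; using identity map")
        iso.fit([0.0, 1.0], [0.0, 1.0])
        return iso
    iso.fit(scores, labels)
    return iso


# ---------------------------------------------------------------------------
# metrics

def hosmer_lemeshow(probs, labels, bins: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-calibration test on equal-frequency bins
    (deciles of risk); chi-square with g-2 degrees of freedom."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(probs, kind="stable")
    chunks = [c for c in np.array_split(order, bins) if c.size]
    stat = 0.0
    g = 0
    for c in chunks:
        p, y = probs[c], labels[c]
        e1 = p.sum()
        e0 = c.size - e1
        o1 = y.sum()
        o0 = c.size - o1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
        g += 1
    df = max(g - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def pick_threshold(probs, labels, rule: str = "f1") -> float:
    """t_opt: decision threshold maximizing F1 (default) or Youden's J."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    grid = np.unique(np.concatenate([probs, [0.5]]))
    best_t, best_v = 0.5, -np.inf
    for t in grid:
        pred = probs >= t
        if rule == "f1":
            v = f1_score(labels, pred, zero_division=0)
        elif rule == "youden":
            tp = np.sum(pred & (labels == 1))
            fn = np.sum(~pred & (labels == 1))
            tn = np.sum(~pred & (labels == 0))
            fp = np.sum(pred & (labels == 0))
            sens = tp / (tp + fn) if tp + fn else 0.0
            spec = tn / (tn + fp) if tn + fp else 0.0
            v = sens + spec - 1
        else:
            raise ValueError(f"unknown threshold rule {rule!r}")
        if v > best_v:
            best_t, best_v = float(t), v
    return best_t


def evaluate_predictions(probs, labels, t_opt: float = 0.5,
                         hl_bins: int = 10) -> dict:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    out = {}
    if np.unique(labels).size < 2:
        out["roc_auc"] = np.nan
        out["pr_auc"] = np.nan
    else:
        out["roc_auc"] = roc_auc_score(labels, probs)
        out["pr_auc"] = average_precision_score(labels, probs)
    pred = (probs >= t_opt).astype(int)
    out.update(
        accuracy=accuracy_score(labels, pred),
        balanced_accuracy=balanced_accuracy_score(labels, pred),
        precision=precision_score(labels, pred, zero_division=0),
        recall=recall_score(labels, pred, zero_division=0),
        f1=f1_score(labels, pred, zero_division=0),
        mcc=matthews_corrcoef(labels, pred),
        brier=brier_score_loss(labels, probs),
    )
    hl_stat, hl_p = hosmer_lemeshow(probs, labels, bins=hl_bins)
    out["hl_stat"] = hl_stat
    out["hl_p"] = hl_p
    out["t_opt"] = t_opt
    return out


# ---------------------------------------------------------------------------
# stacked model

@dataclass
class TargetModel:
    target_id: str
    base_learners: dict
    meta: LogisticRegression
    calibrator: IsotonicRegression
    t_opt: float
    metrics: dict = field(default_factory=dict)
    base_order: tuple = ()
    oof_probs: np.ndarray | None = None
    oof_base_probs: pd.DataFrame | None = None

    @property
    def meta_weights(self) -> dict:
        return dict(zip(self.base_order, self.meta.coef_[0]))

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated p(active)."""
        base = np.column_stack([
            self.base_learners[name].predict_proba(X)[:, 1]
            for name in self.base_order])
        meta_score = self.meta.predict_proba(base)[:, 1]
        return self.calibrator.predict(meta_score)

    def predict_base_proba(self, X) -> pd.DataFrame:
        return pd.DataFrame({
            name: self.base_learners[name].predict_proba(X)[:, 1]
            for name in self.base_order})


def train_stacked_model(X, y, plan: SplitPlan, target_id: str = "",
                        learner_factory=None, rf_trees: int = 500,
                        seed: int = 0, threshold_rule: str = "f1",
                        hl_bins: int = 10) -> TargetModel:
    """Train the stacked ensemble under a fold plan.

    Per fold the base learners are fitted on the training part and produce
    held-out probabilities; the logistic meta-model and the isotonic
    calibrator are fitted strictly on that out-of-fold matrix.  Single-class
    training folds are skipped with a warning.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("need both classes to train")
    pos_weight = (y.size - n_pos) / n_pos

    if learner_factory is None:
        def learner_factory(fold_seed):
            return default_base_learners(rf_trees=rf_trees, seed=fold_seed,
                                         pos_weight=pos_weight)

    names = tuple(learner_factory(0).keys())
    oof = np.full((y.size, len(names)), np.nan)
    fold_aucs = []
    used_any = False
    for fold in range(plan.n_folds):
        train, test = plan.fold_indices(fold)
        if np.unique(y[train]).size < 2:
            warnings.warn(f"fold {fold}: single-class training fold skipped")
            continue
        used_any = True
        learners = learner_factory(seed + fold)
        for j, name in enumerate(names):
            learners[name].fit(X[train], y[train])
            oof[test, j] = learners[name].predict_proba(X[test])[:, 1]
    if not used_any:
        raise ValueError("every fold was single-class; cannot train")

    mask = ~np.isnan(oof).any(axis=1)
    if np.unique(y[mask]).size < 2:
        raise ValueError("out-of-fold labels are single-class after skipping "
                         "degenerate folds; cannot fit the meta-model")
    meta = LogisticRegression(max_iter=1000)
    meta.fit(oof[mask], y[mask])
    meta_oof = np.full(y.size, np.nan)
    meta_oof[mask] = meta.predict_proba(oof[mask])[:, 1]

    calibrator = calibrate_isotonic(meta_oof[mask], y[mask])
    cal_oof = calibrator.predict(meta_oof[mask])

    for fold in range(plan.n_folds):
        _, test = plan.fold_indices(fold)
        sel = mask[test]
        yt = y[test][sel]
        if np.unique(yt).size < 2:
            continue
        fold_aucs.append(roc_auc_score(yt, meta_oof[test][sel]))

    t_opt = pick_threshold(cal_oof, y[mask], rule=threshold_rule)

    final = learner_factory(seed)
    for name in names:
        final[name].fit(X, y)

    metrics = {
        "cv_roc_auc": float(np.mean(fold_aucs)) if fold_aucs else np.nan,
        "cv_auc_std": float(np.std(fold_aucs)) if fold_aucs else np.nan,
        "oof_roc_auc": roc_auc_score(y[mask], meta_oof[mask])
        if np.unique(y[mask]).size > 1 else np.nan,
        "brier_before_calibration": brier_score_loss(y[mask], meta_oof[mask]),
        "brier_after_calibration": brier_score_loss(y[mask], cal_oof),
    }
    model = TargetModel(target_id=target_id, base_learners=final, meta=meta,
                        calibrator=calibrator, t_opt=t_opt, metrics=metrics,
                        base_order=names,
                        oof_probs=np.where(mask, meta_oof, np.nan),
                        oof_base_probs=pd.DataFrame(oof, columns=list(names)))
    return model


def evaluate_model(model: TargetModel, X_test, y_test,
                   hl_bins: int = 10) -> dict:
    """Held-out evaluation at the model's t_opt; single-class test sets get
    missing AUCs."""
    probs = model.predict_proba(np.asarray(X_test))
    out = evaluate_predictions(probs, y_test, t_opt=model.t_opt,
                               hl_bins=hl_bins)
    return {f"test_{k}" if not k.startswith(("hl_", "t_")) else k: v
            for k, v in out.items()}


def metrics_table(models: list[TargetModel], test_metrics: list[dict] | None = None) -> pd.DataFrame:
    """Target-labeled metrics table in the published column layout."""
    rows = []
    for i, m in enumerate(models):
        row = {"target_id": m.target_id,
               "cv_auc_std": m.metrics.get("cv_auc_std"),
               "cv_roc_auc": m.metrics.get("cv_roc_auc")}
        if test_metrics:
            t = test_metrics[i]
            row.update(
                test_roc_auc=t.get("test_roc_auc"),
                test_pr_auc=t.get("test_pr_auc"),
                test_accuracy=t.get("test_accuracy"),
                test_balanced_accuracy=t.get("test_balanced_accuracy"),
                test_precision=t.get("test_precision"),
                test_recall=t.get("test_recall"),
                test_f1=t.get("test_f1"),
                test_mcc=t.get("test_mcc"),
                test_brier=t.get("test_brier"),
                hl_p=t.get("hl_p"),
            )
        row["calibration"] = "bases_calibrated"
        row["t_opt"] = m.t_opt
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hyperparameter search (TPE with random fallback)

def _sample_param(rng, spec):
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2])
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
    if kind == "int":
        return int(rng.integers(spec[1], spec[2] + 1))
    if kind == "choice":
        return spec[1][rng.integers(len(spec[1]))]
    raise ValueError(f"unknown param kind {kind!r}")


def _tpe_propose(rng, spec, good, bad, n_candidates=24):
    """One-dimensional Parzen-estimator proposal: sample candidates from the
    'good' kernel mixture and keep the candidate maximizing the good/bad
    density ratio."""
    kind = spec[0]
    if kind == "choice":
        options = spec[1]
        counts_g = np.array([1.0 + sum(1 for v in good if v == o) for o in options])
        counts_b = np.array([1.0 + sum(1 for v in bad if v == o) for o in options])
        score = (counts_g / counts_g.sum()) / (counts_b / counts_b.sum())
        probs = counts_g / counts_g.sum()
        idx = rng.choice(len(options), size=n_candidates, p=probs)
        best = max(idx, key=lambda i: score[i])
        return options[best]
    lo, hi = spec[1], spec[2]
    logspace = kind == "loguniform"
    tf = np.log if logspace else (lambda x: np.asarray(x, dtype=float))
    g = tf(np.asarray(good, dtype=float))
    b = tf(np.asarray(bad, dtype=float))
    span = tf(hi) - tf(lo)
    bw = max(span / max(len(g), 2), 1e-6 * max(abs(span), 1.0))

    def density(x, centers):
        if centers.size == 0:
            return np.full_like(x, 1.0 / span)
        z = (x[:, None] - centers[None, :]) / bw
        return np.exp(-0.5 * z ** 2).sum(axis=1) / (centers.size * bw)

    centers = g if g.size else tf(np.array([rng.uniform(lo, hi)]))
    picks = centers[rng.integers(centers.size, size=n_candidates)]
    cand = picks + rng.normal(0, bw, size=n_candidates)
    cand = np.clip(cand, tf(lo), tf(hi))
    ratio = density(cand, g) / np.maximum(density(cand, b), 1e-12)
    x = cand[int(np.argmax(ratio))]
    x = float(np.exp(x)) if logspace else float(x)
    if kind == "int":
        x = int(round(x))
        x = min(max(x, spec[1]), spec[2])
    return x


def tune_hyperparameters(objective, search_space: dict, budget: int,
                         seed: int = 0, method: str = "tpe",
                         gamma: float = 0.25, n_startup: int = 10):
    """Maximize ``objective(params)`` over ``search_space`` within ``budget``
    trials.

    search_space values: ("uniform", lo, hi), ("loguniform", lo, hi),
    ("int", lo, hi) or ("choice", [options]).  method="tpe" runs a
    Tree-structured Parzen Estimator after ``n_startup`` random trials;
    method="random" is the pure random-search fallback.  Deterministic given
    the seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "grid":
        from itertools import product as _product

        axes = []
        for k, spec in search_space.items():
            if spec[0] == "choice":
                axes.append([(k, v) for v in spec[1]])
            elif spec[0] == "int":
                axes.append([(k, v) for v in range(spec[1], spec[2] + 1)])
            else:
                raise ValueError("grid enumeration needs finite axes "
                                 "(choice or int)")
        trials = []
        for combo in _product(*axes):
            params = dict(combo)
            trials.append((params, float(objective(params))))
        best_params, best_score = max(trials, key=lambda tr: tr[1])
        return {"best_params": best_params, "best_score": best_score,
                "trials": trials}
    trials = []
    for t in range(budget):
        if method == "random" or t < min(n_startup, budget):
            params = {k: _sample_param(rng, v) for k, v in search_space.items()}
        else:
            scores = np.array([tr[1] for tr in trials])
            cut = np.quantile(scores, 1 - gamma)
            good_idx = [i for i, s in enumerate(scores) if s >= cut]
            bad_idx = [i for i in range(len(scores)) if i not in good_idx]
            params = {}
            for k, spec in search_space.items():
                good = [trials[i][0][k] for i in good_idx]
                bad = [trials[i][0][k] for i in bad_idx]
                params[k] = _tpe_propose(rng, spec, good, bad)
        trials.append((params, float(objective(params))))
    best_params, best_score = max(trials, key=lambda tr: tr[1])
    return {"best_params": best_params, "best_score": best_score,
            "trials": trials}
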