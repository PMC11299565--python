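"""Training and evaluation machinery: balanced lock-box cross-validation.

The cohort is split into five groups balanced on recovery time, initial
severity, left lesion size and outcome.  Groups 1–4 rotate through 4-fold
cross-validation (train on three, validate on one); group 5 is the lock
box — mechanically guarded so its labels can be read exactly once, after
all tuning.  Training uses early stopping on class-weighted binary
cross-entropy validation loss (≤ 200 epochs), single-parameter Platt
(temperature) calibration fitted on the validation split, and is repeated
over learning rates and random seeds.  Model comparison uses the
corrected resampled t-test (variance factor 1/J + n_test/n_train, which
compensates for the dependence between folds) with Benjamini–Hochberg FDR
across a family of comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = ["PartitionPlan", "GuardedLabels", "LockBoxViolation", "TrainRun",
           "EvalReport", "ComparisonResult", "balanced_partition",
           "class_weighted_bce", "inverse_frequency_weights", "run_protocol",
           "platt_calibrate", "apply_calibration", "select_epoch",
           "compute_metrics", "threshold_sweep", "corrected_t_test",
           "fdr_adjust", "baseline_logistic"]


class LockBoxViolation(RuntimeError):
    """Raised when lock-box labels are touched before final evaluation."""


class GuardedLabels:
    """Labels that may be read exactly once, after an explicit unlock."""

    def __init__(self, labels: np.ndarray, name: str = "lockbox"):
        self._labels = np.asarray(labels).copy()
        self._name = name
        self._unlocked = False
        self._accessed = 0

    def __len__(self) -> int:
        return len(self._labels)

    def unlock(self) -> None:
        self._unlocked = True

    @property
    def access_count(self) -> int:
        return self._accessed

    def reveal(self) -> np.ndarray:
        if not self._unlocked:
            raise LockBoxViolation(
                f"{self._name} labels read before final evaluation")
        self._accessed += 1
        logger.info("lock-box %s labels accessed (count=%d)",
                    self._name, self._accessed)
        return self._labels.copy()


@dataclass(frozen=True)
class PartitionPlan:
    """Subject → group assignment with the lock-box group identified."""

    groups: np.ndarray                  # group id in 1..k per subject
    k: int
    lockbox_group: int
    balance_report: pd.DataFrame

    def indices(self, group: int) -> np.ndarray:
        return np.where(self.groups == group)[0]

    @property
    def lockbox_indices(self) -> np.ndarray:
        return self.indices(self.lockbox_group)

    def fold(self, fold_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) indices for fold 0..k-2; lock box excluded."""
        cv_groups = [g for g in range(1, self.k + 1)
                     if g != self.lockbox_group]
        if not 0 <= fold_id < len(cv_groups):
            raise ValueError(f"fold_id must be in 0..{len(cv_groups) - 1}")
        val_g = cv_groups[fold_id]
        val = self.indices(val_g)
        train = np.concatenate([self.indices(g) for g in cv_groups
                                if g != val_g])
        return np.sort(train), np.sort(val)

    @property
    def n_folds(self) -> int:
        return self.k - 1


def _quartile_bins(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average") / len(x)
    return np.minimum((ranks * 4).astype(int), 3)


def balanced_partition(table: pd.DataFrame, k: int = 5,
                       balance_vars=("recovery_time_months",
                                     "initial_severity", "left_lesion_size",
                                     "outcome"),
                       seed: int = 0) -> PartitionPlan:
    """Greedy stratified assignment into ``k`` balanced groups.

    Subjects are sorted into strata (outcome × severity × quartiles of the
    continuous variables), shuffled within stratum, then dealt round-robin
    with a single continuing pointer — so group sizes differ by at most
    one, and any variable whose strata are contiguous in the deal order is
    spread near-uniformly.  The last group (id ``k``) is the lock box.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cohort table is empty")
    if k > n:
        raise ValueError("more groups than subjects")
    missing = [v for v in balance_vars if v not in table.columns]
    if missing:
        raise ValueError(f"balance variables absent from table: {missing}")

    # outcome is the primary stratification key: its strata are then
    # contiguous in the deal order, so per-group prevalence is as even as
    # integer arithmetic allows; the other variables nest inside it
    ordered_vars = [v for v in balance_vars if v == "outcome"] + \
                   [v for v in balance_vars if v != "outcome"]
    keys = []
    for var in ordered_vars:
        col = table[var]
        if col.dtype.kind in "ifu" and col.nunique() > 8:
            keys.append(_quartile_bins(col.to_numpy(dtype=float)))
        else:
            keys.append(pd.factorize(col, sort=True)[0])
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n)
    # lexsort uses the LAST key as primary; tiebreak is least significant
    order = np.lexsort((tiebreak,) + tuple(reversed(keys)))

    groups = np.empty(n, dtype=int)
    start = int(rng.integers(k))
    for pos, idx in enumerate(order):
        groups[idx] = (start + pos) % k + 1

    rows = []
    for g in range(1, k + 1):
        sub = table.iloc[np.where(groups == g)[0]]
        row = {"group": g, "n": len(sub)}
        for var in balance_vars:
            col = sub[var]
            if col.dtype.kind in "ifu":
                row[f"{var}_mean"] = float(col.mean()) if len(sub) else np.nan
            else:
                row[f"{var}_mode"] = col.mode().iloc[0] if len(sub) else None
        rows.append(row)
    return PartitionPlan(groups=groups, k=k, lockbox_group=k,
                         balance_report=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# losses, calibration, metrics
# ---------------------------------------------------------------------------

_EPS = 1e-7


def inverse_frequency_weights(train_labels: np.ndarray) -> dict[int, float]:
    """Per-class weights ∝ inverse class frequency, normalised to mean 1."""
    y = np.asarray(train_labels)
    p1 = y.mean()
    if p1 in (0.0, 1.0):
        raise ValueError("training labels contain a single class")
    w0, w1 = 1.0 / (1.0 - p1), 1.0 / p1
    z = p1 * w1 + (1 - p1) * w0
    return {0: w0 / z, 1: w1 / z}


def class_weighted_bce(probabilities: np.ndarray, labels: np.ndarray,
                       class_weights: dict[int, float] | None = None) -> float:
    """Mean of −w(y)·[y·log p + (1−y)·log(1−p)]; p clipped at 1e-7."""
    p = np.clip(np.asarray(probabilities, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(labels, dtype=np.float64)
    if class_weights is None:
        w = np.ones_like(y)
    else:
        w = np.where(y == 1, class_weights[1], class_weights[0])
    return float(np.mean(-w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def platt_calibrate(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Single-parameter (temperature) Platt scaling fitted on validation.

    Finds T > 0 minimising the negative log-likelihood of
    sigmoid(logit(p)/T); the map is monotone, so rankings (hence AUC) are
    unchanged.
    """
    p = np.clip(np.asarray(probabilities, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(labels, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("validation set contains a single class")
    z = special.logit(p)

    def nll(log_t):
        q = special.expit(z / np.exp(log_t))
        q = np.clip(q, _EPS, 1 - _EPS)
        return -np.mean(y * np.log(q) + (1 - y) * np.log1p(-q))

    res = optimize.minimize_scalar(nll, bounds=(-4.0, 4.0), method="bounded")
    return float(np.exp(res.x))


def apply_calibration(temperature: float, probabilities: np.ndarray
                      ) -> np.ndarray:
    p = np.clip(np.asarray(probabilities, dtype=np.float64), _EPS, 1 - _EPS)
    return special.expit(special.logit(p) / temperature)


def select_epoch(val_losses) -> int:
    """Early-stopping epoch: first argmin of the validation-loss trace."""
    losses = np.asarray(val_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss trace")
    return int(losses.argmin())


def _auc_tie_averaged(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (equivalent to trapezoidal ROC with tie averaging)."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    ranks = stats.rankdata(p, method="average")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5,
                    subgroup_mask: np.ndarray | None = None) -> dict:
    """Accuracy, balanced accuracy, F1 at a threshold; tie-averaged AUC.

    ``subgroup_mask`` restricts the computation (e.g. to severe/moderate
    initial severity).  A single-class label vector yields ``auc = nan``
    with ``auc_defined = False`` rather than a silent 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if subgroup_mask is not None:
        m = np.asarray(subgroup_mask, dtype=bool)
        p, y = p[m], y[m]
    if len(y) == 0:
        return {"n": 0, "accuracy": np.nan, "balanced_accuracy": np.nan,
                "f1": np.nan, "auc": np.nan, "auc_defined": False,
                "threshold": threshold}
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    bal = (sens + spec) / 2
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    single_class = y.min() == y.max()
    auc = np.nan if single_class else _auc_tie_averaged(p, y)
    return {"n": len(y), "accuracy": float(acc),
            "balanced_accuracy": float(bal), "f1": float(f1),
            "auc": float(auc) if not single_class else np.nan,
            "auc_defined": not single_class, "threshold": threshold}


def threshold_sweep(probabilities, labels,
                    thresholds=np.arange(0.1, 0.95, 0.1)) -> pd.DataFrame:
    rows = [compute_metrics(probabilities, labels, threshold=float(t))
            for t in np.round(thresholds, 10)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    differences: np.ndarray
    t_statistic: float
    df: float
    p_value: float
    corrected: bool
    p_adjusted: float | None = None


def corrected_t_test(acc_a, acc_b, n_train: int, n_test: int,
                     corrected: bool = True,
                     pair: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Corrected resampled t-test on paired per-fold/seed accuracies.

    The variance of the mean difference is inflated from 1/J to
    1/J + n_test/n_train, compensating for the dependence induced by
    overlapping training sets across folds.  ``corrected=False`` gives the
    naive paired t-test for reference.
    """
    d = np.asarray(acc_a, dtype=float) - np.asarray(acc_b, dtype=float)
    j = len(d)
    if j < 2:
        raise ValueError("need ≥ 2 paired observations")
    var = d.var(ddof=1)
    mean = d.mean()
    if var == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
        return ComparisonResult(pair, d, float(t), float(j - 1), float(p),
                                corrected)
    factor = (1.0 / j + n_test / n_train) if corrected else 1.0 / j
    t = mean / np.sqrt(factor * var)
    df = j - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(pair, d, float(t), float(df), float(p), corrected)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full training protocol
# ---------------------------------------------------------------------------

@dataclass
class TrainRun:
    fold_id: int
    seed: int
    learning_rate: float
    val_losses: list[float]
    selected_epoch: int
    temperature: float
    lockbox_probabilities: np.ndarray
    val_metrics: dict


@dataclass
class EvalReport:
    runs: list[TrainRun]
    metrics_table: pd.DataFrame
    summary: pd.DataFrame
    lockbox_access_count: int


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_one(classifier, images, labels, tabular, train_idx, val_idx,
              learning_rate: float, max_epochs: int, batch_size: int,
              rng: np.random.Generator, patience: int | None = None
              ) -> tuple[list[float], int, dict]:
    """Fit with early stopping on class-weighted validation BCE.

    Returns (validation-loss trace, selected epoch, best state dict).
    ``patience`` optionally stops early once the best epoch is ``patience``
    epochs old; the selected epoch is always the argmin of the trace.
    """
    y_train = labels[train_idx]
    cw = inverse_frequency_weights(y_train)
    w_train = np.where(y_train == 1, cw[1], cw[0])
    opt = classifier.make_optimizer(learning_rate)
    val_losses: list[float] = []
    best_state = classifier.state_dict()
    best_loss = np.inf
    tab = tabular if classifier.uses_tabular else None
    for epoch in range(max_epochs):
        for batch in _minibatches(len(train_idx), batch_size, rng):
            bidx = train_idx[batch]
            classifier.train_step(
                opt, images[bidx], labels[bidx], w_train[batch],
                tab[bidx] if tab is not None else None)
        p_val = classifier.predict_proba(
            images[val_idx], tab[val_idx] if tab is not None else None)
        vl = class_weighted_bce(p_val, labels[val_idx], cw)
        val_losses.append(vl)
        if vl < best_loss:
            best_loss = vl
            best_state = classifier.state_dict()
        if patience is not None and \
                epoch - select_epoch(val_losses) >= patience:
            break
    return val_losses, select_epoch(val_losses), best_state


def run_protocol(dataset, model_builder, plan: PartitionPlan,
                 learning_rates=(1e-4, 5e-4, 1e-5), seeds=range(20),
                 max_epochs: int = 200, batch_size: int = 32,
                 patience: int | None = None, folds=None) -> EvalReport:
    """Cross-validated training with a single final lock-box read.

    ``dataset`` maps attribute access: ``images`` (n, h, w), ``labels``
    (n,), optional ``tabular`` (n, 3), optional ``subgroup_mask`` (n,).
    ``model_builder(seed)`` returns a fresh :class:`~neuromontage.models.
    Classifier`.  For every (fold, learning rate, seed): train with early
    stopping, restore the best epoch, Platt-calibrate on the validation
    split, and record calibrated lock-box probabilities.  Lock-box labels
    live behind a :class:`GuardedLabels` that is unlocked exactly once at
    report assembly.
    """
    images = np.asarray(dataset["images"], dtype=np.float64)
    labels = np.asarray(dataset["labels"]).astype(int)
    tabular = dataset.get("tabular")
    subgroup = dataset.get("subgroup_mask")
    lb_idx = plan.lockbox_indices
    guard = GuardedLabels(labels[lb_idx])
    # replace lock-box labels with a poison value: any training-path use
    # of them would corrupt the loss loudly rather than silently leak
    work_labels = labels.copy()
    work_labels[lb_idx] = -1

    fold_ids = list(range(plan.n_folds)) if folds is None else list(folds)
    runs: list[TrainRun] = []
    for fold_id in fold_ids:
        train_idx, val_idx = plan.fold(fold_id)
        if np.intersect1d(np.concatenate([train_idx, val_idx]), lb_idx).size:
            raise LockBoxViolation("lock-box subjects leaked into a fold")
        for lr in learning_rates:
            for seed in seeds:
                clf = model_builder(seed)
                rng = np.random.default_rng((seed, fold_id, 7))
                trace, sel, best = train_one(
                    clf, images, work_labels, tabular, train_idx, val_idx,
                    lr, max_epochs, batch_size, rng, patience)
                clf.load_state_dict(best)
                tab = tabular if clf.uses_tabular else None
                p_val = clf.predict_proba(
                    images[val_idx],
                    tab[val_idx] if tab is not None else None)
                temp = platt_calibrate(p_val, work_labels[val_idx])
                p_lb = apply_calibration(temp, clf.predict_proba(
                    images[lb_idx],
                    tab[lb_idx] if tab is not None else None))
                runs.append(TrainRun(
                    fold_id=fold_id, seed=seed, learning_rate=lr,
                    val_losses=trace, selected_epoch=sel, temperature=temp,
                    lockbox_probabilities=p_lb,
                    val_metrics=compute_metrics(
                        apply_calibration(temp, p_val),
                        work_labels[val_idx])))

    guard.unlock()
    y_lb = guard.reveal()
    sub_lb = subgroup[lb_idx] if subgroup is not None else None
    rows = []
    for run in runs:
        rec = compute_metrics(run.lockbox_probabilities, y_lb)
        rec.update({"fold_id": run.fold_id, "seed": run.seed,
                    "learning_rate": run.learning_rate, "scope": "all"})
        rows.append(rec)
        if sub_lb is not None:
            rec2 = compute_metrics(run.lockbox_probabilities, y_lb,
                                   subgroup_mask=sub_lb)
            rec2.update({"fold_id": run.fold_id, "seed": run.seed,
                         "learning_rate": run.learning_rate,
                         "scope": "subgroup"})
            rows.append(rec2)
    metrics_table = pd.DataFrame(rows)

    def _ci(x):
        x = np.asarray(x, dtype=float)
        se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        return 1.96 * se

    summary = (metrics_table.groupby(["scope", "learning_rate"])
               .agg(accuracy=("accuracy", "mean"),
                    accuracy_ci=("accuracy", _ci),
                    balanced_accuracy=("balanced_accuracy", "mean"),
                    balanced_accuracy_ci=("balanced_accuracy", _ci),
                    auc=("auc", "mean"), f1=("f1", "mean"))
               .reset_index())
    return EvalReport(runs=runs, metrics_table=metrics_table,
                      summary=summary,
                      lockbox_access_count=guard.access_count)


def baseline_logistic(train_table: pd.DataFrame, test_features: np.ndarray
                      ) -> np.ndarray:
    """Baseline logistic regression on the three a-priori tabular features.

    Fitted with statsmodels' deterministic BFGS optimiser; returns
    predicted impairment probabilities for ``test_features`` (same
    encoding as :func:`neuromontage.models.encode_tabular`).
    """
    import statsmodels.api as sm

    from .models import encode_tabular

    x = encode_tabular(train_table)
    y = train_table["outcome"].to_numpy(dtype=float)
    model = sm.Logit(y, sm.add_constant(x))
    fit = model.fit(method="bfgs", disp=False)
    xt = sm.add_constant(np.asarray(test_features, dtype=float),
                         has_constant="add")
    return np.asarray(fit.predict(xt))
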