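"""Cross-validation planning, the training-loop contract and accuracy
aggregation.

Two evaluation schemes mirror common emotion-BCI protocols:

* subject-dependent k-fold (default k=5): within every subject, epochs are
  shuffled and split 80/20 into train/test; 30% of the training portion is
  held out for validation (model selection), the remaining 70% is optimised.
* leave-one-subject-out (LOSO): one fold per subject; the held-out
  subject's epochs form the test set and 30% of the pooled remaining epochs
  (unstratified) form the validation set.

Accuracies are aggregated subject-first: the reported mean, std and 95% CI
are computed over per-subject accuracies (Student-t interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sst

from .baselines import BaselineSpec, fit_baseline, predict_baseline
from .data import EpochSet
from .exceptions import ParameterError, SchemeError
from .models import ModelSpec, build_model
from .nn import Adam
from .spectral import extract_band_features

__all__ = ["CVPlan", "TrainConfig", "EvalResult", "plan_subject_dependent",
           "plan_loso", "chance_level", "run_experiment", "train_network"]


@dataclass
class CVPlan:
    scheme: str
    folds: list  # of (train_idx, val_idx, test_idx) integer arrays
    seed: int

    def validate(self, n: int):
        seen = np.zeros(n, dtype=int)
        for tr, va, te in self.folds:
            fold_all = np.concatenate([tr, va, te])
            if len(np.unique(fold_all)) != len(fold_all):
                raise SchemeError("train/val/test sets overlap within a fold")
            seen[te] += 1
        if np.any(seen > 1):
            raise SchemeError("an index is tested in more than one fold")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by every network experiment."""

    lr: float = 1e-3
    epochs: int = 200
    batch: int = 100
    seed: int = 0
    model_selection: str = "best_val"   # or "final"

    def __post_init__(self):
        if self.epochs < 1 or self.batch < 1:
            raise ParameterError("epochs and batch must be >= 1")
        if self.model_selection not in ("best_val", "final"):
            raise ParameterError("model_selection must be best_val or final")


@dataclass
class EvalResult:
    per_fold_accuracy: list
    per_subject_accuracy: dict
    mean: float
    std: float
    ci95: tuple
    chance: float
    n_test_total: int
    histories: list = field(default_factory=list)
    skipped_folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "per_subject_accuracy": {k: float(v) for k, v in
                                     self.per_subject_accuracy.items()},
            "mean": float(self.mean), "std": float(self.std),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "chance": float(self.chance),
            "n_test_total": int(self.n_test_total),
            "skipped_folds": list(self.skipped_folds),
        }


def chance_level(labels) -> float:
    """Accuracy of always predicting the majority class."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ParameterError("empty label vector")
    _, counts = np.unique(labels.astype(str), return_counts=True)
    return counts.max() / len(labels)


def _chunks(idx: np.ndarray, k: int) -> list[np.ndarray]:
    return [a for a in np.array_split(idx, k)]


def plan_subject_dependent(es: EpochSet, k: int = 5, val_frac: float = 0.3,
                           seed: int = 0, stratify: bool = True) -> CVPlan:
    """k-fold plan built per subject (and per class when ``stratify``) then
    pooled, so every subject contributes to every fold."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    if len(es) < k:
        raise ParameterError(f"need at least {k} epochs for {k} folds")
    rng = np.random.default_rng(seed)
    strata = []
    subjects = es.subject_ids.astype(str)
    labels = es.labels.astype(str)
    for s in np.unique(subjects):
        mask = subjects == s
        if stratify:
            for c in np.unique(labels[mask]):
                strata.append(np.flatnonzero(mask & (labels == c)))
        else:
            strata.append(np.flatnonzero(mask))
    per_stratum_chunks = [_chunks(rng.permutation(st), k) for st in strata]
    folds = []
    for f in range(k):
        test = np.sort(np.concatenate(
            [ch[f] for ch in per_stratum_chunks]))
        rest = np.setdiff1d(np.arange(len(es)), test)
        n_val = int(round(val_frac * len(rest)))
        val = np.sort(rng.choice(rest, size=n_val, replace=False))
        train = np.setdiff1d(rest, val)
        folds.append((train, val, test))
    plan = CVPlan(scheme="subject_dependent_kfold", folds=folds, seed=seed)
    plan.validate(len(es))
    return plan


def plan_loso(es: EpochSet, val_frac: float = 0.3, seed: int = 0) -> CVPlan:
    """Leave-one-subject-out: one fold per subject; validation is an
    unstratified random 30% of the pooled remaining epochs."""
    subjects = es.subject_ids.astype(str)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise SchemeError("leave-one-subject-out needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    folds = []
    for s in uniq:
        test = np.flatnonzero(subjects == s)
        rest = np.flatnonzero(subjects != s)
        n_val = int(round(val_frac * len(rest)))
        val = np.sort(rng.choice(rest, size=n_val, replace=False))
        train = np.setdiff1d(rest, val)
        folds.append((train, val, test))
    plan = CVPlan(scheme="loso", folds=folds, seed=seed)
    plan.validate(len(es))
    return plan


# ---------------------------------------------------------------------------
# network training
# ---------------------------------------------------------------------------

def _accuracy(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def train_network(net, X, y, X_val, y_val, tc: TrainConfig) -> dict:
    """Mini-batch Adam training with per-epoch validation.

    Returns a history dict with ``train_loss`` and ``val_acc`` per epoch
    plus the index of the restored checkpoint.  With ``best_val`` selection
    the weights achieving the highest validation accuracy are restored
    (ties favour the earlier epoch).
    """
    rng = np.random.default_rng(tc.seed)
    opt = Adam(net, lr=tc.lr)
    history = {"train_loss": [], "val_acc": []}
    best_acc, best_state, best_epoch = -1.0, None, -1
    n = len(X)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, tc.batch):
            idx = order[i:i + tc.batch]
            loss = net.loss_and_grad(X[idx], y[idx])
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(y_val, net.predict(X_val))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_acc"].append(val_acc)
        if tc.model_selection == "best_val" and val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, net.get_state(), epoch
    if tc.model_selection == "best_val" and best_state is not None:
        net.set_state(best_state)
        history["restored_epoch"] = best_epoch
        history["best_val_acc"] = best_acc
    else:
        history["restored_epoch"] = tc.epochs - 1
        history["best_val_acc"] = history["val_acc"][-1]
    return history


def _subject_t_interval(values: np.ndarray) -> tuple:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return (mean, mean)
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    if sem == 0:
        return (mean, mean)
    tcrit = sst.t.ppf(0.975, n - 1)
    return (mean - tcrit * sem, mean + tcrit * sem)


def run_experiment(spec: Union[ModelSpec, BaselineSpec], es: EpochSet,
                   plan: CVPlan, tc: Optional[TrainConfig] = None
                   ) -> EvalResult:
    """Train and evaluate one model over every fold of a plan.

    Network specs are adapted to the dataset geometry (sampling rate,
    window, channel count, class count); inputs are z-scored per channel
    with training-fold statistics.  Baselines consume band-power features
    (computed once, deterministic) and are fitted on the training portion
    only.  Folds whose training labels collapse to one class are skipped
    with a warning recorded in the result.
    """
    tc = tc or TrainConfig()
    labels = es.labels.astype(str)
    label_set = sorted(np.unique(labels).tolist())
    y_all = np.array([label_set.index(l) for l in labels])
    subjects = es.subject_ids.astype(str)
    is_baseline = isinstance(spec, BaselineSpec)
    if is_baseline:
        feats = extract_band_features(es).values
    else:
        X_all = np.ascontiguousarray(
            es.epochs.transpose(0, 2, 1)[..., None], dtype=np.float32)

    fold_acc, histories, skipped = [], [], []
    pred_store = np.full(len(es), -1, dtype=int)
    tested = np.zeros(len(es), dtype=bool)

    for f, (tr, va, te) in enumerate(plan.folds):
        if len(np.unique(y_all[tr])) < 2:
            skipped.append(f)
            continue
        if is_baseline:
            model = fit_baseline(replace(spec, seed=tc.seed + f),
                                 feats[tr], y_all[tr])
            pred = predict_baseline(model, feats[te])
            histories.append({})
        else:
            fold_seed = (tc.seed * 100003 + 7919 * f) % (2 ** 31)
            mspec = replace(spec.resolve(), fs=es.fs, window_s=es.window_s,
                            n_channels=es.n_channels,
                            n_classes=max(2, len(label_set)),
                            seed=fold_seed)
            net = build_model(mspec)
            mu = X_all[tr].mean(axis=(0, 1), keepdims=True)
            sd = X_all[tr].std(axis=(0, 1), keepdims=True) + 1e-8
            Xtr = (X_all[tr] - mu) / sd
            Xva = (X_all[va] - mu) / sd
            Xte = (X_all[te] - mu) / sd
            hist = train_network(net, Xtr, y_all[tr], Xva, y_all[va],
                                 replace(tc, seed=fold_seed))
            pred = net.predict(Xte)
            histories.append(hist)
        fold_acc.append(_accuracy(y_all[te], pred))
        pred_store[te] = pred
        tested[te] = True

    per_subject = {}
    for s in np.unique(subjects):
        mask = (subjects == s) & tested
        if mask.any():
            per_subject[s] = _accuracy(y_all[mask], pred_store[mask])
    subj_vals = np.array(list(per_subject.values()), dtype=float)
    mean = float(subj_vals.mean()) if len(subj_vals) else float("nan")
    std = float(subj_vals.std(ddof=1)) if len(subj_vals) > 1 else 0.0
    return EvalResult(
        per_fold_accuracy=fold_acc,
        per_subject_accuracy=per_subject,
        mean=mean, std=std, ci95=_subject_t_interval(subj_vals),
        chance=chance_level(labels),
        n_test_total=int(tested.sum()),
        histories=histories, skipped_folds=skipped)
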