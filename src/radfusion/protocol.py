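"""Nested patient-grouped cross-validation and evaluation statistics.

Protocol per outer fold (5 folds, stratified by class, grouped by patient):

1. the fold's patients are the test set; all other patients form the
   training+validation pool;
2. feature ranking and top-50 selection run on the pool only; the
   standardization statistics come from the training subset only;
3. the pool is split into an internal 3-fold plan; inner fold 1 serves as
   the validation set for early stopping and plateau detection;
4. the model trains in two phases: all layers at lr 1e-4 (plateau
   reduction x0.5 down to 1e-7, up to 200 epochs, early-stop patience 10),
   then the first 70% of layers frozen at lr 1e-5 (20 epochs, patience 5);
5. test metrics use the fold's own selection/scaler applied to the held-out
   patients.

Weight carry-over between consecutive outer folds is available for
protocol fidelity but disabled by default: it lets fold f start from
weights influenced by fold f-1's test patients, which leaks information
across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp
from sklearn.metrics import (
    accuracy_score,
    auc as sk_auc,
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
)

from .fusionnet.models import (
    FusionConfig,
    ModelHandle,
    build_base_model,
    build_fusion_model,
    freeze_fraction,
    unfreeze_all,
)
from .phantom import RoiSample
from .preprocess import crop_patch, resize_bicubic, standardize_patch
from .radiomics.extract import extract_table
from .selection import (
    LeakageError,
    apply_scaler,
    fit_scaler,
    rank_features,
    select_top_k,
    selection_frequency,
)

POSITIVE_LABEL = "infection"


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Patient-grouped outer/inner split assignments (folds are 1-based)."""

    outer_assignments: dict[str, int]
    inner_assignments: dict[int, dict[str, int]]
    outer_k: int
    inner_k: int
    seed: int

    def test_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.outer_assignments.items() if f == fold)

    def pool_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.outer_assignments.items() if f != fold)


def _stratified_chunks(pids: list[str], k: int, rng: np.random.Generator,
                       rotate: int) -> list[list[str]]:
    pids = list(pids)
    rng.shuffle(pids)
    n = len(pids)
    base, rem = divmod(n, k)
    sizes = [base + (1 if (i - rotate) % k < rem else 0) for i in range(k)]
    chunks, start = [], 0
    for s in sizes:
        chunks.append(pids[start : start + s])
        start += s
    return chunks


def make_fold_plan(patients: pd.DataFrame, outer_k: int = 5, inner_k: int = 3,
                   seed: int = 0) -> FoldPlan:
    """Stratified-by-label, patient-grouped nested fold plan.

    ``patients`` has columns (patient_id, label). Remainder patients are
    rotated across classes so outer fold sizes differ by at most one.
    """
    labels = sorted(patients["label"].unique())
    for lab in labels:
        if (patients["label"] == lab).sum() < outer_k:
            raise ValueError(f"need >= {outer_k} patients of class {lab!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    outer: dict[str, int] = {}
    for ci, lab in enumerate(labels):
        pids = patients.loc[patients["label"] == lab, "patient_id"].tolist()
        rem = len(pids) % outer_k
        chunks = _stratified_chunks(pids, outer_k, rng, rotate=ci * rem)
        for f, chunk in enumerate(chunks, start=1):
            for p in chunk:
                outer[p] = f
    inner: dict[int, dict[str, int]] = {}
    lab_of = dict(zip(patients["patient_id"], patients["label"]))
    for f in range(1, outer_k + 1):
        rng_f = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(f,)))
        assign: dict[str, int] = {}
        pool = [p for p, fo in outer.items() if fo != f]
        for ci, lab in enumerate(labels):
            pids = [p for p in pool if lab_of[p] == lab]
            rem = len(pids) % inner_k
            chunks = _stratified_chunks(pids, inner_k, rng_f, rotate=ci * rem)
            for g, chunk in enumerate(chunks, start=1):
                for p in chunk:
                    assign[p] = g
        inner[f] = assign
    return FoldPlan(outer, inner, outer_k, inner_k, seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(patch: np.ndarray, rng: np.random.Generator,
            rotation_deg: float = 15.0, zoom: float = 0.10,
            translation: float = 0.10, flips: bool = True,
            p: float = 0.5) -> np.ndarray:
    """Random rotation / zoom / translation / flips, each with probability p.

    Geometric transforms compose around the patch center; interpolation is
    bilinear with edge replication, so the output shape equals the input
    shape. An all-off draw returns the input unchanged.
    """
    out = patch
    h, w = patch.shape[:2]
    angle = rng.uniform(-rotation_deg, rotation_deg) if rng.random() < p else 0.0
    scale = 1.0 + rng.uniform(-zoom, zoom) if rng.random() < p else 1.0
    if rng.random() < p:
        tr = rng.uniform(-translation, translation, size=2) * (w, h)
    else:
        tr = np.zeros(2)
    do_hflip = flips and rng.random() < p
    do_vflip = flips and rng.random() < p

    if angle != 0.0 or scale != 1.0 or np.any(tr != 0):
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        t = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=np.deg2rad(angle), scale=scale)
            + AffineTransform(translation=center + tr)
        )
        out = warp(out, t.inverse, order=1, mode="edge", preserve_range=True)
    if do_hflip:
        out = out[:, ::-1]
    if do_vflip:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# training schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseConfig:
    lr: float
    max_epochs: int
    early_stop_patience: int
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-7
    freeze_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.min_lr > self.lr:
            raise ValueError("min_lr must not exceed the phase learning rate")
        if self.early_stop_patience >= self.max_epochs + 1:
            raise ValueError("patience must be smaller than the epoch budget")


@dataclass(frozen=True)
class TrainConfig:
    """Two-phase schedule, augmentation ranges, batching, and seeds."""

    phase1: PhaseConfig = PhaseConfig(lr=1e-4, max_epochs=200,
                                      early_stop_patience=10)
    phase2: PhaseConfig = PhaseConfig(lr=1e-5, max_epochs=20,
                                      early_stop_patience=5,
                                      freeze_fraction=0.7)
    rotation_deg: float = 15.0
    zoom: float = 0.10
    translation: float = 0.10
    flips: bool = True
    augment_prob: float = 0.5
    batch_size: int = 16
    weight_carryover: bool = False
    seed: int = 0

    @classmethod
    def smoke(cls, seed: int = 0, weight_carryover: bool = False) -> "TrainConfig":
        """Desk-scale schedule: same two-phase structure, shorter budgets
        and a larger phase-1 step suited to a compact model trained for a
        handful of epochs."""
        return cls(
            phase1=PhaseConfig(lr=1e-3, max_epochs=20, early_stop_patience=6,
                               plateau_patience=3),
            phase2=PhaseConfig(lr=1e-4, max_epochs=4, early_stop_patience=3,
                               freeze_fraction=0.7),
            batch_size=16, seed=seed, weight_carryover=weight_carryover,
        )


class PlateauEarlyStop:
    """Validation-loss driven learning-rate plateau reduction + early stop.

    After the best loss fails to improve for ``plateau_patience`` epochs the
    learning rate is multiplied by ``factor`` (floored at ``min_lr``); after
    ``stop_patience`` epochs without improvement training stops. The
    weights of the best epoch are restored by the caller.
    """

    def __init__(self, lr: float, factor: float = 0.5, min_lr: float = 1e-7,
                 plateau_patience: int = 5, stop_patience: int = 10) -> None:
        self.lr = lr
        self.factor = factor
        self.min_lr = min_lr
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self._wait_stop = 0
        self._wait_lr = 0

    def update(self, val_loss: float) -> tuple[float, bool, bool]:
        """Feed one epoch's validation loss -> (lr, should_stop, is_best)."""
        improved = val_loss < self.best
        if improved:
            self.best = val_loss
            self._wait_stop = 0
            self._wait_lr = 0
        else:
            self._wait_stop += 1
            self._wait_lr += 1
            if self._wait_lr >= self.plateau_patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self._wait_lr = 0
        return self.lr, self._wait_stop >= self.stop_patience, improved


@dataclass
class DataSplit:
    """Arrays for one split: network inputs, targets, bookkeeping."""

    images: np.ndarray  # (N, H, W, C)
    radiomics: np.ndarray | None
    onehot: np.ndarray  # (N, 2), column 1 = infection
    labels: np.ndarray  # (N,) ints, 1 = infection
    patient_ids: tuple[str, ...]
    hemispheres: tuple[str, ...]


def _augment_batch(images: np.ndarray, rng: np.random.Generator,
                   cfg: TrainConfig) -> np.ndarray:
    out = np.empty_like(images)
    for i in range(images.shape[0]):
        a = augment(images[i, :, :, 0], rng, cfg.rotation_deg, cfg.zoom,
                    cfg.translation, cfg.flips, cfg.augment_prob)
        out[i] = a[..., None]
    return out


def train_two_phase(model: ModelHandle, train: DataSplit, val: DataSplit,
                    config: TrainConfig) -> tuple[ModelHandle, pd.DataFrame]:
    """Run both training phases; returns the model (best-val weights
    restored after each phase) and the per-epoch history."""
    overlap = set(train.patient_ids) & set(val.patient_ids)
    if overlap:
        raise LeakageError(f"patients in both train and val: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(17,)))
    history: list[dict] = []
    for phase_name, phase in (("phase1", config.phase1), ("phase2", config.phase2)):
        if phase.freeze_fraction is not None:
            freeze_fraction(model, phase.freeze_fraction)
        else:
            unfreeze_all(model)
        opt = model.make_optimizer(phase.lr)
        sched = PlateauEarlyStop(phase.lr, phase.plateau_factor, phase.min_lr,
                                 phase.plateau_patience,
                                 phase.early_stop_patience)
        best_weights = model.get_weights()
        n = train.images.shape[0]
        for epoch in range(1, phase.max_epochs + 1):
            idx = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                b = idx[start : start + config.batch_size]
                imgs = _augment_batch(train.images[b], rng, config)
                rad = None if train.radiomics is None else train.radiomics[b]
                losses.append(model.train_step(opt, imgs, rad, train.onehot[b]))
            val_loss = model.loss(val.images, val.radiomics, val.onehot)
            probs = model.predict_proba(val.images, val.radiomics)
            val_acc = float((probs.argmax(1) == val.labels).mean())
            new_lr, stop, is_best = sched.update(val_loss)
            if is_best:
                best_weights = model.get_weights()
            opt.lr = new_lr
            history.append(dict(phase=phase_name, epoch=epoch, lr=new_lr,
                                train_loss=float(np.mean(losses)),
                                val_loss=val_loss, val_acc=val_acc))
            if stop:
                break
        model.set_weights(best_weights)
    unfreeze_all(model)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    """ROI-level classification metrics for one outer fold (percent)."""

    fold_id: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_points: np.ndarray  # (n, 2) columns (fpr, tpr)
    auc: float


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    fold_id: int = 0) -> FoldMetrics:
    """Metrics from infection-class probabilities and 0/1 labels.

    Decisions use argmax (threshold 0.5); ROC sweeps the probability. With
    single-class labels the ROC/AUC are undefined and reported as NaN.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.shape[0] != y.shape[0]:
        raise ValueError("probabilities and labels must have equal length")
    pred = (probs >= 0.5).astype(int)
    acc = accuracy_score(y, pred) * 100
    prec = precision_score(y, pred, zero_division=0) * 100
    rec = recall_score(y, pred, zero_division=0) * 100
    f1 = f1_score(y, pred, zero_division=0) * 100
    if np.unique(y).size < 2:
        warnings.warn("single-class labels: ROC/AUC undefined", RuntimeWarning)
        roc = np.empty((0, 2))
        auc_val = float("nan")
    else:
        fpr, tpr, _ = roc_curve(y, probs)
        roc = np.column_stack([fpr, tpr])
        auc_val = float(sk_auc(fpr, tpr))
    return FoldMetrics(fold_id, float(acc), float(prec), float(rec),
                       float(f1), roc, auc_val)


def aggregate_folds(metrics: Sequence[FoldMetrics],
                    fpr_grid_step: float = 0.01) -> dict:
    """Mean +- sample sd per metric, and the vertically averaged ROC."""
    if len(metrics) < 2:
        raise ValueError("need >= 2 folds to aggregate")
    table = pd.DataFrame(
        dict(metric=name,
             mean=float(np.mean([getattr(m, name) for m in metrics])),
             sd=float(np.std([getattr(m, name) for m in metrics], ddof=1)))
        for name in ("accuracy", "precision", "recall", "f1")
    )
    grid = np.arange(0.0, 1.0 + fpr_grid_step / 2, fpr_grid_step)
    tprs, aucs = [], []
    for m in metrics:
        if m.roc_points.size == 0:
            continue
        fpr, tpr = m.roc_points[:, 0], m.roc_points[:, 1]
        tprs.append(np.interp(grid, fpr, tpr))
        aucs.append(m.auc)
    roc = None
    if tprs:
        tprs_arr = np.vstack(tprs)
        roc = dict(
            fpr=grid,
            tpr_mean=tprs_arr.mean(axis=0),
            tpr_sd=tprs_arr.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(grid),
            auc_mean=float(np.mean(aucs)),
            auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        )
    return dict(table=table, roc=roc)


# ---------------------------------------------------------------------------
# patient-wise decision rules
# ---------------------------------------------------------------------------

@dataclass
class PatientDecision:
    """Outcome of the strict bilateral rule for one patient."""

    patient_id: str
    label: str
    roi_predictions: tuple[int, int]  # 1 = infected, per hemisphere
    correct: bool
    discordant: bool


def strict_patient_accuracy(
    roi_predictions: dict[str, tuple[int, int]],
    labels: dict[str, str],
) -> tuple[dict[str, float], list[PatientDecision]]:
    """Strict clinically motivated rule on paired (left, right) predictions.

    An infected patient counts as correct if at least one ROI is flagged
    infected; a control counts as correct only if both ROIs are flagged
    non-infected. Returns per-class accuracy (fractions) and the
    per-patient decisions.
    """
    decisions = []
    for pid, preds in roi_predictions.items():
        if len(preds) != 2:
            raise ValueError(f"patient {pid} must have exactly 2 ROI predictions")
        label = labels[pid]
        any_pos = any(int(p) == 1 for p in preds)
        correct = any_pos if label == POSITIVE_LABEL else not any_pos
        decisions.append(
            PatientDecision(pid, label, (int(preds[0]), int(preds[1])),
                            bool(correct), preds[0] != preds[1])
        )
    acc = {}
    for cls in (POSITIVE_LABEL, "control"):
        sub = [d for d in decisions if d.label == cls]
        if sub:
            acc[cls] = float(np.mean([d.correct for d in sub]))
    return acc, decisions


def discordance_rate(fold_decisions: Sequence[Sequence[PatientDecision]]) -> tuple[float, float]:
    """Percent of patients with disagreeing bilateral predictions, mean +- sd
    across folds (sample sd; 0 for a single fold)."""
    rates = []
    for decisions in fold_decisions:
        if not decisions:
            raise ValueError("fold without patient decisions")
        rates.append(100.0 * np.mean([d.discordant for d in decisions]))
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return mean, sd


# ---------------------------------------------------------------------------
# nested cross-validation driver
# ---------------------------------------------------------------------------

def _prepare_inputs(samples: Sequence[RoiSample], input_size: int) -> dict[str, np.ndarray]:
    """Patch preparation per ROI: crop 32, resize to the network input size,
    min-max standardize, replicate channels."""
    out = {}
    for s in samples:
        crop = crop_patch(s, 32)
        patch = crop if input_size == 32 else resize_bicubic(crop, input_size)
        out[f"{s.patient_id}|{s.hemisphere}"] = standardize_patch(patch)
    return out


def _split_for(pids: set[str], samples, inputs, feat_rows, sel, labels01):
    keys = [i for i, s in enumerate(samples) if s.patient_id in pids]
    imgs = np.stack([inputs[f"{samples[i].patient_id}|{samples[i].hemisphere}"]
                     for i in keys])
    rad = apply_scaler(sel, feat_rows.iloc[keys]) if sel is not None else None
    y = np.array([labels01[i] for i in keys])
    onehot = np.eye(2)[y]
    return DataSplit(imgs, rad, onehot, y,
                     tuple(samples[i].patient_id for i in keys),
                     tuple(samples[i].hemisphere for i in keys))


def run_nested_cv(cohort: Sequence[RoiSample], region: str,
                  model_kind: str = "fusion",
                  model_config: FusionConfig | None = None,
                  train_config: TrainConfig | None = None,
                  features: pd.DataFrame | None = None,
                  outer_k: int = 5, inner_k: int = 3,
                  selection_k: int = 50, n_bins: int = 32) -> dict:
    """Full nested CV for one region and one architecture.

    Returns fold metrics, per-fold selections, patient decisions,
    aggregated statistics, the selection-frequency table, and training
    histories.
    """
    if model_kind not in ("base", "fusion"):
        raise ValueError("model_kind must be 'base' or 'fusion'")
    model_config = model_config or FusionConfig.tiny()
    train_config = train_config or TrainConfig.smoke()
    samples = [s for s in cohort if s.region == region]
    if not samples:
        raise ValueError(f"no samples for region {region!r}")
    if features is None:
        features = extract_table(samples, n_bins=n_bins)
    features = features.reset_index(drop=True)
    key = lambda df: list(zip(df["patient_id"], df["hemisphere"]))
    feat_region = features[features["region"] == region].reset_index(drop=True)
    order = {k: i for i, k in enumerate(key(feat_region))}
    samples = sorted(samples, key=lambda s: order[(s.patient_id, s.hemisphere)])
    labels01 = [1 if s.label == POSITIVE_LABEL else 0 for s in samples]

    patients = pd.DataFrame(
        sorted({(s.patient_id, s.label) for s in samples}),
        columns=["patient_id", "label"],
    )
    plan = make_fold_plan(patients, outer_k, inner_k, seed=train_config.seed)
    inputs = _prepare_inputs(samples, model_config.input_size)
    feat_cols = feat_region.drop(columns=["patient_id", "label", "region",
                                          "hemisphere"])

    fold_metrics, selections, fold_decisions, histories = [], [], [], []
    prev_weights = None
    for f in range(1, outer_k + 1):
        test_p = set(plan.test_patients(f))
        pool_p = set(plan.pool_patients(f))
        val_p = {p for p, g in plan.inner_assignments[f].items() if g == 1}
        train_p = pool_p - val_p
        assert not (test_p & pool_p), "outer partition violated"

        pool_rows = [i for i, s in enumerate(samples) if s.patient_id in pool_p]
        sel = None
        if model_kind == "fusion":
            scores = rank_features(
                feat_cols.iloc[pool_rows].to_numpy(),
                np.array([labels01[i] for i in pool_rows]),
                sample_patients=[samples[i].patient_id for i in pool_rows],
                test_patients=test_p,
            )
            sel = select_top_k(scores, k=selection_k, fold_id=f)
            train_rows = [i for i, s in enumerate(samples)
                          if s.patient_id in train_p]
            fit_scaler(sel, feat_region.iloc[train_rows])
            selections.append(sel)

        train_split = _split_for(train_p, samples, inputs, feat_region, sel, labels01)
        val_split = _split_for(val_p, samples, inputs, feat_region, sel, labels01)
        test_split = _split_for(test_p, samples, inputs, feat_region, sel, labels01)
        if set(test_split.patient_ids) & (set(train_split.patient_ids)
                                          | set(val_split.patient_ids)):
            raise LeakageError("test patients reached training data")

        model_seed = int(np.random.SeedSequence(
            train_config.seed, spawn_key=(100 + f,)).generate_state(1)[0] % (2**31))
        builder = build_fusion_model if model_kind == "fusion" else build_base_model
        model = builder(model_config, seed=model_seed)
        if train_config.weight_carryover and prev_weights is not None:
            model.set_weights(prev_weights)
        fold_cfg = replace(train_config, seed=model_seed)
        model, hist = train_two_phase(model, train_split, val_split, fold_cfg)
        histories.append(hist.assign(fold=f))
        if train_config.weight_carryover:
            prev_weights = model.get_weights()

        probs = model.predict_proba(test_split.images, test_split.radiomics)[:, 1]
        fold_metrics.append(compute_metrics(probs, test_split.labels, fold_id=f))

        pred = (probs >= 0.5).astype(int)
        by_patient: dict[str, dict[str, int]] = {}
        for pid, hemi, p in zip(test_split.patient_ids,
                                test_split.hemispheres, pred):
            by_patient.setdefault(pid, {})[hemi] = int(p)
        roi_preds = {pid: (d["left"], d["right"]) for pid, d in by_patient.items()}
        label_map = dict(zip(patients["patient_id"], patients["label"]))
        _, decisions = strict_patient_accuracy(roi_preds, label_map)
        fold_decisions.append(decisions)

    agg = aggregate_folds(fold_metrics)
    result = dict(
        plan=plan,
        fold_metrics=fold_metrics,
        aggregate=agg,
        selections=selections,
        selection_frequency=selection_frequency(selections) if selections else None,
        fold_decisions=fold_decisions,
        discordance=discordance_rate(fold_decisions),
        histories=pd.concat(histories, ignore_index=True),
    )
    # per-fold strict patient-wise accuracy, averaged
    strict = {"infection": [], "control": []}
    for decisions in fold_decisions:
        acc, _ = strict_patient_accuracy(
            {d.patient_id: d.roi_predictions for d in decisions},
            {d.patient_id: d.label for d in decisions},
        )
        for cls, v in acc.items():
            strict[cls].append(v)
    result["strict_patient_accuracy"] = {
        cls: (float(np.mean(v)) if v else float("nan")) for cls, v in strict.items()
    }
    return result
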