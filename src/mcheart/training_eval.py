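"""Training loop, patient-level aggregation, and challenge-style scoring.

Training is single-instance: every recording is an independent training
sample carrying its patient's murmur label, and only at inference are the
per-site murmur probabilities of a patient collapsed (by their maximum) into
one patient-level probability. The underlying network is a binary
Present-vs-Absent classifier with cost-sensitive weighting of the Present
class; the three-way Present / Unknown / Absent decision is carved out after
training by a probability band (t_low, t_high) fitted to maximize the
weighted accuracy of the training patients.

Weighted accuracy scores the 3x3 murmur confusion with expert-class weights
5 (Present), 3 (Unknown), 1 (Absent):

    S = (5 m_PP + 3 m_UU + m_AA)
        / (5 (m_PP+m_UP+m_AP) + 3 (m_PU+m_UU+m_AU) + (m_PA+m_UA+m_AA))

and the clinical-outcome score weights true positives five-fold:

    S = (5 n_TP + n_TN) / (5 (n_TP+n_FN) + (n_FP+n_TN)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from ._nn import weighted_cross_entropy
from .augmentation import AugmentConfig, augment_batch
from .dsp_features import MCHeartFeaturizer, tensors_to_arrays
from .io_formats import MURMUR_LABELS, PatientRecord
from .relcnn_model import DEFAULT_BLOCK_FILTERS, ReLCNN, RelcnnConfig, build_relcnn

__all__ = [
    "TrainConfig",
    "MurmurConfusion",
    "OutcomeConfusion",
    "UnknownBand",
    "FeatureDataset",
    "weighted_accuracy",
    "outcome_score",
    "binary_metrics",
    "aggregate_patient",
    "fit_unknown_band",
    "classify_patient",
    "best_constant_weighted_accuracy",
    "learning_rate_schedule",
    "featurize_patients",
    "train",
    "evaluate",
    "evaluate_probs",
    "patient_probabilities",
    "ReLCNNClassifier",
]

CLASS_ORDER = ("Present", "Unknown", "Absent")
_EXPERT_WEIGHTS = {"Present": 5.0, "Unknown": 3.0, "Absent": 1.0}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, sigmoid-decay learning rate)."""

    epochs: int = 100
    batch_size: int = 64
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    class_weight_present: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_end >= self.lr_start:
            raise ValueError("lr_end must be below lr_start")
        if self.class_weight_present < 1:
            raise ValueError("class weight must be >= 1")


def learning_rate_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Logistic interpolation from lr_start to lr_end over the epochs.

    lr(e) = lr_end + (lr_start - lr_end) * sigmoid(-gamma (e - E/2)) with
    gamma = 10/E, so lr(0) is within 1% of lr_start and the final epoch sits
    within 1% of lr_start's scale above lr_end.
    """
    e_total = cfg.epochs
    gamma = 10.0 / e_total
    return cfg.lr_end + (cfg.lr_start - cfg.lr_end) * float(
        _sigmoid(-gamma * (epoch - e_total / 2.0))
    )


# ---------------------------------------------------------------------------
# Confusions and scores


@dataclass
class MurmurConfusion:
    """3x3 counts, rows = classifier class, columns = expert class, both in
    the order Present, Unknown, Absent."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 matrix")

    @classmethod
    def from_labels(cls, predicted, expert) -> "MurmurConfusion":
        idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        counts = np.zeros((3, 3), dtype=np.int64)
        for p, e in zip(predicted, expert, strict=True):
            counts[idx[p], idx[e]] += 1
        return cls(counts)


@dataclass
class OutcomeConfusion:
    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_fn, self.n_tn) < 0:
            raise ValueError("counts must be nonnegative")


def weighted_accuracy(c: MurmurConfusion) -> float:
    m = np.asarray(c.counts, dtype=np.float64)
    col_w = np.array([5.0, 3.0, 1.0])
    denominator = float((col_w * m.sum(axis=0)).sum())
    if denominator == 0:
        raise ValueError("weighted accuracy undefined for an all-zero confusion")
    return float((col_w * np.diag(m)).sum() / denominator)


def outcome_score(c: OutcomeConfusion) -> float:
    denominator = 5.0 * (c.n_tp + c.n_fn) + (c.n_fp + c.n_tn)
    if denominator == 0:
        raise ValueError("outcome score undefined for an empty confusion")
    return float((5.0 * c.n_tp + c.n_tn) / denominator)


def binary_metrics(
    scores, labels, threshold: float = 0.5
) -> dict[str, float]:
    """AUROC, AUPRC, F-measure and accuracy of patient-level probabilities.

    The F-measure and accuracy use the given operating threshold; the rank
    metrics require both classes to be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("rank metrics undefined when only one class is present")
    preds = (scores >= threshold).astype(np.int64)
    return {
        "AUROC": float(roc_auc_score(labels, scores)),
        "AUPRC": float(average_precision_score(labels, scores)),
        "F-Measure": float(f1_score(labels, preds, zero_division=0.0)),
        "Acc": float(accuracy_score(labels, preds)),
    }


def aggregate_patient(per_site_probs) -> float:
    """Patient-level murmur probability: max over auscultation sites."""
    probs = list(per_site_probs)
    if not probs:
        raise ValueError("need at least one per-site probability")
    return float(max(probs))


@dataclass(frozen=True)
class UnknownBand:
    """Probability band [t_low, t_high): Present above, Unknown inside,
    Absent below."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low <= self.t_high <= 1.0:
            raise ValueError("need 0 <= t_low <= t_high <= 1")


def classify_patient(p: float, band: UnknownBand) -> str:
    if p >= band.t_high:
        return "Present"
    if p >= band.t_low:
        return "Unknown"
    return "Absent"


def fit_unknown_band(
    train_probs, train_labels, grid_step: float = 0.01
) -> UnknownBand:
    """Grid-search the (t_low, t_high) pair maximizing weighted accuracy.

    Ties break toward the widest Absent region (largest t_low) and then to
    the smallest t_high, making the result canonical; the degenerate optimum
    when all patients score below every threshold is therefore (1.0, 1.0).
    """
    probs = np.asarray(train_probs, dtype=np.float64)
    labels = list(train_labels)
    if probs.size == 0:
        raise ValueError("cannot fit a threshold band on an empty set")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    # counts of p >= g per expert class, for every grid point
    n_ge = {}
    n_class = {}
    for c in CLASS_ORDER:
        pc = probs[[lab == c for lab in labels]]
        n_class[c] = pc.size
        n_ge[c] = (pc[None, :] >= grid[:, None]).sum(axis=1)
    denom = float(sum(_EXPERT_WEIGHTS[c] * n_class[c] for c in CLASS_ORDER))
    if denom == 0:
        raise ValueError("no labeled patients")

    best = None
    for i_low, t_low in enumerate(grid):
        for i_high in range(i_low, grid.size):
            # diagonal counts under this band
            m_pp = n_ge["Present"][i_high]
            m_uu = n_ge["Unknown"][i_low] - n_ge["Unknown"][i_high]
            m_aa = n_class["Absent"] - n_ge["Absent"][i_low]
            score = (5.0 * m_pp + 3.0 * m_uu + 1.0 * m_aa) / denom
            key = (score, t_low, -grid[i_high])
            if best is None or key > best[0]:
                best = (key, UnknownBand(float(t_low), float(grid[i_high])))
    return best[1]


def best_constant_weighted_accuracy(expert_labels) -> float:
    """Weighted accuracy of the best constant prediction for these experts."""
    scores = []
    for const in CLASS_ORDER:
        conf = MurmurConfusion.from_labels([const] * len(expert_labels), expert_labels)
        scores.append(weighted_accuracy(conf))
    return max(scores)


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class FeatureDataset:
    """Per-recording feature arrays with the patient bookkeeping needed for
    single-instance training and patient-level evaluation."""

    X: np.ndarray  # (n_recordings, channels, n_mels, frames)
    scalars: np.ndarray  # (n_recordings, n_scalars)
    patient_ids: list[str]
    murmur: list[str]  # patient label inherited by each recording

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.patient_ids) == len(self.murmur) == self.scalars.shape[0] == n):
            raise ValueError("inconsistent dataset lengths")
        for m in self.murmur:
            if m not in MURMUR_LABELS:
                raise ValueError(f"bad murmur label {m!r}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def patient_labels(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for pid, m in zip(self.patient_ids, self.murmur):
            out[pid] = m
        return out


def featurize_patients(
    patients: list[PatientRecord], featurizer: MCHeartFeaturizer
) -> FeatureDataset:
    """Extract features for every recording of every patient.

    Recordings at unnamed ("OTHER") auscultation sites are dropped when the
    featurizer's ``drop_other_sites`` flag is set (the default pipeline
    filter); the filter is per-recording, so a patient survives as long as
    one named-site recording remains.
    """
    recs, pids, murmurs = [], [], []
    for p in patients:
        for r in p.recordings:
            if featurizer.drop_other_sites and r.site == "OTHER" and len(
                [q for q in p.recordings if q.site != "OTHER"]
            ):
                continue
            recs.append(r)
            pids.append(p.patient_id)
            murmurs.append(p.murmur)
    tensors = featurizer.fit(recs).transform(recs)
    X, scalars = tensors_to_arrays(tensors)
    return FeatureDataset(X=X, scalars=scalars, patient_ids=pids, murmur=murmurs)


# ---------------------------------------------------------------------------
# Training and evaluation


def _binary_targets(murmur: list[str]) -> np.ndarray:
    """One-hot (Absent, Present) targets; Unknown rows are all-zero."""
    y = np.zeros((len(murmur), 2))
    for i, m in enumerate(murmur):
        if m == "Present":
            y[i, 1] = 1.0
        elif m == "Absent":
            y[i, 0] = 1.0
    return y


def _forward_probs(model: ReLCNN, ds: FeatureDataset, batch: int = 64) -> np.ndarray:
    probs = []
    for i in range(0, ds.n, batch):
        probs.append(model.predict_proba(ds.X[i : i + batch], ds.scalars[i : i + batch]))
    return np.concatenate(probs)[:, 1]  # P(Present)


def patient_probabilities(
    model: ReLCNN, ds: FeatureDataset
) -> dict[str, tuple[float, str]]:
    """Per-patient (max-aggregated probability, expert label)."""
    rec_probs = _forward_probs(model, ds)
    per_patient: dict[str, list[float]] = {}
    for pid, p in zip(ds.patient_ids, rec_probs):
        per_patient.setdefault(pid, []).append(float(p))
    labels = ds.patient_labels()
    return {
        pid: (aggregate_patient(ps), labels[pid]) for pid, ps in per_patient.items()
    }


def train(
    model: ReLCNN,
    train_set: FeatureDataset,
    val_set: FeatureDataset | None = None,
    cfg: TrainConfig = TrainConfig(),
    aug: AugmentConfig | None = None,
) -> tuple[ReLCNN, dict[str, list[float]]]:
    """Single-instance training with cost-sensitive cross-entropy.

    Unknown-labeled recordings carry no binary target and are excluded from
    the loss (they still take part in threshold fitting and evaluation).
    History records the mean training loss per epoch and, when a validation
    set is supplied, the validation weighted accuracy under a band fitted on
    the training patients.
    """
    if train_set.n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    keep = np.array([m != "Unknown" for m in train_set.murmur])
    x_all, s_all = train_set.X[keep], train_set.scalars[keep]
    y_all = _binary_targets([m for m, k in zip(train_set.murmur, keep) if k])
    if x_all.shape[0] == 0:
        raise ValueError("no Present/Absent recordings to train on")
    class_weights = np.array([1.0, cfg.class_weight_present])
    opt = model.make_optimizer(cfg.lr_start)
    history: dict[str, list[float]] = {"loss": [], "val_weighted_accuracy": []}

    for epoch in range(cfg.epochs):
        opt.lr = learning_rate_schedule(epoch, cfg)
        order = rng.permutation(x_all.shape[0])
        losses = []
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bx, by, bs = x_all[idx], y_all[idx], s_all[idx]
            if aug is not None:
                bx, by, bs = augment_batch(bx, by, aug, rng, scalars=bs)
            logits = model.forward_logits(bx, bs, train=True)
            loss, dlogits = weighted_cross_entropy(logits, by, class_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss}; "
                    "check feature scaling and learning rate"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if val_set is not None:
            model.refresh_batchnorm(x_all, s_all)
            train_pp = patient_probabilities(model, train_set)
            band = fit_unknown_band(
                [p for p, _ in train_pp.values()], [m for _, m in train_pp.values()]
            )
            report = evaluate_probs(patient_probabilities(model, val_set), band)
            history["val_weighted_accuracy"].append(report["Weighted Acc"])
    model.refresh_batchnorm(x_all, s_all)
    return model, history


def evaluate_probs(
    probs_by_patient: dict[str, tuple[float, str]], band: UnknownBand
) -> dict:
    """Score patient-level probabilities against expert labels.

    Produces the murmur confusion (row-major, class order Present, Unknown,
    Absent), weighted accuracy, the clinical-outcome score with classified-
    Present as the abnormal prediction and expert-Present as the abnormal
    state (Unknown experts excluded), and the binary rank metrics at the
    band's Present threshold.
    """
    pids = sorted(probs_by_patient)
    probs = np.array([probs_by_patient[p][0] for p in pids])
    expert = [probs_by_patient[p][1] for p in pids]
    predicted = [classify_patient(p, band) for p in probs]
    confusion = MurmurConfusion.from_labels(predicted, expert)

    known = [i for i, e in enumerate(expert) if e != "Unknown"]
    y_true = np.array([1 if expert[i] == "Present" else 0 for i in known])
    y_pred = np.array([1 if predicted[i] == "Present" else 0 for i in known])
    outcome = OutcomeConfusion(
        n_tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        n_fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        n_fn=int(((y_pred == 0) & (y_true == 1)).sum()),
        n_tn=int(((y_pred == 0) & (y_true == 0)).sum()),
    )
    report = {
        "confusion": confusion.counts.tolist(),
        "class_order": list(CLASS_ORDER),
        "Weighted Acc": weighted_accuracy(confusion),
        "outcome_score": outcome_score(outcome),
        "band": [band.t_low, band.t_high],
        "n_patients": len(pids),
    }
    try:
        report.update(binary_metrics(probs[known], y_true, threshold=band.t_high))
    except ValueError:
        pass  # single-class evaluation sets have no rank metrics
    return report


def evaluate(model: ReLCNN, ds: FeatureDataset, band: UnknownBand) -> dict:
    """Per-recording probabilities -> patient aggregation -> band -> scores."""
    return evaluate_probs(patient_probabilities(model, ds), band)


# ---------------------------------------------------------------------------
# sklearn-style estimator


class ReLCNNClassifier(ClassifierMixin, BaseEstimator):
    """Binary per-recording murmur classifier with the ReLCNN backbone.

    ``X`` is an array of feature tensors, shape (n_recordings, channels,
    n_mels, frames); ``scalars`` optionally carries per-recording side
    features. Labels may be strings ("Absent"/"Present") or {0, 1}; the
    positive class is the lexicographically larger one. Patient aggregation
    and the unknown band are applied on top of this estimator by
    :func:`patient_probabilities` / :func:`fit_unknown_band`.
    """

    def __init__(
        self,
        block_filters: tuple[int, ...] = DEFAULT_BLOCK_FILTERS,
        first_kernel: int = 5,
        mha_heads: int = 8,
        d_model: int = 64,
        use_mha: bool = True,
        activation: str = "swish",
        epochs: int = 100,
        batch_size: int = 64,
        lr_start: float = 1e-3,
        lr_end: float = 1e-5,
        class_weight_present: float = 3.0,
        augment: bool = True,
        mixup_alpha: float = 0.5,
        mixup_prob: float = 0.7,
        cutout_prob: float = 0.8,
        cutout_frac: tuple[float, float] = (0.25, 0.25),
        seed: int = 0,
    ) -> None:
        self.block_filters = block_filters
        self.first_kernel = first_kernel
        self.mha_heads = mha_heads
        self.d_model = d_model
        self.use_mha = use_mha
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.class_weight_present = class_weight_present
        self.augment = augment
        self.mixup_alpha = mixup_alpha
        self.mixup_prob = mixup_prob
        self.cutout_prob = cutout_prob
        self.cutout_frac = cutout_frac
        self.seed = seed

    def _dataset(self, X, y, scalars) -> FeatureDataset:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError("X must be (n, channels, n_mels, frames)")
        if scalars is None:
            scalars = np.zeros((X.shape[0], 0))
        scalars = np.asarray(scalars, dtype=np.float64)
        murmur = [
            "Present" if c == self.classes_[1] else "Absent" for c in np.asarray(y)
        ]
        pids = [f"r{i}" for i in range(X.shape[0])]
        return FeatureDataset(X=X, scalars=scalars, patient_ids=pids, murmur=murmur)

    def fit(self, X, y, scalars=None) -> "ReLCNNClassifier":
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_!r}")
        ds = self._dataset(X, y, scalars)
        cfg = RelcnnConfig(
            block_filters=tuple(self.block_filters),
            first_kernel=self.first_kernel,
            mha_heads=self.mha_heads,
            d_model=self.d_model,
            use_mha=self.use_mha,
            activation=self.activation,
            scalar_feature_names=tuple(
                f"s{i}" for i in range(ds.scalars.shape[1])
            ),
        )
        self.model_ = build_relcnn(cfg, ds.X.shape[1:], seed=self.seed)
        train_cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_start=self.lr_start,
            lr_end=self.lr_end,
            class_weight_present=self.class_weight_present,
            seed=self.seed,
        )
        aug = (
            AugmentConfig(
                mixup_alpha=self.mixup_alpha,
                mixup_prob=self.mixup_prob,
                cutout_prob=self.cutout_prob,
                cutout_frac=self.cutout_frac,
            )
            if self.augment
            else None
        )
        _, self.history_ = train(self.model_, ds, cfg=train_cfg, aug=aug)
        return self

    def predict_proba(self, X, scalars=None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if scalars is None:
            scalars = np.zeros((X.shape[0], self.model_.n_scalars))
        out = []
        for i in range(0, X.shape[0], 64):
            out.append(self.model_.predict_proba(X[i : i + 64], scalars[i : i + 64]))
        return np.concatenate(out)

    def predict(self, X, scalars=None) -> np.ndarray:
        return self.classes_[self.predict_proba(X, scalars).argmax(axis=1)]
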