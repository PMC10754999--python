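"""Training protocol: 7:3 split, 5-fold cross-validation, Adam, seeded runs.

The protocol mirrors a standard small-dataset spectroscopy study design:
replicate-averaged spectra are split once into a training and a held-out
test set in a 7:3 ratio; five-fold cross-validation inside the training set
reports mean +/- SD validation metrics; the reported model is then retrained
on the full training set and evaluated exactly once on the untouched test
set.  Defaults: batch size 8, 200 epochs, Adam with learning rate 1e-4, no
early stopping, no schedule.  The split is simple random by default (a
stratified variant is available); all randomness derives from the config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, DataError, NumericError
from .graph import LayerGraph, build
from .metrics import ConfusionMatrix, confusion_matrix
from .nn import Adam, Network, SoftmaxCrossEntropy
from .spectra import SpectralDataset


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 200
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    split_ratio: float = 0.7
    n_folds: int = 5
    stratified_split: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ConfigError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise DataError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class FoldResult:
    fold_index: int
    model: Network
    confusion: ConfusionMatrix
    history: dict  # per-epoch loss/accuracy traces


def split_train_test(ds: SpectralDataset, cfg: TrainConfig) -> SplitResult:
    """Single 7:3 sample-level split, deterministic given the seed.

    With ``stratified_split`` the per-class train proportions are preserved
    to within one sample; otherwise the split is simple random (so per-class
    test counts fluctuate, as they do in practice).
    """
    ids = ds.meta["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise DataError("split requires one spectrum per sample; average replicates first")
    if len(ids) < len(ds.class_names):
        raise DataError("fewer samples than classes")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    n_train = int(round(cfg.split_ratio * len(ids)))
    if cfg.stratified_split:
        train: list[str] = []
        labels = ds.labels
        for cname in ds.class_names:
            cls_ids = [i for i, lab in zip(ids, labels) if lab == cname]
            k = int(round(cfg.split_ratio * len(cls_ids)))
            perm = rng.permutation(len(cls_ids))
            train.extend(cls_ids[i] for i in perm[:k])
        train_set = set(train)
        test = [i for i in ids if i not in train_set]
    else:
        perm = rng.permutation(len(ids))
        train = [ids[i] for i in perm[:n_train]]
        train_set = set(train)
        test = [i for i in ids if i not in train_set]
    lab_by_id = dict(zip(ids, ds.labels))
    missing = set(ds.class_names) - {lab_by_id[i] for i in train}
    if missing:
        raise DataError(f"classes {sorted(missing)} absent from the training set; "
                        "use stratified_split or a larger dataset")
    return SplitResult(train_ids=train, test_ids=test)


def make_folds(train_ids: Sequence[str], n_folds: int, seed: int) -> list:
    """Partition ``train_ids`` into ``n_folds`` (fit_ids, val_ids) pairs.

    Validation sets are pairwise disjoint, their union is ``train_ids``, and
    fold sizes differ by at most one.  Deterministic given the seed.
    """
    train_ids = list(train_ids)
    if n_folds > len(train_ids):
        raise DataError(f"n_folds={n_folds} exceeds number of training samples {len(train_ids)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    perm = rng.permutation(len(train_ids))
    shuffled = [train_ids[i] for i in perm]
    # first (n % k) folds get the extra sample
    sizes = [len(shuffled) // n_folds + (1 if i < len(shuffled) % n_folds else 0)
             for i in range(n_folds)]
    folds, start = [], 0
    for sz in sizes:
        val = shuffled[start : start + sz]
        val_set = set(val)
        fit = [i for i in shuffled if i not in val_set]
        folds.append((fit, val))
        start += sz
    return folds


def _xy(ds: SpectralDataset):
    return ds.absorbance.astype(np.float32), ds.label_indices


def train_model(
    graph: LayerGraph,
    fit_ds: SpectralDataset,
    val_ds: SpectralDataset | None,
    cfg: TrainConfig,
    *,
    model_seed: int = 0,
) -> tuple:
    """Train one network; returns ``(network, history)``.

    ``history`` holds per-epoch training loss/accuracy (and validation
    loss/accuracy when a validation set is given).  Final-epoch weights are
    returned; there is no early stopping.
    """
    if graph.input_length != fit_ds.grid.n_points:
        raise DataError(
            f"graph input_length {graph.input_length} != grid points {fit_ds.grid.n_points}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2, model_seed)))
    net = Network(graph, rng)
    opt = Adam(net, lr=cfg.learning_rate)
    loss_fn = SoftmaxCrossEntropy()
    X, y = _xy(fit_ds)
    history: dict[str, list] = {"loss": [], "accuracy": []}
    if val_ds is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(X[idx], train=True)
            loss = loss_fn.forward(logits, y[idx])
            if not np.isfinite(loss):
                raise NumericError(f"non-finite training loss at epoch {epoch}")
            net.backward(loss_fn.backward())
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.sum(losses) / len(X)))
        history["accuracy"].append(correct / len(X))
        if val_ds is not None:
            Xv, yv = _xy(val_ds)
            probs = net.predict_proba(Xv)
            vloss = float(-np.log(np.clip(probs[np.arange(len(yv)), yv], 1e-12, None)).mean())
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(float((probs.argmax(axis=1) == yv).mean()))
    return net, history


def evaluate_model(net: Network, ds: SpectralDataset) -> tuple:
    """Returns ``(ConfusionMatrix, probability matrix)`` for a dataset."""
    X, y = _xy(ds)
    probs = net.predict_proba(X)
    pred = probs.argmax(axis=1)
    names = list(ds.class_names)
    cm = confusion_matrix(
        [names[i] for i in y], [names[i] for i in pred], class_names=names
    )
    return cm, probs


@dataclass
class ExperimentResult:
    """Everything produced for one architecture in :func:`run_experiment`."""

    model_name: str
    graph: LayerGraph
    folds: list  # FoldResult
    final_model: Network
    test_confusion: ConfusionMatrix
    test_probabilities: np.ndarray
    test_ids: list
    test_labels: list
    test_predictions: list
    cv_val_accuracy_mean: float
    cv_val_accuracy_sd: float


def run_experiment(
    ds: SpectralDataset,
    model_names: Sequence[str],
    cfg: TrainConfig,
    *,
    builder_kwargs: dict | None = None,
) -> dict:
    """Full protocol for each named architecture on one dataset.

    ``ds`` must be replicate-averaged (one spectrum per sample).  For each
    architecture: five cross-validation folds inside the training set, then
    a final model trained on the full training set and evaluated once on the
    held-out test set.  The test set appears in no fold.  Returns
    ``{model_name: ExperimentResult}``.
    """
    split = split_train_test(ds, cfg)
    folds = make_folds(split.train_ids, cfg.n_folds, cfg.seed)
    test_set = set(split.test_ids)
    for fit_ids, val_ids in folds:
        assert not (set(fit_ids) | set(val_ids)) & test_set, "fold leaks into test set"
        assert not set(fit_ids) & set(val_ids), "fit/val overlap inside a fold"
    results: dict[str, ExperimentResult] = {}
    kwargs = builder_kwargs or {}
    for mi, name in enumerate(model_names):
        graph = build(name, ds.grid.n_points, len(ds.class_names), **kwargs.get(name, {}))
        fold_results = []
        for fi, (fit_ids, val_ids) in enumerate(folds):
            net, hist = train_model(
                graph, ds.select_samples(fit_ids), ds.select_samples(val_ids), cfg,
                model_seed=1000 * mi + fi,
            )
            cm, _ = evaluate_model(net, ds.select_samples(val_ids))
            fold_results.append(FoldResult(fi, net, cm, hist))
        final_net, _ = train_model(
            graph, ds.select_samples(split.train_ids), None, cfg, model_seed=1000 * mi + 999
        )
        test_ds = ds.select_samples(split.test_ids)
        cm, probs = evaluate_model(final_net, test_ds)
        names = list(ds.class_names)
        yt = test_ds.label_indices
        val_accs = [f.confusion.accuracy() for f in fold_results]
        results[name] = ExperimentResult(
            model_name=name,
            graph=graph,
            folds=fold_results,
            final_model=final_net,
            test_confusion=cm,
            test_probabilities=probs,
            test_ids=test_ds.meta["sample_id"].astype(str).tolist(),
            test_labels=[names[i] for i in yt],
            test_predictions=[names[i] for i in probs.argmax(axis=1)],
            cv_val_accuracy_mean=float(np.mean(val_accs)),
            cv_val_accuracy_sd=float(np.std(val_accs, ddof=1)) if len(val_accs) > 1 else 0.0,
        )
    return results
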