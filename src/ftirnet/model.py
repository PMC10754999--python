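"""Model/Results front end.

:class:`SpectrumClassifier` bundles a dataset, an architecture and a
training configuration; :meth:`~SpectrumClassifier.fit` runs the full
protocol (train/test split, k-fold cross-validation, final refit, held-out
evaluation) and returns a :class:`ClassificationResults` carrying the
confusion matrix, all scalar metrics, per-class ROC curves and a
``summary()`` table.  :func:`benchmark` runs several architectures on the
same split for side-by-side comparison.

Example
-------
>>> from ftirnet import synth, spectra
>>> from ftirnet.model import SpectrumClassifier
>>> from ftirnet.training import TrainConfig
>>> ds = spectra.average_replicates(synth.generate(synth.preset("easy", seed=1)))
>>> res = SpectrumClassifier(ds, architecture="msresnet",
...                          config=TrainConfig(epochs=30, seed=1)).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .graph import ARCHITECTURES
from .metrics import MetricsReport, full_report
from .spectra import SpectralDataset, average_replicates, normalize
from .training import ExperimentResult, TrainConfig, run_experiment


class SpectrumClassifier:
    """A 1D network classifier for labelled spectra on a common grid.

    Parameters
    ----------
    dataset : SpectralDataset
        Labelled spectra.  If replicate acquisitions are present they are
        averaged to one spectrum per sample before splitting.
    architecture : str
        One of ``alexnet1d``, ``resnet1d``, ``mscnn``, ``msresnet``.
    config : TrainConfig, optional
        Split/CV/optimizer settings; defaults follow the standard protocol
        (7:3 split, 5 folds, Adam 1e-4, batch 8, 200 epochs).
    preprocess : str
        Per-spectrum normalization applied before training: ``none``
        (default), ``minmax`` or ``vector``.
    """

    def __init__(self, dataset: SpectralDataset, architecture: str = "msresnet",
                 config: TrainConfig | None = None, preprocess: str = "none",
                 builder_kwargs: dict | None = None):
        if architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {architecture!r}; choose from {ARCHITECTURES}")
        if dataset.meta["sample_id"].duplicated().any():
            dataset = average_replicates(dataset)
        self.dataset = normalize(dataset, preprocess)
        self.architecture = architecture
        self.config = config or TrainConfig()
        self.builder_kwargs = builder_kwargs or {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid=None, **kwargs) -> "SpectrumClassifier":
        """Build from a wide DataFrame: metadata columns ``sample_id``,
        ``replicate_id``, ``class_label`` plus one numeric column per
        wavenumber."""
        from .spectra import WavenumberGrid

        meta_cols = ["sample_id", "replicate_id", "class_label"]
        wn_cols = [c for c in df.columns if c not in meta_cols]
        axis = np.array([float(c) for c in wn_cols])
        grid = grid or WavenumberGrid.from_axis(axis)
        ds = SpectralDataset(
            grid=grid,
            absorbance=df[wn_cols].to_numpy(dtype=float),
            meta=df[meta_cols].copy(),
            class_names=tuple(dict.fromkeys(df["class_label"])),
        )
        return cls(ds, **kwargs)

    def fit(self) -> "ClassificationResults":
        results = run_experiment(
            self.dataset, [self.architecture], self.config,
            builder_kwargs={self.architecture: self.builder_kwargs},
        )
        return ClassificationResults(self, results[self.architecture])


@dataclass
class ClassificationResults:
    """Fit artifacts: CV summaries, held-out confusion matrix, metrics."""

    model: SpectrumClassifier
    experiment: ExperimentResult

    def __post_init__(self) -> None:
        self.report: MetricsReport = full_report(
            self.experiment.test_confusion,
            self.experiment.test_probabilities,
            self.experiment.test_labels,
        )

    # -- convenience accessors -------------------------------------------
    @property
    def confusion(self):
        return self.experiment.test_confusion

    @property
    def class_names(self):
        return self.experiment.test_confusion.class_names

    def cv_table(self) -> pd.DataFrame:
        rows = [
            {
                "fold": f.fold_index,
                "val_accuracy": f.confusion.accuracy(),
                "final_loss": f.history["loss"][-1],
            }
            for f in self.experiment.folds
        ]
        return pd.DataFrame(rows)

    def predictions(self) -> pd.DataFrame:
        probs = self.experiment.test_probabilities
        df = pd.DataFrame(
            {
                "sample_id": self.experiment.test_ids,
                "true": self.experiment.test_labels,
                "predicted": self.experiment.test_predictions,
            }
        )
        for i, c in enumerate(self.class_names):
            df[f"p_{c}"] = probs[:, i]
        return df

    def predict(self, dataset: SpectralDataset) -> pd.DataFrame:
        """Class probabilities and labels for new spectra on the same grid."""
        ds = normalize(dataset, "none")
        probs = self.experiment.final_model.predict_proba(ds.absorbance.astype(np.float32))
        names = list(self.class_names)
        out = pd.DataFrame({"sample_id": ds.meta["sample_id"]})
        out["predicted"] = [names[i] for i in probs.argmax(axis=1)]
        for i, c in enumerate(names):
            out[f"p_{c}"] = probs[:, i]
        return out

    def summary(self) -> str:
        e = self.experiment
        r = self.report
        lines = []
        w = 58
        lines.append("Spectrum Classification Results".center(w))
        lines.append("=" * w)
        lines.append(f"{'Architecture:':<22}{e.model_name:>36}")
        lines.append(f"{'Trainable parameters:':<22}{e.graph.count_parameters():>36,}")
        cfg = self.model.config
        lines.append(f"{'Train/test split:':<22}{f'{cfg.split_ratio:.0%} / {1 - cfg.split_ratio:.0%}':>36}")
        lines.append(f"{'CV folds:':<22}{cfg.n_folds:>36}")
        lines.append(f"{'Epochs / batch / lr:':<22}{f'{cfg.epochs} / {cfg.batch_size} / {cfg.learning_rate:g}':>36}")
        lines.append(f"{'Seed:':<22}{cfg.seed:>36}")
        lines.append("-" * w)
        lines.append(
            f"{'CV val accuracy:':<22}"
            f"{f'{e.cv_val_accuracy_mean:.4f} +/- {e.cv_val_accuracy_sd:.4f}':>36}"
        )
        lines.append(f"{'Test accuracy:':<22}{r.accuracy:>36.4f}")
        lines.append(f"{'Sensitivity (macro):':<22}{r.sensitivity:>36.4f}")
        lines.append(f"{'Precision (macro):':<22}{r.precision:>36.4f}")
        lines.append(f"{'Specificity (macro):':<22}{r.specificity:>36.4f}")
        if r.auc is not None:
            lines.append(f"{'AUC (macro OvR):':<22}{r.auc:>36.4f}")
        lines.append("-" * w)
        lines.append("Per-class accuracy (recall):")
        for c, v in zip(self.class_names, r.per_class_accuracy):
            a = f"  {c:<8}{v:.4f}"
            if c in r.per_class_auc:
                a += f"   (AUC {r.per_class_auc[c]:.4f})"
            lines.append(a)
        lines.append("=" * w)
        return "\n".join(lines)


def benchmark(dataset: SpectralDataset, architectures=ARCHITECTURES,
              config: TrainConfig | None = None) -> "BenchmarkResults":
    """Run several architectures on the identical split; side-by-side table."""
    if dataset.meta["sample_id"].duplicated().any():
        dataset = average_replicates(dataset)
    config = config or TrainConfig()
    results = run_experiment(dataset, list(architectures), config)
    return BenchmarkResults(results)


@dataclass
class BenchmarkResults:
    experiments: dict

    def table(self) -> pd.DataFrame:
        """One row per architecture: per-class accuracy, average accuracy and
        the scalar metrics; columns ordered like a published comparison table."""
        rows = []
        for name, e in self.experiments.items():
            rep = full_report(e.test_confusion, e.test_probabilities, e.test_labels)
            row = {"model": name}
            for c, v in zip(e.test_confusion.class_names, rep.per_class_accuracy):
                row[c] = v
            row["average_accuracy"] = rep.sensitivity
            row.update(rep.scalars())
            rows.append(row)
        return pd.DataFrame(rows)

    def best(self, column: str = "average_accuracy") -> str:
        t = self.table().set_index("model")
        return str(t[column].idxmax())
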