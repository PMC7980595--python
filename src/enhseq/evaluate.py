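"""Cross-validated evaluation: accuracy/AUC/ROC, single-cell-type and
pairwise cell-type discrimination tasks.

The single-type task distinguishes one cell type's enhancer segments from
GC-matched negative sequences, featurized with that cell type's fold-change
dictionaries.  The pairwise task distinguishes enhancers of two cell types:
each direction assigns one type as the positive class and featurizes ALL
sequences with the positive type's dictionaries, and the reported metrics
average the two directions (label swapping makes the protocol symmetric in
the two types).

Classes are balanced by seeded down-sampling of the larger side; metrics are
per-fold and averaged over folds, with ROC points pooled over test folds.

Dictionary scope.  By default (``dictionary_scope="all"``) the fold-change
dictionaries are the ones built from ALL positive segments, the standard
protocol for this representation.  Because a held-out positive's own long
k-mers (9/11-mers are near-unique) are then stored in the dictionary with
elevated fold changes, cross-validated metrics include a dictionary-
membership component on top of genuine motif signal.  The strict mode
(``dictionary_scope="train"``) rebuilds dictionaries per fold from the
training positives only, removing that leak; use it for null calibrations
and whenever an unbiased generalization estimate is needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .features import FeatureArray, KSet, featurize_all
from .genome_io import EnhancerSegment
from .kmers import KmerDictionary, build_dictionaries
from .models import (FoldSplit, LabeledDataset, ModelConfig, make_folds,
                     train_model)

logger = logging.getLogger(__name__)


def accuracy(scores: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> float:
    """Fraction of correct calls; a score exactly at the threshold counts as a
    positive prediction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(scores) == 0:
        raise ValueError("need at least one sample")
    return float(np.mean((scores >= threshold).astype(int) == labels))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) AUC; ties contribute one half."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: Sequence[float],
               labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve as (fpr, tpr) arrays, starting at (0,0), ending at (1,1)."""
    fpr, tpr, _ = roc_curve(np.asarray(labels, dtype=int),
                            np.asarray(scores, dtype=float))
    return fpr, tpr


@dataclass
class CvReport:
    """Per-fold and averaged metrics for one classifier on one task."""

    task: str
    per_fold: list[tuple[float, float]]  # (accuracy, auc)
    roc: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.zeros(0), np.zeros(0)))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([a for a, _ in self.per_fold]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([u for _, u in self.per_fold]))

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "per_fold": [{"accuracy": a, "auc": u} for a, u in self.per_fold],
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
        }

    def save(self, path: str | Path, roc_path: str | Path | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        if roc_path is not None:
            fpr, tpr = self.roc
            with open(roc_path, "w") as fh:
                fh.write("fpr\ttpr\n")
                for x, y in zip(fpr, tpr):
                    fh.write(f"{x!r}\t{y!r}\n")


@dataclass
class PairwiseResult:
    """Two-direction cell-type discrimination with averaged metrics."""

    cell_a: str
    cell_b: str
    per_direction: list[CvReport]

    @property
    def averaged_accuracy(self) -> float:
        return float(np.mean([r.mean_accuracy for r in self.per_direction]))

    @property
    def averaged_auc(self) -> float:
        return float(np.mean([r.mean_auc for r in self.per_direction]))

    def to_dict(self) -> dict:
        return {
            "cell_a": self.cell_a,
            "cell_b": self.cell_b,
            "per_direction": [r.to_dict() for r in self.per_direction],
            "averaged_accuracy": self.averaged_accuracy,
            "averaged_auc": self.averaged_auc,
        }


def _downsample(items: Sequence, n: int, rng: np.random.Generator) -> list:
    if len(items) <= n:
        return list(items)
    idx = rng.choice(len(items), size=n, replace=False)
    return [items[i] for i in np.sort(idx)]


def equalize(a: Sequence, b: Sequence,
             rng: np.random.Generator) -> tuple[list, list]:
    """Balance two sets by down-sampling the larger (seeded)."""
    n = min(len(a), len(b))
    return _downsample(a, n, rng), _downsample(b, n, rng)


def _cross_validate(dataset: LabeledDataset, config: ModelConfig, task: str,
                    n_folds: int, seed: int) -> CvReport:
    split: FoldSplit = make_folds(dataset, n_folds=n_folds, seed=seed)
    return _run_folds(lambda f: dataset, split, config, task, seed)


def _run_folds(dataset_for_fold, split: FoldSplit, config: ModelConfig,
               task: str, seed: int) -> CvReport:
    """Train/score every fold; ``dataset_for_fold(f)`` supplies the (possibly
    fold-specific) featurized dataset, indexed consistently with the split."""
    per_fold: list[tuple[float, float]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for f, fold in enumerate(split.folds):
        dataset = dataset_for_fold(f)
        model = train_model(config.with_seed(seed + 1000 * (f + 1)),
                            dataset.subset(fold["train"]),
                            dataset.subset(fold["val"]))
        test = dataset.subset(fold["test"])
        scores = model.predict(test.X)
        per_fold.append((accuracy(scores, test.y), auc(scores, test.y)))
        pooled_scores.append(scores)
        pooled_labels.append(test.y)
        logger.info("%s fold %d: accuracy=%.3f auc=%.3f",
                    task, f, *per_fold[-1])
    roc = roc_points(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return CvReport(task=task, per_fold=per_fold, roc=roc)


def _strict_cv(pos: list[EnhancerSegment], neg: list[EnhancerSegment],
               controls: Sequence[EnhancerSegment], config: ModelConfig,
               task: str, n_folds: int, seed: int, ks: KSet, alpha: float,
               cell_type: str) -> CvReport:
    """Cross-validation with per-fold dictionaries from training positives
    only (vs the full control set, which never enters the test data)."""
    labels = np.concatenate([np.ones(len(pos), dtype=int),
                             np.zeros(len(neg), dtype=int)])
    index_only = LabeledDataset(np.zeros((len(labels), 1, 1)), labels)
    split = make_folds(index_only, n_folds=n_folds, seed=seed)
    ctrl_cores = [c.core for c in controls]

    def dataset_for_fold(f: int) -> LabeledDataset:
        train_idx = set(split.folds[f]["train"].tolist())
        train_pos = [pos[i].core for i in range(len(pos)) if i in train_idx]
        dicts_f = build_dictionaries(train_pos, ctrl_cores, ks=ks.ks,
                                     alpha=alpha)
        fpos = featurize_all(pos, dicts_f, ks, cell_type)
        fneg = featurize_all(neg, dicts_f, ks, cell_type)
        return LabeledDataset.from_feature_arrays(fpos, fneg)

    return _run_folds(dataset_for_fold, split, config, task, seed)


def run_single_type(
    positives: Sequence[EnhancerSegment],
    negatives: Sequence[EnhancerSegment],
    dicts: Mapping[int, KmerDictionary],
    config: ModelConfig,
    n_folds: int = 5,
    seed: int = 0,
    ks: KSet = KSet(),
    cell_type: str = "",
    dictionary_scope: str = "all",
    controls: Sequence[EnhancerSegment] | None = None,
    alpha: float = 1.0,
) -> CvReport:
    """Enhancers-vs-background cross-validated evaluation for one cell type.

    Classes are equalized by seeded down-sampling; all sequences are
    featurized with the positive cell type's dictionaries.  With
    ``dictionary_scope="train"`` the supplied ``dicts`` are ignored and
    per-fold dictionaries are rebuilt from training positives versus
    ``controls`` (see module docstring).
    """
    rng = np.random.default_rng(seed)
    pos, neg = equalize(positives, negatives, rng)
    task = f"single:{cell_type or 'positives'}:{config.arch}"
    if dictionary_scope == "train":
        if controls is None:
            raise ValueError("strict dictionary scope requires controls")
        return _strict_cv(pos, neg, controls, config, task, n_folds, seed,
                          ks, alpha, cell_type)
    if dictionary_scope != "all":
        raise ValueError("dictionary_scope must be 'all' or 'train'")
    fpos = featurize_all(pos, dicts, ks, cell_type)
    fneg = featurize_all(neg, dicts, ks, cell_type)
    dataset = LabeledDataset.from_feature_arrays(fpos, fneg)
    return _cross_validate(dataset, config, task, n_folds, seed)


def run_pairwise(
    enhancers_a: Sequence[EnhancerSegment],
    enhancers_b: Sequence[EnhancerSegment],
    dicts_a: Mapping[int, KmerDictionary],
    dicts_b: Mapping[int, KmerDictionary],
    config: ModelConfig,
    n_folds: int = 5,
    seed: int = 0,
    ks: KSet = KSet(),
    cell_a: str = "A",
    cell_b: str = "B",
    dictionary_scope: str = "all",
    controls_a: Sequence[EnhancerSegment] | None = None,
    controls_b: Sequence[EnhancerSegment] | None = None,
    alpha: float = 1.0,
    feature_channels: str = "positive",
) -> PairwiseResult:
    """Discriminate enhancers of two cell types, swapping positive/negative
    assignments and averaging the two directions.

    In each direction every sequence (both types) is featurized with the
    positive type's dictionaries (``feature_channels="positive"``, the
    default); with ``feature_channels="both"`` every sequence instead carries
    both types' dictionaries side by side (2 |K| channels), identical in the
    two directions up to the label swap.  With ``dictionary_scope="train"``
    each direction rebuilds the positive type's dictionaries per fold from
    its training positives versus that type's controls.
    """
    rng = np.random.default_rng(seed)
    segs_a, segs_b = equalize(enhancers_a, enhancers_b, rng)
    if dictionary_scope not in ("all", "train"):
        raise ValueError("dictionary_scope must be 'all' or 'train'")
    if dictionary_scope == "train" and (controls_a is None or controls_b is None):
        raise ValueError("strict dictionary scope requires controls for both types")
    if feature_channels not in ("positive", "both"):
        raise ValueError("feature_channels must be 'positive' or 'both'")
    if feature_channels == "both" and dictionary_scope == "train":
        raise ValueError(
            "both-dictionaries features are not available in strict scope")

    def _features(segs, name):
        if feature_channels == "positive":
            return None  # handled per direction below
        fa = featurize_all(segs, dicts_a, ks, name)
        fb = featurize_all(segs, dicts_b, ks, name)
        return [FeatureArray(np.concatenate([x.values, y.values], axis=1),
                             segment_id=x.segment_id, cell_type=name)
                for x, y in zip(fa, fb)]

    both_a = _features(segs_a, cell_a)
    both_b = _features(segs_b, cell_b)

    reports = []
    for pos_name, pos_segs, neg_segs, dicts, controls, fpos, fneg in (
        (cell_a, segs_a, segs_b, dicts_a, controls_a, both_a, both_b),
        (cell_b, segs_b, segs_a, dicts_b, controls_b, both_b, both_a),
    ):
        task = f"pairwise:{cell_a}-{cell_b}:pos={pos_name}:{config.arch}"
        if dictionary_scope == "train":
            reports.append(_strict_cv(pos_segs, neg_segs, controls, config,
                                      task, n_folds, seed, ks, alpha, pos_name))
            continue
        if feature_channels == "positive":
            fpos = featurize_all(pos_segs, dicts, ks, pos_name)
            fneg = featurize_all(neg_segs, dicts, ks, pos_name)
        dataset = LabeledDataset.from_feature_arrays(fpos, fneg)
        reports.append(_cross_validate(dataset, config, task, n_folds, seed))
    return PairwiseResult(cell_a=cell_a, cell_b=cell_b, per_direction=reports)


def subsample_repeat(
    positives: Sequence[EnhancerSegment],
    negatives: Sequence[EnhancerSegment],
    dicts: Mapping[int, KmerDictionary],
    config: ModelConfig,
    n_per_class: int = 2000,
    repeats: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    ks: KSet = KSet(),
    cell_type: str = "",
) -> tuple[list[CvReport], dict]:
    """Repeated evaluation on random subsamples of ``n_per_class`` sequences
    per class (the protocol used to bound per-model training time); returns
    the per-repeat reports and a mean +/- sd summary."""
    if len(positives) < n_per_class or len(negatives) < n_per_class:
        logger.warning("fewer than %d sequences per class available; using all",
                       n_per_class)
    master = np.random.default_rng(seed)
    reports = []
    for r in range(repeats):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        pos = _downsample(positives, n_per_class, rng)
        neg = _downsample(negatives, n_per_class, rng)
        reports.append(run_single_type(
            pos, neg, dicts, config, n_folds=n_folds, seed=sub_seed, ks=ks,
            cell_type=f"{cell_type}#rep{r}"))
    accs = [r.mean_accuracy for r in reports]
    aucs = [r.mean_auc for r in reports]
    summary = {
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs, ddof=1)) if repeats > 1 else 0.0,
        "repeats": repeats,
        "n_per_class": n_per_class,
    }
    return reports, summary


def plot_roc(reports: Sequence[CvReport], path: str | Path) -> None:
    """Write a ROC overlay plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for report in reports:
        fpr, tpr = report.roc
        ax.plot(fpr, tpr, label=f"{report.task} (AUC={report.mean_auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
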