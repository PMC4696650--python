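"""Merge studies on signature genes, adjust batch effects, classify samples.

Batch adjustment is an exact per-batch location-scale standardization: for
each gene, each study's values are centered and scaled within-batch and the
gene is then rescaled to its pooled pre-adjustment mean and standard
deviation.  This is the closed-form limit of ComBat with the empirical-Bayes
shrinkage turned off, and is deterministic.  To avoid leakage the adjuster
can be fit on training samples and applied frozen to held-out samples.

Classification uses a C-classification support vector machine with a radial
basis kernel; cost and kernel width are tuned by stratified k-fold
cross-validation on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .consensus import SignatureTable
from .errors import BatchSizeError, MergeError, SplitError
from .io import CASE, ExpressionDataset

_SD_FLOOR = 1e-8


@dataclass
class MergedMatrix:
    """Pooled samples x signature genes with batch (study) and class labels.

    A freshly merged matrix requires >= 2 samples per batch (needed to fit
    batch adjustment); train/test subsets produced by splitting relax this,
    since frozen adjustment parameters apply to any batch size.
    """

    values: pd.DataFrame  # genes x samples
    batch: pd.Series  # per-sample dataset_id
    sample_class: pd.Series  # per-sample case/control
    check_batches: bool = True

    def __post_init__(self):
        if self.values.isna().any().any():
            raise MergeError("merged matrix contains missing values")
        counts = self.batch.value_counts()
        if self.check_batches and (counts < 2).any():
            small = list(counts.index[counts < 2])
            raise BatchSizeError(f"batches with < 2 samples: {small}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset(self, samples: list[str]) -> "MergedMatrix":
        return MergedMatrix(
            values=self.values[samples],
            batch=self.batch.loc[samples],
            sample_class=self.sample_class.loc[samples],
            check_batches=False,
        )


def merge_on_signature(
    datasets: list[ExpressionDataset],
    sig: SignatureTable,
    gene_tables=None,
) -> MergedMatrix:
    """Pool samples from all studies over signature genes shared by every study.

    ``gene_tables`` (per-study gene-level DE tables, same order as
    ``datasets``) supplies the probe chosen for each gene during collapse;
    without it, probe IDs are assumed to be gene symbols already.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 datasets to merge")
    if len(sig) == 0:
        raise ValueError("signature is empty")
    sig_genes = sig.genes

    per_study: list[pd.DataFrame] = []
    for i, ds in enumerate(datasets):
        if gene_tables is not None:
            tab = gene_tables[i].table
            probe_of = dict(zip(tab.index, tab["probe_id"]))
            genes = [g for g in sig_genes if g in probe_of]
            block = ds.values.loc[[probe_of[g] for g in genes]]
            block.index = genes
        else:
            genes = [g for g in sig_genes if g in ds.values.index]
            block = ds.values.loc[genes]
        block = block.dropna(axis=0)  # merged matrix must be complete
        block.columns = [f"{ds.dataset_id}:{c}" for c in block.columns]
        per_study.append(block)

    shared = [
        g for g in sig_genes if all(g in block.index for block in per_study)
    ]
    if not shared:
        raise MergeError("no signature gene is measured in every dataset")
    values = pd.concat([block.loc[shared] for block in per_study], axis=1)
    batch = pd.Series(
        np.concatenate(
            [[ds.dataset_id] * block.shape[1] for ds, block in zip(datasets, per_study)]
        ),
        index=values.columns,
    )
    sample_class = pd.Series(
        np.concatenate([ds.sample_class.to_numpy() for ds in datasets]),
        index=values.columns,
    )
    return MergedMatrix(values=values, batch=batch, sample_class=sample_class)


class BatchAdjuster:
    """Location-scale batch standardization with frozen-parameter transform."""

    def __init__(self):
        self.batch_mean_: dict[str, pd.Series] = {}
        self.batch_sd_: dict[str, pd.Series] = {}
        self.target_mean_: pd.Series | None = None
        self.target_sd_: pd.Series | None = None
        self.z_sd_: pd.Series | None = None

    def fit(self, merged: MergedMatrix) -> "BatchAdjuster":
        counts = merged.batch.value_counts()
        if (counts < 2).any():
            raise BatchSizeError("every batch needs >= 2 samples to fit")
        values = merged.values
        self.target_mean_ = values.mean(axis=1)
        self.target_sd_ = values.std(axis=1, ddof=1)
        for b in counts.index:
            cols = merged.batch.index[merged.batch == b]
            block = values[cols]
            self.batch_mean_[b] = block.mean(axis=1)
            self.batch_sd_[b] = block.std(axis=1, ddof=1)
        # Pooled sd of the within-batch standardized fit data: the frozen
        # factor that restores the gene's pooled pre-adjustment sd.
        z = self._standardize(merged)
        z_sd = z.std(axis=1, ddof=1)
        self.z_sd_ = z_sd.where(z_sd >= _SD_FLOOR, 1.0)
        return self

    def _standardize(self, merged: MergedMatrix) -> pd.DataFrame:
        out = merged.values.copy()
        for b in merged.batch.unique():
            if b not in self.batch_mean_:
                raise KeyError(f"batch {b!r} unseen during fit")
            cols = merged.batch.index[merged.batch == b]
            centered = out[cols].sub(self.batch_mean_[b], axis=0)
            sd = self.batch_sd_[b].where(self.batch_sd_[b] >= _SD_FLOOR, 1.0)
            out[cols] = centered.div(sd, axis=0)
        return out

    def transform(self, merged: MergedMatrix) -> MergedMatrix:
        """Apply the frozen adjustment; no statistics are re-estimated."""
        if self.target_mean_ is None:
            raise RuntimeError("adjuster is not fitted")
        z = self._standardize(merged).div(self.z_sd_, axis=0)
        out = z.mul(self.target_sd_, axis=0).add(self.target_mean_, axis=0)
        return MergedMatrix(
            values=out,
            batch=merged.batch,
            sample_class=merged.sample_class,
            check_batches=False,
        )


def batch_adjust(merged: MergedMatrix) -> MergedMatrix:
    """Fit-and-transform convenience for a single pooled matrix."""
    if merged.batch.nunique() == 1:
        return merged  # single batch: nothing to adjust
    return BatchAdjuster().fit(merged).transform(merged)


def stratified_split(
    merged: MergedMatrix, test_fraction: float, seed: int
) -> tuple[MergedMatrix, MergedMatrix]:
    """Class-stratified random train/test split, deterministic given seed.

    Per class the test size is round(class size x fraction), at least 1;
    every class must keep >= 2 training samples.
    """
    if not 0 < test_fraction < 0.5:
        raise ValueError("test_fraction must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    test_samples: list[str] = []
    for cls in sorted(merged.sample_class.unique()):
        members = list(merged.sample_class.index[merged.sample_class == cls])
        n_test = max(1, round(len(members) * test_fraction))
        if len(members) - n_test < 2:
            raise SplitError(
                f"class {cls!r} has {len(members)} samples; cannot reserve "
                f"{n_test} for testing and keep >= 2 for training"
            )
        test_samples.extend(rng.choice(members, size=n_test, replace=False))
    test_set = set(test_samples)
    train_samples = [s for s in merged.values.columns if s not in test_set]
    test_samples = [s for s in merged.values.columns if s in test_set]
    return merged.subset(train_samples), merged.subset(test_samples)


DEFAULT_COSTS = (0.1, 1.0, 10.0, 100.0)


def default_gammas(n_genes: int) -> tuple[float, ...]:
    """Kernel-width grid scaled to the feature count."""
    return (1.0 / (2.0 * n_genes), 1.0 / n_genes, 2.0 / n_genes)


@dataclass
class ClassifierReport:
    """Cross-validated and held-out performance of the tuned RBF-SVM."""

    cv_accuracies: list[float]
    mean_cv_accuracy: float
    test_accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    best_cost: float
    best_gamma: float
    n_test_case: int
    n_test_control: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "cv_accuracies": [round(a, 6) for a in self.cv_accuracies],
            "mean_cv_accuracy": round(self.mean_cv_accuracy, 6),
            "test_accuracy": round(self.test_accuracy, 6),
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "best_cost": self.best_cost,
            "best_gamma": self.best_gamma,
            "n_test_case": self.n_test_case,
            "n_test_control": self.n_test_control,
            "seed": self.seed,
        }


def tune_train_evaluate(
    train: MergedMatrix,
    test: MergedMatrix,
    folds: int = 10,
    costs: tuple[float, ...] = DEFAULT_COSTS,
    gammas: tuple[float, ...] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Grid-tune an RBF SVM by stratified k-fold CV, refit, score held-out.

    Accuracy is the CV criterion; the best (cost, gamma) pair is refit on
    the full training set and evaluated on the test set with a confusion
    matrix (case = positive class).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X_train = train.values.T.to_numpy(dtype=float)
    y_train = (train.sample_class == CASE).to_numpy().astype(int)
    X_test = test.values.T.to_numpy(dtype=float)
    y_test = (test.sample_class == CASE).to_numpy().astype(int)
    if len(np.unique(y_train)) < 2:
        raise SplitError("training set must contain both classes")
    if gammas is None:
        gammas = default_gammas(train.n_genes)

    folds = min(folds, int(np.bincount(y_train).min()))
    if folds < 2:
        raise SplitError("a class is too small for 2-fold stratified CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X_train, y_train))

    best = None
    for cost in costs:
        for gamma in gammas:
            fold_acc = []
            for tr_idx, va_idx in splits:
                clf = SVC(C=cost, gamma=gamma, kernel="rbf")
                clf.fit(X_train[tr_idx], y_train[tr_idx])
                fold_acc.append(
                    float((clf.predict(X_train[va_idx]) == y_train[va_idx]).mean())
                )
            mean_acc = float(np.mean(fold_acc))
            if best is None or mean_acc > best[0]:
                best = (mean_acc, cost, gamma, fold_acc)

    mean_cv, best_cost, best_gamma, cv_accuracies = best
    clf = SVC(C=best_cost, gamma=best_gamma, kernel="rbf")
    clf.fit(X_train, y_train)
    pred = clf.predict(X_test)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    return ClassifierReport(
        cv_accuracies=cv_accuracies,
        mean_cv_accuracy=mean_cv,
        test_accuracy=float((pred == y_test).mean()),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        best_cost=best_cost,
        best_gamma=best_gamma,
        n_test_case=int(y_test.sum()),
        n_test_control=int((1 - y_test).sum()),
        seed=seed,
    )
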