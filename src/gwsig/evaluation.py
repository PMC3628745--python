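"""Classifier-based evaluation of gene signatures.

A signature is scored per study by leave-one-out (LOO) cross-validation
of a maximum-margin classifier: for each held-out sample, features are
standardized on the training fold, a linear-kernel SVM (C = 1.0 by
default — the standard choice for p >> n expression data) is trained on
the remaining samples, and the held-out sample is predicted. Accuracy is
the fraction of held-out samples classified correctly; the fold count
equals the sample count.

Wrapper feature selection evaluates top-k prefixes of the combined
ranking over a grid of k values and picks the smallest k whose average
accuracy is within a tolerance of the grid maximum (the accuracy
plateau), favouring parsimonious signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataio import CASE, CONTROL, SignatureList
from .errors import ConfigError, EvaluationError
from .preprocess import GeneMatrix
from .scoring import GWGSTable, log2_matrix, top_k


@dataclass
class ClassifierConfig:
    """SVM settings: kernel, regularization constant, per-fold standardization."""

    kernel: str = "linear"
    C: float = 1.0
    standardize: bool = True

    def build(self):
        svc = SVC(kernel=self.kernel, C=self.C)
        return make_pipeline(StandardScaler(), svc) if self.standardize else svc


@dataclass
class LOOResult:
    accuracy: float
    n_folds: int
    predictions: list[str]
    genes_used: tuple[str, ...]
    genes_missing: tuple[str, ...]


def loo_accuracy(
    gm: GeneMatrix,
    sig: SignatureList,
    config: ClassifierConfig | None = None,
) -> LOOResult:
    """Leave-one-out accuracy of a signature on one study.

    Signature genes the study's platform lacks are dropped (and
    reported); if none remain, the signature is not evaluable on that
    study and an :class:`EvaluationError` is raised.
    """
    config = config or ClassifierConfig()
    present = set(gm.gene_symbols)
    used = tuple(g for g in sig.genes if g in present)
    missing = tuple(g for g in sig.genes if g not in present)
    if not used:
        raise EvaluationError(
            f"no gene of signature {sig.name!r} is present in study {gm.study_id}"
        )
    sub = gm.subset(used)
    X = log2_matrix(sub.values, sub.scale_flag).T  # samples × genes
    # a platform-missing sample value would poison the SVM; impute per-gene mean
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    y = np.array([gm.labels[s] for s in gm.sample_ids])
    for cls in (CASE, CONTROL):
        if (y == cls).sum() < 2:
            raise EvaluationError(
                f"study {gm.study_id}: class {cls!r} has fewer than 2 samples"
            )
    preds = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        clf = config.build()
        clf.fit(X[train_idx], y[train_idx])
        preds.append(str(clf.predict(X[test_idx])[0]))
    correct = sum(p == t for p, t in zip(preds, y))
    return LOOResult(
        accuracy=correct / len(y),
        n_folds=len(y),
        predictions=preds,
        genes_used=used,
        genes_missing=missing,
    )


@dataclass
class SelectionCurve:
    """Accuracy as a function of signature size, with the plateau choice."""

    grid: list[int]
    accuracy: list[float]
    chosen_k: int
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.grid, "accuracy": self.accuracy})


def choose_plateau_k(grid: Sequence[int], accuracy: Sequence[float], tolerance: float) -> int:
    """Smallest k whose accuracy is within ``tolerance`` of the grid maximum."""
    if len(grid) == 0:
        raise ConfigError("empty k grid")
    if list(grid) != sorted(set(grid)):
        raise ConfigError("k grid must be strictly increasing")
    best = max(accuracy)
    for k, acc in zip(grid, accuracy):
        if acc >= best - tolerance:
            return int(k)
    raise AssertionError("unreachable: grid maximum is within tolerance of itself")


def wrapper_select(
    gwgs: GWGSTable,
    studies: Sequence[GeneMatrix],
    grid: Sequence[int],
    tolerance: float = 0.005,
    config: ClassifierConfig | None = None,
) -> SelectionCurve:
    """Evaluate top-k prefixes of the combined ranking over a k grid.

    For each k the top-k signature is scored by average LOO accuracy
    across studies; chosen_k is the smallest k on the accuracy plateau.
    """
    if len(grid) == 0:
        raise ConfigError("empty k grid")
    m = len(gwgs.s_r)
    bad = [k for k in grid if not 1 <= k <= m]
    if bad:
        raise ConfigError(f"grid values outside [1, {m}]: {bad}")
    accs = []
    for k in grid:
        sig = top_k(gwgs, int(k))
        per_study = [loo_accuracy(gm, sig, config).accuracy for gm in studies]
        accs.append(float(np.mean(per_study)))
    chosen = choose_plateau_k(list(grid), accs, tolerance)
    return SelectionCurve(grid=[int(k) for k in grid], accuracy=accs,
                          chosen_k=chosen, tolerance=tolerance)


def cross_study_report(
    signatures: Sequence[SignatureList],
    studies: Sequence[GeneMatrix],
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Per-signature × per-study LOO accuracies plus an unweighted average.

    A signature with no gene on a study's platform gets NaN in that cell;
    the average is taken over evaluable cells only.
    """
    if not studies:
        raise EvaluationError("need at least one study")
    rows = {}
    for sig in signatures:
        cells = {}
        for gm in studies:
            try:
                cells[gm.study_id] = loo_accuracy(gm, sig, config).accuracy
            except EvaluationError:
                cells[gm.study_id] = np.nan
        vals = [v for v in cells.values() if not np.isnan(v)]
        if not vals:
            raise EvaluationError(f"signature {sig.name!r} evaluable on no study")
        cells["average"] = float(np.mean(vals))
        rows[sig.name] = cells
    return pd.DataFrame.from_dict(rows, orient="index")
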