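"""Per-study differential-expression scores, genome-wide ranks, and the
rank-based meta-analysis statistics.

The central quantities:

* per-study score ``s_ij = -2 log(r_ij / m)`` converting a gene's
  differential-expression rank ``r_ij`` (1 = most differentially
  expressed) into a nonnegative evidence value bounded by
  ``-2 log(1/m)``, where ``m`` is the size of the cross-study gene
  universe;
* the combined score ``s_i^r = sum_j w_j s_ij`` over the n studies with
  nonnegative weights summing to one;
* the Fisher-combination baseline ``s_p = -2 sum_i log(p_i)``,
  chi-square distributed with 2n degrees of freedom under the null of
  uniform p-values.

Natural log is the default (matching the Fisher/chi-square convention);
gene ordering is log-base invariant, and base 10 is available via the
``log_base`` argument.

Ranks are assigned among genes *present* in a study (a gene a platform
does not carry is marked missing, never ranked), while the denominator
``m`` is the global universe size, so the best attainable per-study
score is identical across studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CASE, CONTROL, SignatureList
from .errors import ConfigError, DataError

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import GeneMatrix, GeneUniverse


# ---------------------------------------------------------------------------
# differential-expression measures


def log2_matrix(values: np.ndarray, scale_flag: str) -> np.ndarray:
    """Return ``values`` on the log2 scale, validating positivity for linear input."""
    values = np.asarray(values, dtype=float)
    if scale_flag == "log2":
        return values
    if scale_flag != "linear":
        raise DataError(f"unknown scale flag {scale_flag!r}")
    with np.errstate(invalid="ignore"):
        nonpos = values <= 0
    if np.any(nonpos & ~np.isnan(values)):
        raise DataError("linear-scale matrix contains non-positive values; cannot take log2")
    return np.log2(values)


def log2_fold_change_rows(
    values: np.ndarray,
    case_cols: Sequence[int],
    control_cols: Sequence[int],
    scale_flag: str,
    direction: str = "absolute",
) -> np.ndarray:
    """Row-wise log2 fold change between class means.

    Means are taken in log2 space (geometric means for linear input),
    ignoring missing entries. ``direction='absolute'`` puts under- and
    over-expression on one scale; ``'signed'`` keeps case minus control.
    """
    if direction not in ("absolute", "signed"):
        raise ConfigError(f"direction must be 'absolute' or 'signed', got {direction!r}")
    if len(case_cols) == 0 or len(control_cols) == 0:
        raise DataError("fold change needs at least one sample per class")
    logv = log2_matrix(values, scale_flag)
    case_mean = np.nanmean(logv[:, list(case_cols)], axis=1)
    ctrl_mean = np.nanmean(logv[:, list(control_cols)], axis=1)
    fc = case_mean - ctrl_mean
    return np.abs(fc) if direction == "absolute" else fc


@dataclass
class DEScoreTable:
    """Per-gene differential-expression scores for one study.

    ``higher_is_better`` encodes the rank direction: fold changes rank
    descending, p-values ascending.
    """

    study_id: str
    scores: pd.Series
    measure: str
    direction: str = "absolute"

    @property
    def higher_is_better(self) -> bool:
        return self.measure != "t_test_p"


def fold_change(gm: "GeneMatrix", direction: str = "absolute") -> DEScoreTable:
    """Log2 fold change per gene between case and control samples."""
    case_cols = gm.class_columns(CASE)
    ctrl_cols = gm.class_columns(CONTROL)
    fc = log2_fold_change_rows(gm.values, case_cols, ctrl_cols, gm.scale_flag, direction)
    return DEScoreTable(
        study_id=gm.study_id,
        scores=pd.Series(fc, index=gm.gene_symbols, name="log2fc"),
        measure="fold_change",
        direction=direction,
    )


def t_test_p(gm: "GeneMatrix") -> DEScoreTable:
    """Two-sided Welch t-test p-value per gene (smaller = more significant).

    Degenerate genes with zero variance in both classes and equal means
    get p = 1 by convention.
    """
    case_cols = gm.class_columns(CASE)
    ctrl_cols = gm.class_columns(CONTROL)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise DataError("t-test needs at least two samples per class")
    logv = log2_matrix(gm.values, gm.scale_flag)
    x, y = logv[:, case_cols], logv[:, ctrl_cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    equal_means = np.isclose(np.nanmean(x, axis=1), np.nanmean(y, axis=1))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0  # zero variance, distinct means: maximally significant
    return DEScoreTable(
        study_id=gm.study_id,
        scores=pd.Series(p, index=gm.gene_symbols, name="p_value"),
        measure="t_test_p",
    )


# ---------------------------------------------------------------------------
# ranking and the per-study / combined significance scores


def rank_genes(table: DEScoreTable, universe: "GeneUniverse") -> pd.Series:
    """Rank universe genes by differential expression within one study.

    Returns a Series over all universe genes: rank 1 for the most
    differentially expressed present gene, NaN for genes absent from the
    study. Tied scores receive the mean of the occupied positions, so a
    non-integer rank is possible. Present genes must all be scored.
    """
    present = [g for g in universe.genes if universe.is_present(g, table.study_id)]
    missing_scores = [g for g in present if g not in table.scores.index]
    if missing_scores:
        raise DataError(
            f"study {table.study_id}: no DE score for present genes {missing_scores[:5]}"
        )
    vals = table.scores.loc[present].to_numpy(dtype=float)
    keyed = -vals if table.higher_is_better else vals
    ranks = stats.rankdata(keyed, method="average")
    out = pd.Series(np.nan, index=pd.Index(universe.genes, name="gene"), name=table.study_id)
    out.loc[present] = ranks
    return out


def gwrs(r, m: int, *, log_base: float = math.e):
    """Per-study rank score ``s = -2 log(r / m)``.

    ``r`` may be a scalar or array of rank numbers in [1, m] (fractional
    ranks from ties allowed); missing (NaN) in gives missing out. ``m``
    is the universe size. Scores lie in ``[0, -2 log(1/m)]`` and strictly
    decrease in ``r``.
    """
    if m < 1:
        raise DataError(f"universe size m must be >= 1, got {m}")
    arr = np.asarray(r, dtype=float)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 1) | (arr[valid] > m)):
        raise DataError(f"rank out of domain [1, {m}]")
    out = np.full(arr.shape, np.nan)
    out[valid] = -2.0 * np.log(arr[valid] / m) / np.log(log_base)
    return float(out) if out.ndim == 0 else out


def gwrs_max(m: int, *, log_base: float = math.e) -> float:
    """Upper end of the per-study score range, attained at rank 1."""
    return -2.0 * math.log(1.0 / m, log_base)


def gwrs_matrix(ranks: pd.DataFrame, m: int, *, log_base: float = math.e) -> pd.DataFrame:
    """Apply the rank score element-wise to an m × n rank table."""
    return pd.DataFrame(
        gwrs(ranks.to_numpy(dtype=float), m, log_base=log_base),
        index=ranks.index,
        columns=ranks.columns,
    )


@dataclass
class WeightVector:
    """Nonnegative per-study weights summing to one."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ConfigError("study weights must be nonnegative")
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-12):
            raise ConfigError(f"study weights must sum to 1, got {self.weights.sum()!r}")

    def __len__(self) -> int:
        return len(self.weights)


def equal_weights(n: int) -> WeightVector:
    return WeightVector(np.full(n, 1.0 / n))


def gwgs(s_row, w: WeightVector, *, missing_policy: str = "renormalize") -> tuple[float, int]:
    """Combine one gene's per-study scores into its global score.

    Returns ``(s_r, n_contributing)``. Missing entries are handled per
    ``missing_policy``: ``'renormalize'`` (default) rescales the weights
    over the contributing studies; ``'zero'`` treats a missing score as 0
    while keeping the nominal weights.
    """
    if missing_policy not in ("renormalize", "zero"):
        raise ConfigError(f"missing_policy must be 'renormalize' or 'zero', got {missing_policy!r}")
    s = np.asarray(s_row, dtype=float)
    if s.shape != w.weights.shape:
        raise DataError(f"score row length {s.shape} does not match {len(w)} weights")
    mask = ~np.isnan(s)
    n_contrib = int(mask.sum())
    if n_contrib == 0:
        raise DataError("all per-study scores missing; gene should have been filtered")
    if missing_policy == "zero":
        return float(np.where(mask, s, 0.0) @ w.weights), n_contrib
    w_eff = w.weights[mask]
    total = w_eff.sum()
    if total <= 0:
        raise DataError("contributing studies carry zero total weight")
    return float(s[mask] @ (w_eff / total)), n_contrib


@dataclass
class GWGSTable:
    """Per-gene combined scores with provenance (weights, contributing-study counts)."""

    s_r: pd.Series
    n_contributing: pd.Series
    weights: WeightVector
    missing_policy: str = "renormalize"

    def sorted_genes(self) -> list[str]:
        """Genes in descending score order; ties break by contributing-study
        count (more first), then symbol order."""
        return sorted(
            self.s_r.index,
            key=lambda g: (-self.s_r[g], -int(self.n_contributing[g]), g),
        )


def gwgs_table(
    s_matrix: pd.DataFrame,
    w: WeightVector | None = None,
    *,
    missing_policy: str = "renormalize",
) -> GWGSTable:
    """Combine an m × n per-study score table into per-gene global scores."""
    if w is None:
        w = equal_weights(s_matrix.shape[1])
    if len(w) != s_matrix.shape[1]:
        raise ConfigError(f"{len(w)} weights for {s_matrix.shape[1]} studies")
    s_r = np.empty(len(s_matrix))
    n_contrib = np.empty(len(s_matrix), dtype=int)
    vals = s_matrix.to_numpy(dtype=float)
    for i in range(len(s_matrix)):
        s_r[i], n_contrib[i] = gwgs(vals[i], w, missing_policy=missing_policy)
    idx = pd.Index(s_matrix.index, name="gene")
    return GWGSTable(
        s_r=pd.Series(s_r, index=idx, name="s_r"),
        n_contributing=pd.Series(n_contrib, index=idx, name="n_contributing"),
        weights=w,
        missing_policy=missing_policy,
    )


def top_k(table: GWGSTable, k: int) -> SignatureList:
    """The k genes with largest combined score, in descending order.

    Boundary ties break by contributing-study count, then symbol order.
    """
    m = len(table.s_r)
    if not 1 <= k <= m:
        raise ConfigError(f"k must be in [1, {m}], got {k}")
    order = table.sorted_genes()
    return SignatureList(name=f"top{k}", genes=tuple(order[:k]))


# ---------------------------------------------------------------------------
# Fisher / p-value combination baseline


def rhodes_sp(p_row) -> float:
    """Fisher's combined statistic ``s_p = -2 sum_i log(p_i)``.

    Each p must lie in (0, 1]; values outside raise (no silent clipping).
    Under the null of independent uniform p-values, s_p follows a
    chi-square distribution with 2n degrees of freedom.
    """
    p = np.asarray(p_row, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value row")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def rhodes_sp_table(p_matrix: pd.DataFrame) -> pd.Series:
    """Row-wise Fisher combination over a gene × study p-value table."""
    return pd.Series(
        [rhodes_sp(row) for row in p_matrix.to_numpy(dtype=float)],
        index=p_matrix.index,
        name="s_p",
    )
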