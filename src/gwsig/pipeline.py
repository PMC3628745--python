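"""End-to-end orchestration: collapse → universe → rank → score → combine.

This is the programmatic spine shared by the CLI stages, the tests and
the reproduction script. Each function is pure given its inputs; the CLI
adds file I/O around them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset, ProbeAnnotation
from .errors import ConfigError
from .preprocess import GeneMatrix, GeneUniverse, build_universe, collapse_study
from .scoring import (
    DEScoreTable,
    GWGSTable,
    WeightVector,
    equal_weights,
    fold_change,
    gwgs_table,
    gwrs_matrix,
    rank_genes,
    t_test_p,
)


@dataclass
class ScoringOptions:
    """Knobs of the integration stage with the package defaults."""

    measure: str = "fold_change"  # or "t_test_p"
    direction: str = "absolute"  # or "signed"
    log_base: float = math.e
    delta: int = 2
    weights: Sequence[float] | str = "equal"
    missing_policy: str = "renormalize"

    def validate(self, n_studies: int) -> None:
        if self.measure not in ("fold_change", "t_test_p"):
            raise ConfigError(f"unknown DE measure {self.measure!r}")
        if self.direction not in ("absolute", "signed"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if self.log_base <= 1:
            raise ConfigError("log_base must be > 1")
        if not 0 <= self.delta < n_studies:
            raise ConfigError(f"delta must satisfy 0 <= delta < n={n_studies}")
        if self.missing_policy not in ("renormalize", "zero"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")

    def weight_vector(self, n_studies: int) -> WeightVector:
        if isinstance(self.weights, str):
            if self.weights != "equal":
                raise ConfigError(f"weights must be 'equal' or a list, got {self.weights!r}")
            return equal_weights(n_studies)
        if len(self.weights) != n_studies:
            raise ConfigError(f"{len(self.weights)} weights for {n_studies} studies")
        return WeightVector(np.asarray(self.weights, dtype=float))


@dataclass
class IntegrationResult:
    """Everything the integration stage produces, for inspection or export."""

    gene_matrices: list[GeneMatrix]
    universe: GeneUniverse
    de_tables: list[DEScoreTable]
    ranks: pd.DataFrame  # m × n rank numbers, NaN = absent
    gwrs: pd.DataFrame  # m × n per-study scores
    gwgs: GWGSTable


def collapse_all(
    datasets: Sequence[ExpressionDataset],
    annotations: dict[str, ProbeAnnotation],
    *,
    direction: str = "absolute",
) -> list[GeneMatrix]:
    return [collapse_study(ds, annotations[ds.study_id], direction=direction) for ds in datasets]


def integrate(
    gene_matrices: Sequence[GeneMatrix],
    options: ScoringOptions | None = None,
) -> IntegrationResult:
    """Run universe construction, per-study ranking and score combination."""
    options = options or ScoringOptions()
    options.validate(len(gene_matrices))
    universe = build_universe(list(gene_matrices), options.delta)
    de_tables = []
    for gm in gene_matrices:
        present = [g for g in universe.genes if universe.is_present(g, gm.study_id)]
        sub = gm.subset(present)
        table = (
            fold_change(sub, options.direction)
            if options.measure == "fold_change"
            else t_test_p(sub)
        )
        de_tables.append(table)
    ranks = pd.DataFrame(
        {t.study_id: rank_genes(t, universe) for t in de_tables},
        index=pd.Index(universe.genes, name="gene"),
    )
    s_matrix = gwrs_matrix(ranks, universe.m, log_base=options.log_base)
    w = options.weight_vector(len(gene_matrices))
    combined = gwgs_table(s_matrix, w, missing_policy=options.missing_policy)
    return IntegrationResult(
        gene_matrices=list(gene_matrices),
        universe=universe,
        de_tables=de_tables,
        ranks=ranks,
        gwrs=s_matrix,
        gwgs=combined,
    )


def integrate_datasets(
    datasets: Sequence[ExpressionDataset],
    annotations: dict[str, ProbeAnnotation],
    options: ScoringOptions | None = None,
) -> IntegrationResult:
    """Convenience wrapper: probe collapse followed by :func:`integrate`."""
    options = options or ScoringOptions()
    gms = collapse_all(datasets, annotations, direction=options.direction)
    return integrate(gms, options)


def gwgs_frame(result: IntegrationResult) -> pd.DataFrame:
    """Combined table for export: s_r, contributing-study count, per-study r and s."""
    out = pd.DataFrame(
        {"s_r": result.gwgs.s_r, "n_contributing": result.gwgs.n_contributing}
    )
    for study in result.ranks.columns:
        out[f"r_{study}"] = result.ranks[study]
        out[f"s_{study}"] = result.gwrs[study]
    return out.loc[result.gwgs.sorted_genes()]
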