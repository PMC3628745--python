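"""Probe-to-gene collapse and the cross-study missingness filter.

Each study's probe-level matrix is reduced to one row per gene: a probe
mapping to several genes donates its row to each of them, and a gene
measured by several probes keeps the row of its most differentially
expressed probe (the "max" collapse — chosen so the most competitive
evidence for a gene survives, rather than being averaged down). Collapse
is per-study, so the same gene may be represented by different probes on
different platforms.

The union of collapsed gene lists forms the candidate universe; a gene
absent from more than ``delta`` of the n studies is removed (``delta=2``
of five studies in the original application). Genes absent from an
individual retained study are marked missing and propagate a missing
marker through ranks and scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import CASE, CONTROL, ExpressionDataset, ProbeAnnotation
from .errors import ConfigError, DataError
from .scoring import log2_fold_change_rows


@dataclass
class GeneMatrix:
    """Gene-level expression matrix for one study after probe collapse."""

    study_id: str
    gene_symbols: list[str]
    sample_ids: list[str]
    labels: dict[str, str]
    values: np.ndarray
    scale_flag: str
    provenance: dict[str, str]  # gene -> winning probe id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise DataError(f"duplicate gene symbols in collapsed matrix for {self.study_id}")
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise DataError("collapsed matrix shape does not match gene/sample lists")
        missing_prov = [g for g in self.gene_symbols if g not in self.provenance]
        if missing_prov:
            raise DataError(f"genes without a provenance probe: {missing_prov[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def class_columns(self, cls: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sample_ids) if self.labels[s] == cls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_symbols, columns=self.sample_ids)

    def subset(self, genes: Sequence[str]) -> "GeneMatrix":
        """Restrict to the listed genes (order preserved, all must be present)."""
        index = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes not in study {self.study_id}: {missing[:5]}")
        rows = [index[g] for g in genes]
        return GeneMatrix(
            study_id=self.study_id,
            gene_symbols=list(genes),
            sample_ids=self.sample_ids,
            labels=self.labels,
            values=self.values[rows],
            scale_flag=self.scale_flag,
            provenance={g: self.provenance[g] for g in genes},
        )


@dataclass
class GeneUniverse:
    """The retained gene list G with a gene × study presence table.

    Every retained gene is absent from at most ``delta`` studies.
    """

    genes: list[str]
    presence: pd.DataFrame  # genes × studies, bool
    delta: int

    def __post_init__(self) -> None:
        if list(self.presence.index) != list(self.genes):
            raise DataError("presence table index does not match gene list")
        absent = (~self.presence).sum(axis=1)
        if (absent > self.delta).any():
            bad = list(absent.index[absent > self.delta])[:5]
            raise DataError(f"genes exceed the allowed absence count: {bad}")

    @property
    def m(self) -> int:
        return len(self.genes)

    @property
    def n(self) -> int:
        return self.presence.shape[1]

    @property
    def studies(self) -> list[str]:
        return list(self.presence.columns)

    def is_present(self, gene: str, study_id: str) -> bool:
        return bool(self.presence.at[gene, study_id])


def expand_multigene_probes(
    ds: ExpressionDataset, ann: ProbeAnnotation
) -> tuple[dict[str, list[str]], int]:
    """Expand probes into per-gene candidate lists.

    Returns ``(candidates, n_unannotated)`` where ``candidates`` maps each
    gene symbol to the probes measuring it (a k-gene probe appears under
    all k genes, sharing its expression row). Probes without an
    annotation entry are dropped and counted.
    """
    if len(ann) == 0:
        raise DataError("probe annotation is empty")
    candidates: dict[str, list[str]] = {}
    n_unannotated = 0
    for probe in ds.probe_ids:
        if probe not in ann:
            n_unannotated += 1
            continue
        for gene in ann.genes_for(probe):
            candidates.setdefault(gene, []).append(probe)
    return candidates, n_unannotated


def collapse_probes(
    ds: ExpressionDataset,
    candidates: Mapping[str, Sequence[str]],
    de_score: Mapping[str, float],
) -> GeneMatrix:
    """Keep, per gene, the candidate probe with the maximal DE score.

    Score ties break deterministically toward the lexicographically
    smallest probe id, so the result is invariant to candidate order.
    """
    probe_row = {p: i for i, p in enumerate(ds.probe_ids)}
    genes = sorted(candidates)
    rows, provenance = [], {}
    for gene in genes:
        probes = candidates[gene]
        missing = [p for p in probes if p not in de_score]
        if missing:
            raise DataError(f"no DE score for candidate probes {missing[:5]} of gene {gene}")
        winner = min(probes, key=lambda p: (-de_score[p], p))
        rows.append(probe_row[winner])
        provenance[gene] = winner
    return GeneMatrix(
        study_id=ds.study_id,
        gene_symbols=genes,
        sample_ids=list(ds.sample_ids),
        labels=dict(ds.labels),
        values=ds.values[rows],
        scale_flag=ds.scale_flag,
        provenance=provenance,
    )


def probe_de_scores(ds: ExpressionDataset, direction: str = "absolute") -> dict[str, float]:
    """Probe-level log2 fold-change scores used to pick the winning probe."""
    scores = log2_fold_change_rows(
        ds.values, ds.class_columns(CASE), ds.class_columns(CONTROL), ds.scale_flag, direction
    )
    return dict(zip(ds.probe_ids, scores.tolist()))


def collapse_study(
    ds: ExpressionDataset, ann: ProbeAnnotation, *, direction: str = "absolute"
) -> GeneMatrix:
    """Full per-study collapse: expand multi-gene probes, score at probe
    level, keep the max-scoring probe per gene."""
    candidates, _ = expand_multigene_probes(ds, ann)
    if not candidates:
        raise DataError(f"no annotated probes in study {ds.study_id}")
    return collapse_probes(ds, candidates, probe_de_scores(ds, direction))


def build_universe(gene_matrices: Sequence[GeneMatrix], delta: int) -> GeneUniverse:
    """Union the per-study gene lists and apply the absence filter.

    A gene absent from strictly more than ``delta`` studies is removed;
    absence in exactly ``delta`` studies is allowed. Requires
    ``0 <= delta < n``.
    """
    if not gene_matrices:
        raise DataError("need at least one collapsed study")
    n = len(gene_matrices)
    if not 0 <= delta < n:
        raise ConfigError(f"delta must satisfy 0 <= delta < n={n}, got {delta}")
    study_ids = [gm.study_id for gm in gene_matrices]
    if len(set(study_ids)) != n:
        raise DataError(f"duplicate study ids: {study_ids}")
    union = sorted(set().union(*(gm.gene_symbols for gm in gene_matrices)))
    presence = pd.DataFrame(
        {gm.study_id: [g in set(gm.gene_symbols) for g in union] for gm in gene_matrices},
        index=pd.Index(union, name="gene"),
    )
    absent = (~presence).sum(axis=1)
    kept = [g for g in union if absent[g] <= delta]
    return GeneUniverse(genes=kept, presence=presence.loc[kept], delta=delta)


def write_gene_matrix(gm: GeneMatrix, path: str | Path) -> None:
    gm.to_frame().to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def write_provenance(gm: GeneMatrix, de_score: Mapping[str, float], path: str | Path) -> None:
    rows = [
        (g, gm.provenance[g], de_score.get(gm.provenance[g], float("nan")))
        for g in gm.gene_symbols
    ]
    pd.DataFrame(rows, columns=["gene", "probe_id", "de_score"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    out = universe.presence.astype(int)
    out.to_csv(path, sep="\t")
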