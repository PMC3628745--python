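"""Meta-analysis of published signature gene lists.

Given a collection of gene signatures from independent studies, compute
their pairwise overlap matrix, count in how many signatures each gene
occurs (occurrence histogram), and partition a query signature into
literature buckets: genes reported by at least one reference microarray
signature, genes absent from all references but present in a supplied
wet-lab-validated list, and genes in neither (candidate novel genes).

Symbols are expected to be pre-normalized (see
:func:`gwsig.dataio.normalize_symbol`); comparison is exact string
match, so dialect differences between sources are the caller's
responsibility to reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import SignatureList
from .errors import DataError


@dataclass
class OverlapMatrix:
    """Upper-triangular pairwise intersection counts between signatures."""

    names: list[str]
    sizes: dict[str, int]
    counts: pd.DataFrame  # upper triangle filled; diagonal and lower NaN

    def count(self, a: str, b: str) -> int:
        i, j = self.names.index(a), self.names.index(b)
        if i == j:
            raise DataError("overlap of a signature with itself is undefined")
        if i > j:
            i, j = j, i
        return int(self.counts.iat[i, j])


def overlap_matrix(sigs: Sequence[SignatureList]) -> OverlapMatrix:
    """Pairwise intersection sizes |genes_i ∩ genes_j| for i < j."""
    if len(sigs) < 2:
        raise DataError("need at least two signatures to compare")
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise DataError(f"duplicate signature names: {names}")
    counts = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(sigs):
        for j in range(i + 1, len(sigs)):
            counts.iat[i, j] = len(a.gene_set & sigs[j].gene_set)
    return OverlapMatrix(names=names, sizes={s.name: len(s) for s in sigs}, counts=counts)


@dataclass
class OccurrenceTable:
    """Per-gene signature-occurrence counts with a cumulative histogram."""

    counts: pd.Series  # gene -> number of reference signatures containing it
    cumulative: dict[int, int]  # threshold t -> number of genes with count >= t


def occurrence_counts(
    query: SignatureList | Sequence[str],
    refs: Sequence[SignatureList],
    *,
    max_threshold: int = 5,
) -> OccurrenceTable:
    """Count, for each query gene, the reference signatures containing it.

    The cumulative histogram reports how many query genes occur in at
    least t references for t = 1..max_threshold.
    """
    if not refs:
        raise DataError("need at least one reference signature")
    genes = list(query.genes) if isinstance(query, SignatureList) else list(query)
    ref_sets = [r.gene_set for r in refs]
    counts = pd.Series(
        {g: sum(g in rs for rs in ref_sets) for g in genes}, name="n_signatures"
    ).reindex(genes)
    cumulative = {t: int((counts >= t).sum()) for t in range(1, max_threshold + 1)}
    return OccurrenceTable(counts=counts, cumulative=cumulative)


def bucket_membership(
    query: SignatureList,
    refs: Sequence[SignatureList],
    validated: SignatureList,
) -> dict[str, frozenset[str]]:
    """Partition query genes into literature buckets.

    Returns disjoint sets under keys ``in_reference`` (reported by ≥1
    reference signature), ``validated_only`` (in no reference but in the
    wet-lab-validated list; reference membership takes precedence) and
    ``novel`` (in neither). The three sets partition the query exactly.
    """
    ref_union: frozenset[str] = frozenset().union(*(r.gene_set for r in refs)) if refs else frozenset()
    in_ref = query.gene_set & ref_union
    validated_only = (query.gene_set - ref_union) & validated.gene_set
    novel = query.gene_set - ref_union - validated.gene_set
    return {
        "in_reference": frozenset(in_ref),
        "validated_only": frozenset(validated_only),
        "novel": frozenset(novel),
    }


def overlap_to_frame(om: OverlapMatrix) -> pd.DataFrame:
    """Render the overlap matrix with 'name (size)' headers for export."""
    labels = [f"{n} ({om.sizes[n]})" for n in om.names]
    out = om.counts.copy()
    out.index = labels
    out.columns = labels
    return out
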