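"""Input/output for the tabular formats the framework touches.

Expression matrices are delimited text in a series-matrix-like layout:
a header row of sample identifiers and a first column of probe-set
identifiers. Probe annotations are two-column TSV mapping a probe-set id
to a gene field which may name several genes (``"ABCB1 / ABCB4"``).
Signature lists are one-symbol-per-line text files.

Gene symbols are compared verbatim as printed by their source studies:
normalization is uppercase + trim + delimiter split only, with no alias
or HGNC resolution, so overlap counts stay reproducible from printed
lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, LabelError

CASE = "case"
CONTROL = "control"

#: tokens accepted as a missing value in input matrices
MISSING_TOKENS = ("", "NA", "na", "NaN", "nan")

#: delimiters that join multiple gene symbols in one annotation field
_MULTI_GENE_SPLIT = re.compile(r"\s*///\s*|\s+/\s+")


@dataclass
class ExpressionDataset:
    """Probe-level expression matrix with two-class sample labels for one study.

    ``values`` is a probe × sample real matrix; ``scale_flag`` declares
    whether it is on a linear or log2 scale (fold-change computation
    branches on this; the scale is declared, never auto-detected).
    """

    study_id: str
    probe_ids: list[str]
    sample_ids: list[str]
    labels: dict[str, str]
    values: np.ndarray
    scale_flag: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_flag not in ("linear", "log2"):
            raise DataError(f"scale_flag must be 'linear' or 'log2', got {self.scale_flag!r}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = pd.Index(self.probe_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate probe ids in study {self.study_id}: {dupes[:5]}")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise LabelError(f"samples without a class label: {missing}")
        classes = {self.labels[s] for s in self.sample_ids}
        if classes != {CASE, CONTROL}:
            raise LabelError(
                f"labels must cover exactly the classes {{case, control}}, got {sorted(classes)}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_columns(self, cls: str) -> np.ndarray:
        """Column indices of samples belonging to class ``cls``."""
        return np.array([i for i, s in enumerate(self.sample_ids) if self.labels[s] == cls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class ProbeAnnotation:
    """Map from probe-set identifier to one or more gene symbols."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        for probe, genes in self.entries.items():
            if not genes or any(not g for g in genes):
                raise DataError(f"probe {probe!r} maps to an empty gene symbol")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, probe: str) -> bool:
        return probe in self.entries

    def genes_for(self, probe: str) -> list[str]:
        return self.entries[probe]


@dataclass
class SignatureList:
    """A named gene list with normalized, de-duplicated symbols.

    ``genes`` keeps first-occurrence order (meaningful for ranked
    signatures such as a top-k list); set semantics are available via
    :attr:`gene_set`. ``duplicates_dropped`` is the load report for
    symbols that collapsed onto an earlier entry during normalization.
    """

    name: str
    genes: tuple[str, ...]
    duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"signature {self.name!r} contains duplicate symbols")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def normalize_symbol(raw: str) -> list[str]:
    """Normalize a printed gene symbol into one or more canonical tokens.

    Uppercases, strips surrounding whitespace and splits multi-gene
    fields on ``" / "`` or ``"///"``. Idempotent token-wise. Raises
    :class:`DataError` on whitespace-only input.
    """
    if raw is None or not str(raw).strip():
        raise DataError(f"cannot normalize empty gene symbol {raw!r}")
    tokens = [t.strip().upper() for t in _MULTI_GENE_SPLIT.split(str(raw).strip())]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise DataError(f"gene field {raw!r} contains no symbols after splitting")
    return tokens


def _dedupe(symbols: Iterable[str]) -> tuple[tuple[str, ...], int]:
    seen: dict[str, None] = {}
    dropped = 0
    for s in symbols:
        if s in seen:
            dropped += 1
        else:
            seen[s] = None
    return tuple(seen), dropped


def make_signature(name: str, symbols: Iterable[str], *, normalize: bool = True) -> SignatureList:
    """Build a SignatureList from raw symbols, normalizing and de-duplicating."""
    tokens: list[str] = []
    for raw in symbols:
        tokens.extend(normalize_symbol(raw) if normalize else [raw])
    genes, dropped = _dedupe(tokens)
    return SignatureList(name=name, genes=genes, duplicates_dropped=dropped)


def read_signature(path: str | Path, name: str | None = None) -> SignatureList:
    """Read a one-symbol-per-line (or single-column CSV) signature file."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln.split(",")[0].strip() for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise DataError(f"signature file {path} contains no gene symbols")
    return make_signature(name or path.stem, lines)


def write_signature(sig: SignatureList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sig.genes) + "\n")


def read_expression(
    path: str | Path,
    label_map: Mapping[str, str],
    *,
    study_id: str | None = None,
    scale_flag: str = "log2",
    sep: str = "\t",
) -> ExpressionDataset:
    """Read a probe × sample expression matrix with a sample-id header row.

    Rows with unparseable values raise a :class:`FormatError` rather than
    being silently dropped; empty cells and ``NA`` are accepted as missing.
    Every sample in the header must appear in ``label_map``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate probe ids in {path}: {dupes[:5]}")
    unknown = [s for s in df.columns if s not in label_map]
    if unknown:
        raise LabelError(f"header samples absent from label map: {unknown}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        cleaned = np.where(np.isin(raw, MISSING_TOKENS), "nan", raw)
        try:
            values[:, j] = cleaned.astype(float)
        except ValueError as exc:
            raise FormatError(f"unparseable value in column {col!r} of {path}: {exc}") from exc
    labels = {s: label_map[s] for s in df.columns}
    return ExpressionDataset(
        study_id=study_id or path.stem,
        probe_ids=list(df.index),
        sample_ids=list(df.columns),
        labels=labels,
        values=values,
        scale_flag=scale_flag,
    )


def write_expression(ds: ExpressionDataset, path: str | Path, *, float_format: str = "%.10g") -> None:
    ds.to_frame().to_csv(path, sep="\t", float_format=float_format, na_rep="NA")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, class) into a label map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs columns (sample_id, class)")
    sample_col, class_col = df.columns[:2]
    labels = dict(zip(df[sample_col], df[class_col]))
    bad = sorted(set(labels.values()) - {CASE, CONTROL})
    if bad:
        raise LabelError(f"unknown class tags in {path}: {bad} (expected case/control)")
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "class": [labels[s] for s in labels]}
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column TSV (probe_id, gene_field); multi-gene fields are split."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"annotation file {path} needs columns (probe_id, gene_field)")
    probe_col, gene_col = df.columns[:2]
    entries: dict[str, list[str]] = {}
    for probe, gene_field in zip(df[probe_col], df[gene_col]):
        if probe in entries:
            raise FormatError(f"duplicate probe id {probe!r} in annotation {path}")
        entries[probe] = normalize_symbol(gene_field)
    return ProbeAnnotation(entries=entries)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    rows = [(p, " /// ".join(genes)) for p, genes in ann.entries.items()]
    pd.DataFrame(rows, columns=["probe_id", "gene_field"]).to_csv(path, sep="\t", index=False)


_BUNDLED = {
    "melanoma_top200": "melanoma_top200.txt",
    "melanoma_12gene": "melanoma_12gene.txt",
}


def load_bundled_signature(key: str) -> SignatureList:
    """Load a signature shipped with the package.

    ``melanoma_top200`` is the published 200-gene integrated melanoma
    signature (rank order preserved); ``melanoma_12gene`` is the 12-gene
    diagnostic subset linked to melanoma driver-gene pathways.
    """
    if key not in _BUNDLED:
        raise KeyError(f"unknown bundled signature {key!r}; options: {sorted(_BUNDLED)}")
    text = resources.files("gwsig.data").joinpath(_BUNDLED[key]).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return make_signature(key, lines)
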