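"""Synthetic multi-study microarray data with planted differential expression.

The generator emulates the structure of a cross-laboratory two-class
microarray compendium: several studies over a partially overlapping gene
universe, one to a few probe-sets per gene, an occasional probe mapping
to two genes, per-study missing genes (a platform simply lacks them) and
a planted subset of differentially expressed genes shared by all
studies.

Generative model (log2 space): each gene draws a baseline expression
level once, shared across studies; control samples are
Normal(baseline, noise_sd) and case samples are shifted by a signed
per-gene effect for planted genes. Each probe of a gene adds its own
affinity offset plus probe-level noise, so probes of one gene disagree
realistically and the max-collapse has work to do. All randomness flows
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset, ProbeAnnotation
from .errors import ConfigError

#: spread of probe-specific affinity offsets (log2 units)
PROBE_AFFINITY_SD = 0.3
#: extra probe-level measurement noise on top of the gene signal (log2 units)
PROBE_NOISE_SD = 0.2


@dataclass
class SynthConfig:
    """Study-condition parameters for the generator.

    Defaults mirror a five-study melanoma-style compendium: 2000 genes,
    100 planted differentially expressed genes with a 2.0 log2-unit mean
    shift against unit-SD noise, 10 case + 10 control samples per study,
    1–3 probes per gene, 5% of probes mapping to two genes, and an 8%
    chance a study's platform lacks a given gene. Planted genes are
    guaranteed to survive a δ=2 absence filter (``max_planted_absence``).
    """

    n_studies: int = 5
    genes_total: int = 2000
    planted_de_count: int = 100
    effect_size: float = 2.0
    noise_sd: float = 1.0
    samples_per_class: int | tuple[int, int] = 10  # int or (n_control, n_case)
    probe_multiplicity: tuple[int, int] = (1, 3)
    multi_gene_probe_rate: float = 0.05
    absence_rate: float = 0.08
    max_planted_absence: int | None = None  # default: min(2, n_studies - 1)
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ConfigError("need at least one study")
        if not 0 < self.planted_de_count <= self.genes_total:
            raise ConfigError("planted_de_count must be in [1, genes_total]")
        if not 0 <= self.absence_rate < 1:
            raise ConfigError("absence_rate must lie in [0, 1)")
        if self.absence_rate > 0.5:
            raise ConfigError(
                "absence_rate above 0.5 would hollow out the gene universe; "
                "planted genes could not reliably survive the absence filter"
            )
        if not 0 <= self.planted_absence_cap < self.n_studies:
            raise ConfigError("max_planted_absence must be in [0, n_studies)")
        lo, hi = self.probe_multiplicity
        if not 1 <= lo <= hi:
            raise ConfigError("probe_multiplicity must be (lo, hi) with 1 <= lo <= hi")
        nc, na = self._class_sizes()
        if nc < 2 or na < 2:
            raise ConfigError("need at least two samples per class")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")

    @property
    def planted_absence_cap(self) -> int:
        if self.max_planted_absence is None:
            return min(2, self.n_studies - 1)
        return self.max_planted_absence

    def _class_sizes(self) -> tuple[int, int]:
        if isinstance(self.samples_per_class, tuple):
            return self.samples_per_class
        return self.samples_per_class, self.samples_per_class


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated compendium."""

    planted: frozenset[str]
    effects: dict[str, float]  # signed log2 shift, 0 for background genes
    presence: pd.DataFrame  # gene × study bool


@dataclass
class SynthResult:
    datasets: list[ExpressionDataset]
    annotations: dict[str, ProbeAnnotation]  # study_id -> annotation
    truth: SynthTruth


def generate(cfg: SynthConfig) -> SynthResult:
    """Generate a reproducible multi-study compendium from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"SG{i:05d}" for i in range(cfg.genes_total)]
    planted = sorted(rng.choice(cfg.genes_total, size=cfg.planted_de_count, replace=False))
    planted_set = frozenset(genes[i] for i in planted)
    signs = rng.choice([-1.0, 1.0], size=cfg.planted_de_count)
    effects = {g: 0.0 for g in genes}
    for idx, sign in zip(planted, signs):
        effects[genes[idx]] = float(sign * cfg.effect_size)
    baseline = rng.uniform(*cfg.baseline_range, size=cfg.genes_total)

    # per-study gene absence; planted genes capped so they survive the δ filter
    absent = rng.random((cfg.genes_total, cfg.n_studies)) < cfg.absence_rate
    cap = cfg.planted_absence_cap
    for idx in planted:
        n_absent = int(absent[idx].sum())
        if n_absent > cap:
            absent_studies = np.flatnonzero(absent[idx])
            keep_absent = rng.choice(absent_studies, size=cap, replace=False)
            absent[idx] = False
            absent[idx, keep_absent] = True
    presence = pd.DataFrame(
        ~absent,
        index=pd.Index(genes, name="gene"),
        columns=[f"study{j + 1}" for j in range(cfg.n_studies)],
    )

    n_control, n_case = cfg._class_sizes()
    datasets, annotations = [], {}
    for j in range(cfg.n_studies):
        study_id = f"study{j + 1}"
        sample_ids = [f"{study_id}_ctrl{i + 1}" for i in range(n_control)] + [
            f"{study_id}_case{i + 1}" for i in range(n_case)
        ]
        labels = {s: ("control" if "_ctrl" in s else "case") for s in sample_ids}
        present_idx = np.flatnonzero(presence[study_id].to_numpy())
        # gene-level sample signal for this study
        n_samples = n_control + n_case
        gene_signal = np.empty((len(present_idx), n_samples))
        for row, gi in enumerate(present_idx):
            mu = baseline[gi]
            eff = effects[genes[gi]]
            ctrl = rng.normal(mu, cfg.noise_sd, size=n_control)
            case = rng.normal(mu + eff, cfg.noise_sd, size=n_case)
            gene_signal[row] = np.concatenate([ctrl, case])
        # instantiate probes
        lo, hi = cfg.probe_multiplicity
        multiplicity = rng.integers(lo, hi + 1, size=len(present_idx))
        probe_ids: list[str] = []
        probe_rows: list[np.ndarray] = []
        entries: dict[str, list[str]] = {}
        counter = 0
        for row, gi in enumerate(present_idx):
            for _ in range(multiplicity[row]):
                probe = f"{study_id}_{counter:05d}_at"
                counter += 1
                offset = rng.normal(0.0, PROBE_AFFINITY_SD)
                noise = rng.normal(0.0, PROBE_NOISE_SD, size=n_samples)
                probe_rows.append(gene_signal[row] + offset + noise)
                mapped = [genes[gi]]
                if rng.random() < cfg.multi_gene_probe_rate and len(present_idx) > 1:
                    other = int(rng.choice(present_idx))
                    if other != gi:
                        mapped.append(genes[other])
                probe_ids.append(probe)
                entries[probe] = mapped
        datasets.append(
            ExpressionDataset(
                study_id=study_id,
                probe_ids=probe_ids,
                sample_ids=sample_ids,
                labels=labels,
                values=np.vstack(probe_rows),
                scale_flag="log2",
            )
        )
        annotations[study_id] = ProbeAnnotation(entries=entries)
    truth = SynthTruth(planted=planted_set, effects=effects, presence=presence)
    return SynthResult(datasets=datasets, annotations=annotations, truth=truth)


def write_truth(truth: SynthTruth, path) -> None:
    """Emit the ground truth as a TSV (gene, planted, effect, presence per study)."""
    out = truth.presence.astype(int).copy()
    out.insert(0, "effect", [truth.effects[g] for g in out.index])
    out.insert(0, "planted", [int(g in truth.planted) for g in out.index])
    out.to_csv(path, sep="\t")
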