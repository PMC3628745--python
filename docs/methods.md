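# Methods

## Model

The framework treats each study as a voter over a shared gene universe.
Study *j* scores every gene it measures with a differential-expression
measure, ranks the scored genes in descending order of evidence
(rank 1 = strongest), and converts the rank into the per-study score

    s_ij = -2 log(r_ij / m)

where *m* is the size of the retained cross-study gene universe.
The combined score of gene *i* is the convex combination
`s_i^r = sum_j w_j s_ij` with nonnegative weights summing to one
(equal weights `1/n` by default; weights may encode data-quality or
sample-type preferences). Because only ranks leave a study, any
monotone rescaling of one study's statistics — a different array
platform, a different normalization, a multiplicative batch effect —
leaves its contribution unchanged. The Fisher combination
`s_p = -2 sum_i log(p_i)` is retained as the classical baseline; under
independent uniform p-values it is chi-square with 2n degrees of
freedom, which the test suite verifies by simulation.

### Assumptions

* Studies are independent and address the same two-class contrast.
* Within a study, the chosen DE measure orders genes sensibly; no
  distributional form is assumed beyond that.
* Cross-study evidence is exchangeable up to the chosen weights: a
  rank-1 gene is equally meaningful in every study, which is why the
  score denominator is the global *m* rather than the per-study count
  of measured genes (the best attainable s_ij is then identical across
  studies).

## Preprocessing

Probe-sets are collapsed to genes per study. A probe annotated to k
genes donates its expression row to all k (multi-gene annotations such
as `"ABCB1 / ABCB4"` are split during symbol normalization). A gene
measured by several probes keeps the row of the probe with the largest
probe-level absolute log2 fold change — the "max" collapse, chosen so a
gene is represented by its most competitive evidence instead of being
dragged toward the platform average by mean- or median-collapsing.
Score ties break to the lexicographically smallest probe id, making the
collapse deterministic and order-independent. Collapse is per-study:
the same gene may be carried by different probes on different
platforms.

The universe is the union of collapsed gene lists minus any gene absent
from strictly more than δ studies (default δ = 2; absence in exactly δ
studies is allowed). Genes absent from a retained study carry a missing
marker through ranks and scores; by default the combination weights are
renormalized over the contributing studies, so platform coverage is not
conflated with biology. The alternative policy (`missing_policy="zero"`,
treating a missing score as 0) is available for sensitivity analysis.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `measure` | `fold_change` | per-study DE measure; `t_test_p` (Welch) as alternative. Fold change is the default because rank stability matters more than calibrated p-values at the small sample sizes typical of these studies. |
| `direction` | `absolute` | `absolute` puts under- and over-expression on one scale; `signed` available. The collapse step uses the same measure, absolute by default. |
| `delta` | 2 | maximum allowed per-gene absence count; must be < n. |
| `weights` | equal (1/n) | per-study combination weights. |
| `missing_policy` | `renormalize` | handling of missing per-study scores in the combination. |
| `log_base` | e | natural log matches the Fisher/chi-square convention; orderings are base-invariant, only the scale changes (base 10 exposed). |
| SVM `kernel`, `C` | linear, 1.0 | evaluation classifier; features standardized on each training fold. |
| plateau `tolerance` | 0.005 | absolute accuracy slack defining "similar performance" in wrapper selection. |

Ties in DE scores receive the mean of the occupied rank positions
(fractional ranks are admitted by the score formula); final gene
orderings break ties by contributing-study count, then symbol, so every
output is deterministic.

## Evaluation protocol

A signature is evaluated per study by leave-one-out cross-validation:
one fold per sample, features standardized on the training fold only,
linear-kernel SVM, accuracy = fraction of held-out samples classified
correctly. Cross-study reports average the per-study accuracies without
weighting; a signature with no gene on a platform yields a flagged
non-evaluable cell rather than a zero. The "across-laboratory" reading
is per-study LOO with a shared signature — train-on-one/test-on-another
transfer is deliberately not the default. Wrapper feature selection
evaluates top-k prefixes over a user grid (canonically 20–500) and
returns the smallest k whose average accuracy is within the tolerance
of the grid maximum; ties resolve toward smaller k (parsimony).

## Synthetic data

The generator emulates a multi-study compendium in log2 space: each
gene draws one baseline level uniform on [6, 12] shared across studies
(so fold-change and t-test orderings differ and both code paths are
exercised); control samples are Normal(baseline, `noise_sd`), case
samples are shifted by a random-signed `effect_size` for planted genes.
Probes instantiate genes with multiplicity uniform on {1..3}, add a
probe-specific affinity offset (SD 0.3) plus probe-level noise
(SD 0.2), and 5% of probes additionally map to a second gene. Absence
is simulated at gene level (the platform lacks the gene) independently
per study at rate 0.08; planted genes have their absence capped at
min(2, n−1) studies so the planted signal always survives the default
δ filter. A single integer seed fully determines the output.

Default conditions — 5 studies, 2000 genes, 100 planted genes with a
2.0 log2-unit shift against unit noise, 10+10 samples per study —
represent a clearly detectable but non-trivial multi-study signal: a
single study recovers most but not all planted genes in its top 200,
and integration closes the gap.

What the generator does **not** emulate: probe-level intensity physics
(PM/MM), spatial artifacts, real platform annotation maps,
heavy-tailed or correlated gene noise, confounded batch structure, and
sample heterogeneity within a class. Passing tests therefore
demonstrate correctness of the algorithms and the expected qualitative
behaviour (integration ≥ best single study, null calibration, monotone
recovery in effect size and study count), not performance on any real
compendium.

## Numerical choices and degenerate inputs

* Linear-scale matrices must be strictly positive before log2; a
  non-positive value is an error, never silently clipped.
* Welch t-test on a gene with zero variance in both classes: p = 1 when
  the means are equal (no evidence), p = 0 when they differ (infinite
  standardized separation).
* Fisher combination rejects p ≤ 0 or p > 1 outright; no machine-epsilon
  clipping is applied on the caller's behalf.
* Missing expression cells (`NA`/empty) are accepted on input and
  ignored by class means; a signature-evaluation matrix imputes the
  per-gene mean before classification.
* All sorts are stable with explicit tie-break keys; re-running any
  stage with the same config and seed reproduces artifacts
  byte-for-byte.

## Design choices where the design was open

* **Ranking pool.** Ranks are assigned only among genes present in a
  study, while the score denominator stays the global *m*. The
  alternative (letting absent genes consume rank positions) would make
  the best attainable score depend on platform coverage.
* **Collapse score.** The probe chosen per gene is the one maximizing
  the same DE measure later used for ranking, computed at probe level
  before collapse, absolute by default (a config switch restores signed
  scoring).
* **Classifier settings.** Linear kernel, C = 1.0, per-fold
  standardization: the standard configuration for p >> n expression
  classification. Exact reproduction of any externally published
  accuracy table is not asserted anywhere, since published SVM settings
  for such tables are typically unreported.
* **Symbol matching.** Uppercase + trim + delimiter split only, no
  alias/HGNC resolution — overlap counts stay reproducible from printed
  lists, at the documented risk that symbol-dialect differences between
  sources deflate overlap counts.

## Problem sizes

The test suite and the reproduction script run the full pipeline at
2000 genes × 5 studies (the default synthetic conditions), the oracle
comparison at 50 genes × 3 studies, and Monte-Carlo calibrations at
10⁴ draws — sizes at which every documented behaviour is already
clearly measurable while the whole suite completes in well under a
minute on one core.

## Known limitations

* Equal study weights are a modelling choice, not an optimum; no
  data-driven weighting is provided.
* The δ filter and missing-score renormalization assume missingness is
  platform-driven (missing completely at random with respect to the
  contrast); informative missingness would bias the combined score.
* No batch correction or cross-study normalization is attempted — by
  design the method never compares expression values across studies,
  but this also means within-study confounding passes through.
* SAM and ANOVA DE measures are interface hooks only; the occurrence
  analysis reproduces printed-list relations and does not attempt
  literature mining.
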