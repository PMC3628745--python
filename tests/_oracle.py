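"""Independent brute-force recomputation of the full integration pipeline.

Deliberately written with plain Python containers, explicit loops and
``math.log`` — no shared code with the package internals — so it can
serve as an oracle for the collapse → rank → score → combine chain.
Assumes log2-scale input matrices.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def brute_force_integration(datasets, annotations, delta, k):
    """Return (universe_genes, s_r dict, top-k gene list) by exhaustive computation."""
    per_study_scores = {}  # study -> {gene: abs log2 fc of winning probe}
    for ds in datasets:
        ann = annotations[ds.study_id]
        case_cols = [i for i, s in enumerate(ds.sample_ids) if ds.labels[s] == "case"]
        ctrl_cols = [i for i, s in enumerate(ds.sample_ids) if ds.labels[s] == "control"]
        probe_fc = {}
        for r, probe in enumerate(ds.probe_ids):
            row = ds.values[r]
            fc = _mean([row[c] for c in case_cols]) - _mean([row[c] for c in ctrl_cols])
            probe_fc[probe] = abs(fc)
        gene_probes = {}
        for probe in ds.probe_ids:
            if probe not in ann.entries:
                continue
            for gene in ann.entries[probe]:
                gene_probes.setdefault(gene, []).append(probe)
        scores = {}
        for gene, probes in gene_probes.items():
            best = None
            for p in probes:  # max score, ties to smallest probe id
                if best is None or probe_fc[p] > probe_fc[best] or (
                    probe_fc[p] == probe_fc[best] and p < best
                ):
                    best = p
            scores[gene] = probe_fc[best]
        per_study_scores[ds.study_id] = scores

    studies = [ds.study_id for ds in datasets]
    union = sorted(set().union(*(set(s) for s in per_study_scores.values())))
    kept = [
        g for g in union
        if sum(g not in per_study_scores[st] for st in studies) <= delta
    ]
    m = len(kept)

    # per-study ranks with mean-rank ties, present genes only
    s_values = {g: [] for g in kept}
    for st in studies:
        scores = per_study_scores[st]
        present = [g for g in kept if g in scores]
        order = sorted(present, key=lambda g: -scores[g])
        ranks = {}
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and scores[order[j]] == scores[order[i]]:
                j += 1
            avg = _mean(list(range(i + 1, j + 1)))
            for g in order[i:j]:
                ranks[g] = avg
            i = j
        for g in kept:
            if g in ranks:
                s_values[g].append(-2.0 * math.log(ranks[g] / m))
            else:
                s_values[g].append(None)

    s_r, n_contrib = {}, {}
    for g in kept:
        contributing = [s for s in s_values[g] if s is not None]
        s_r[g] = _mean(contributing)  # equal weights renormalized = plain mean
        n_contrib[g] = len(contributing)
    order = sorted(kept, key=lambda g: (-s_r[g], -n_contrib[g], g))
    return kept, s_r, order[:k]
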