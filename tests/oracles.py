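"""Independent brute-force oracles used to cross-check the estimators.

These are deliberately naive re-implementations (explicit loops, direct
formula transcription) kept separate from the package code paths they
verify.
"""

import itertools
import math

import numpy as np


def sd(xs):
    xs = list(xs)
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def genorm_trace(cq_by_gene):
    """Stepwise geNorm on a {gene: [cq per sample]} dict (efficiency 2).

    Returns (reported_M, exclusion_order, final_pair) with the same tie
    rule as the package: the lexicographically last id among tied-worst
    genes is removed.
    """

    def pair_v(a, b):
        return sd(x - y for x, y in zip(cq_by_gene[b], cq_by_gene[a]))

    active = sorted(cq_by_gene)
    reported, order = {}, {}
    step = 0
    while len(active) > 2:
        m = {
            g: sum(pair_v(g, h) for h in active if h != g) / (len(active) - 1)
            for g in active
        }
        worst = max(m.values())
        drop = max(g for g in active if m[g] == worst)
        step += 1
        reported[drop] = m[drop]
        order[drop] = step
        active.remove(drop)
    final = pair_v(active[0], active[1])
    for i, g in enumerate(sorted(active)):
        reported[g] = final
        order[g] = len(cq_by_gene) - 1 + i
    return reported, order, tuple(sorted(active))


def delta_ct_values(cq_by_gene):
    """Comparative ΔCt: mean over partners of SD of pairwise differences."""
    out = {}
    for g in cq_by_gene:
        sds = [
            sd(x - y for x, y in zip(cq_by_gene[g], cq_by_gene[h]))
            for h in cq_by_gene
            if h != g
        ]
        out[g] = sum(sds) / len(sds)
    return out


def bestkeeper_values(cq_by_gene, dispersion="mad"):
    """BestKeeper sd/cv/r by direct enumeration."""
    genes = list(cq_by_gene)
    n = len(cq_by_gene[genes[0]])
    out = {}
    index = [
        math.exp(sum(math.log(cq_by_gene[g][j]) for g in genes) / len(genes))
        for j in range(n)
    ]
    for g in genes:
        xs = cq_by_gene[g]
        mean = sum(xs) / n
        if dispersion == "mad":
            disp = sum(abs(x - mean) for x in xs) / n
        else:
            disp = sd(xs)
        r = np.corrcoef(xs, index)[0, 1] if sd(xs) > 0 else float("nan")
        out[g] = {"sd_cp": disp, "cv_pct": 100 * disp / mean, "r_index": r}
    return out


def normfinder_values(log2_by_gene, groups=None):
    """Second independent coding of the Andersen estimators.

    ``log2_by_gene``: {gene: [log2 expression per sample]};
    ``groups``: optional per-sample labels.
    """
    genes = list(log2_by_gene)
    G = len(genes)
    n = len(log2_by_gene[genes[0]])
    z = {
        g: [
            log2_by_gene[g][j] - sum(log2_by_gene[h][j] for h in genes) / G
            for j in range(n)
        ]
        for g in genes
    }

    def corrected(zsub):
        s2 = {g: sd(zsub[g]) ** 2 for g in genes}
        t = sum(s2.values())
        return {
            g: max(0.0, (s2[g] - t / (G * (G - 1))) * G / (G - 2)) for g in genes
        }

    if groups is None:
        var = corrected(z)
        return {g: math.sqrt(var[g]) for g in genes}

    labels = list(dict.fromkeys(groups))
    m = len(labels)
    idx = {lab: [j for j, x in enumerate(groups) if x == lab] for lab in labels}
    var_gi, d_hat = {}, {}
    for lab in labels:
        zi = {g: [z[g][j] for j in idx[lab]] for g in genes}
        var_gi[lab] = corrected(zi)
        for g in genes:
            d_hat[(g, lab)] = sum(zi[g]) / len(idx[lab]) - sum(z[g]) / n
    sampling = {
        (g, lab): var_gi[lab][g] / len(idx[lab]) for g in genes for lab in labels
    }
    gamma2 = max(
        0.0,
        sum(d**2 for d in d_hat.values()) / ((G - 1) * (m - 1))
        - sum(sampling.values()) / (G * m),
    )
    out = {}
    for g in genes:
        acc = 0.0
        for lab in labels:
            shrink = (
                gamma2 / (gamma2 + sampling[(g, lab)])
                if gamma2 + sampling[(g, lab)] > 0
                else 0.0
            )
            acc += abs(d_hat[(g, lab)] * shrink) + math.sqrt(sampling[(g, lab)])
        out[g] = acc / m
    return out


def upgma_heights(dist):
    """Brute-force UPGMA merge heights from a condensed-style square matrix."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    d = {
        (i, j): float(dist[i, j])
        for i, j in itertools.combinations(range(dist.shape[0]), 2)
    }

    def cdist(a, b):
        return sum(
            float(dist[i, j]) if i < j else float(dist[j, i])
            for i in clusters[a]
            for j in clusters[b]
        ) / (len(clusters[a]) * len(clusters[b]))

    next_id = dist.shape[0]
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((a, b) for a, b in itertools.combinations(keys, 2)),
            key=lambda ab: cdist(*ab),
        )
        heights.append(cdist(*best))
        clusters[next_id] = clusters.pop(best[0]) + clusters.pop(best[1])
        next_id += 1
    return heights
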