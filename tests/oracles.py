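"""Independent brute-force oracles, deliberately coded with plain loops
and no shared code with the package implementation."""

from __future__ import annotations

import math

import numpy as np


def brute_force_quantify(spot_rows, probe_to_species, fold=5.0):
    """Plain-python transcription of the detection-calling chain.

    ``spot_rows``: iterable of (probe_id, cy5, cy3).
    Returns (background, baseline, calls, abundance) where ``calls``
    maps species -> (pass_intensity, pass_ratio, positive) and
    ``abundance`` maps species -> relative abundance.
    """
    per_species: dict[str, list[tuple[float, float]]] = {}
    for probe, cy5, cy3 in spot_rows:
        per_species.setdefault(probe_to_species[probe], []).append((cy5, cy3))

    stats = {}
    for sp, vals in per_species.items():
        m5 = sum(v[0] for v in vals) / len(vals)
        m3 = sum(v[1] for v in vals) / len(vals)
        ratio = m5 / m3 if m3 > 0 else None
        stats[sp] = (m5, m3, ratio)

    species = sorted(stats)
    by_intensity = sorted(species, key=lambda s: (stats[s][0], s))
    k_bg = max(1, math.floor(0.3 * len(species)))
    background = sum(stats[s][0] for s in by_intensity[:k_bg]) / k_bg

    defined = [s for s in species if stats[s][2] is not None]
    by_ratio = sorted(defined, key=lambda s: (stats[s][2], s))
    k_bl = max(1, math.floor(len(defined) / 2))
    baseline = sum(stats[s][2] for s in by_ratio[:k_bl]) / k_bl

    calls = {}
    for s in species:
        p_int = stats[s][0] > fold * background
        p_rat = stats[s][2] is not None and stats[s][2] > fold * baseline
        calls[s] = (p_int, p_rat, p_int and p_rat)

    total = sum(stats[s][2] for s in species if calls[s][2])
    abundance = {
        s: (stats[s][2] / total if calls[s][2] else 0.0) for s in species
    }
    return background, baseline, calls, abundance


def pairwise_auc(scores, labels):
    """Concordance probability over every positive/negative pair; ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        r = (i + j + 1) / 2.0
        for t in range(i, j):
            ranks[order[t]] = r
        i = j
    n_a = len(a)
    obs = sum(ranks[:n_a])
    mean = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n_a):
        stat = sum(ranks[i] for i in combo)
        total += 1
        if abs(stat - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def lda_effect_oracle(x, y):
    """Single-round LEfSe effect sizes via the closed-form LDA axis.

    ``x``: (n, p) rescaled abundances, ``y``: boolean class labels.
    Returns the per-feature effect e so score = log10(1 + e).
    """
    mu1, mu0 = x[y].mean(axis=0), x[~y].mean(axis=0)
    xc = np.vstack([x[y] - mu1, x[~y] - mu0])
    sw = xc.T @ xc / (len(x) - 2)
    w = np.linalg.solve(sw, mu1 - mu0)
    w = w / np.linalg.norm(w)
    proj = x @ w
    gap = abs(proj[y].mean() - proj[~y].mean())
    coeff = np.abs(w * gap)
    raw = np.abs(mu1 - mu0)
    return 0.5 * (raw + coeff)
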