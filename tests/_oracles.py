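"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorized code paths: plain
Python loops and direct formula transcriptions.
"""

from __future__ import annotations

import math

import numpy as np


def bf_backward(values):
    """Direct transcription of the backward-generator formulas."""
    xs = [float(v) for v in values]
    n = len(xs)
    ex = sum(xs) / n
    en = math.sqrt(math.pi / 2.0) * sum(abs(x - ex) for x in xs) / n
    s2 = sum((x - ex) ** 2 for x in xs) / (n - 1)
    gap = s2 - en**2
    he = math.sqrt(gap) if gap > 0 else 0.0
    return ex, en, he


def bf_quantize(band, levels):
    band = np.asarray(band, dtype=float)
    lo, hi = band.min(), band.max()
    out = np.zeros(band.shape, dtype=int)
    if hi == lo:
        return out
    for r in range(band.shape[0]):
        for c in range(band.shape[1]):
            q = int((band[r, c] - lo) / (hi - lo) * levels)
            out[r, c] = min(max(q, 0), levels - 1)
    return out


def bf_glcm(patch, offsets, levels, symmetric):
    patch = np.asarray(patch)
    h, w = patch.shape
    counts = np.zeros((levels, levels))
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[patch[r, c], patch[r2, c2]] += 1.0
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def bf_haralick(P):
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    pi = [sum(P[i, j] for j in range(L)) for i in range(L)]
    pj = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_i = sum(i * pi[i] for i in range(L))
    mu_j = sum(j * pj[j] for j in range(L))
    var_i = sum((i - mu_i) ** 2 * pi[i] for i in range(L))
    var_j = sum((j - mu_j) ** 2 * pj[j] for j in range(L))
    mean = var = hom = con = dis = ent = asm = cor = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            mean += i * p
            var += (i - mu_i) ** 2 * p
            hom += p / (1.0 + (i - j) ** 2)
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            if p > 0:
                ent -= p * math.log(p)
            asm += p * p
            cor += (i - mu_i) * (j - mu_j) * p
    denom = math.sqrt(var_i * var_j)
    cor = cor / denom if denom else float("nan")
    return np.array([mean, var, hom, con, dis, ent, asm, cor])


def bf_texture_at(band, cfg, r, c):
    """Recompute the eight texture parameters of one pixel from scratch."""
    q = bf_quantize(band, cfg.levels)
    half = cfg.window // 2
    padded = np.pad(q, half, mode="reflect")
    patch = padded[r : r + cfg.window, c : c + cfg.window]
    P = bf_glcm(patch, cfg.offsets, cfg.levels, cfg.symmetric)
    return bf_haralick(P)


def bf_decide_1d(x, params_by_species):
    """Assign x to the species minimizing (x - Ex)^2 / (2 En^2);
    ties go to the lexicographically smallest species id."""
    scores = {
        sp: (x - p.Ex) ** 2 / (2.0 * p.En**2) for sp, p in params_by_species.items()
    }
    best = min(scores.values())
    return sorted(sp for sp, s in scores.items() if s == best)[0]
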