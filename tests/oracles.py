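"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the library calls the implementations use:
component labelling is a hand-written flood fill, dilation is a per-pixel
neighborhood sweep, the KS statistic is a sup over pooled points, and BH
adjustment follows the step-up recipe directly.
"""

from __future__ import annotations

import numpy as np


def naive_nucleinator(image, cell_mask, k_sd=1.0, min_size=25, dilation=1):
    """Per-pixel threshold + flood-fill components + chebyshev dilation."""
    img = np.asarray(image, float)
    cm = np.asarray(cell_mask, bool)
    pix = img[cm]
    mu, sd = pix.mean(), pix.std()
    if sd == 0:
        return np.zeros_like(cm)
    cand = (img > mu + k_sd * sd) & cm
    h, w = cand.shape
    seen = np.zeros_like(cand)
    keep = np.zeros_like(cand)
    for r0 in range(h):
        for c0 in range(w):
            if not cand[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and cand[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if len(comp) > min_size:
                for r, c in comp:
                    keep[r, c] = True
    if dilation and keep.any():
        out = np.zeros_like(keep)
        rows, cols = np.nonzero(keep)
        for r, c in zip(rows, cols):
            r0, r1 = max(0, r - dilation), min(h, r + dilation + 1)
            c0, c1 = max(0, c - dilation), min(w, c + dilation + 1)
            out[r0:r1, c0:c1] = True
        keep = out
    return keep


def brute_ks_statistic(a, b):
    """sup |ECDF_a - ECDF_b| over all pooled sample points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    pooled = np.concatenate([a, b])
    d = 0.0
    for x in pooled:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def oneway_anova_f(groups):
    """Textbook one-way ANOVA F statistic from sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)
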