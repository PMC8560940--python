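"""Brute-force oracles, independent of the library's code paths.

Ranking is done by explicit sorting, the Kruskal-Wallis H by the textbook
formula, and the null distributions by full enumeration (all group splits,
all 2^n sign patterns) — nothing here calls scipy or the package internals.
"""

import itertools

import numpy as np


def rank_with_ties(values):
    """Average ranks by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from the textbook rank formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    h = 0.0
    off = 0
    for g in groups:
        r = sum(ranks[off : off + len(g)])
        h += r * r / len(g)
        off += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - sum(c**3 - c for c in counts) / (n**3 - n)
    return h / correction


def kw_exact_p_oracle(groups):
    """Exact permutation p by enumerating every split of the pooled sample."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = kw_h_oracle(groups)
    count = total = 0

    def splits(remaining, szs):
        if not szs:
            yield []
            return
        for combo in itertools.combinations(remaining, szs[0]):
            rest = [i for i in remaining if i not in combo]
            for tail in splits(rest, szs[1:]):
                yield [list(combo)] + tail

    for assign in splits(list(range(len(pooled))), sizes):
        perm = [[pooled[i] for i in ix] for ix in assign]
        count += kw_h_oracle(perm) >= h_obs - 1e-12
        total += 1
    return count / total


def wilcoxon_exact_p_oracle(diffs):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = [x for x in diffs if x != 0]
    ranks = rank_with_ties([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def loop_masked_mean(ff, mask, slice_range=None):
    """Masked mean by an explicit voxel loop (optionally bulk-restricted)."""
    vals = []
    nx, ny, nz = ff.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if slice_range is not None and not (
                    slice_range[0] <= k <= slice_range[1]
                ):
                    continue
                if mask[i, j, k] and not np.isnan(ff[i, j, k]):
                    vals.append(ff[i, j, k])
    return np.mean(vals)
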