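"""Independent brute-force oracles shared by the diversity tests and the
acceptance suite. These enumerate every branch / element explicitly and
never call the implementations they check."""

import numpy as np


def branches(tree):
    """(length, set of descendant leaf names) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        out.append((node.length, leaves))
    return out


def brute_faith_pd(counts, taxa, tree):
    present = {t for t, c in zip(taxa, counts) if c > 0}
    return sum(b for b, leaves in branches(tree) if leaves & present)


def brute_unweighted_unifrac(x, y, taxa, tree):
    px = {t for t, c in zip(taxa, x) if c > 0}
    py = {t for t, c in zip(taxa, y) if c > 0}
    unique = observed = 0.0
    for b, leaves in branches(tree):
        in_x, in_y = bool(leaves & px), bool(leaves & py)
        if in_x or in_y:
            observed += b
            if in_x != in_y:
                unique += b
    return unique / observed


def brute_weighted_unifrac(x, y, taxa, tree, normalized=True):
    tx, ty = sum(x), sum(y)
    num = den = 0.0
    for b, leaves in branches(tree):
        pa = sum(c for t, c in zip(taxa, x) if t in leaves) / tx
        pb = sum(c for t, c in zip(taxa, y) if t in leaves) / ty
        num += b * abs(pa - pb)
        den += b * (pa + pb)
    return num / den if normalized else num


def brute_bray_curtis(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def brute_chao1(counts):
    counts = np.asarray(counts)
    s = (counts > 0).sum()
    f1 = (counts == 1).sum()
    f2 = (counts == 2).sum()
    if f2 > 0:
        return s + f1 ** 2 / (2 * f2)
    return s + f1 * (f1 - 1) / 2

def brute_pcoa_coords(d):
    """Classical scaling by explicit eigendecomposition."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    w, v = w[::-1], v[:, ::-1]
    pos = w > max(w.max(), 0) * 1e-12
    return v[:, pos] * np.sqrt(w[pos])


def brute_ld_prune(g, positions, window_kb, step_snps, r2_max):
    """Independent re-implementation of the documented greedy pruning."""
    m = g.shape[1]
    p = g.mean(axis=0) / 2
    maf = np.minimum(p, 1 - p)
    kept = set(range(m))
    start = 0
    while start < m:
        window = [i for i in range(start, m)
                  if positions[i] < positions[start] + window_kb * 1000]
        while True:
            pair = None
            present = sorted(i for i in window if i in kept)
            for ai in range(len(present)):
                for bi in range(ai + 1, len(present)):
                    i, j = present[ai], present[bi]
                    if g[:, i].std() == 0 or g[:, j].std() == 0:
                        continue
                    if np.corrcoef(g[:, i], g[:, j])[0, 1] ** 2 > r2_max:
                        pair = (i, j)
                        break
                if pair:
                    break
            if pair is None:
                break
            i, j = pair
            kept.discard(i if maf[i] < maf[j] else j)
        start += step_snps
    return sorted(kept)
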