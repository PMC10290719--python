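"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's index bookkeeping: signatures are
enumerated by naive loops over site pairs/triples and located by searching
the space's descriptive labels, so agreement with the implementation is a
genuine cross-check.
"""

import itertools
import math

import numpy as np


def brute_force_signature(sites, space):
    """O(n^3) enumeration of 2-/3-point signatures from (family, xyz) sites."""
    counts = np.zeros(space.dimension, dtype=np.int64)

    def bin_of(d):
        for i, (lo, hi) in enumerate(space.bins):
            if lo <= d < hi:
                return i
        return None

    n = len(sites)
    if 2 in space.point_counts:
        for i in range(n):
            for j in range(i + 1, n):
                d = math.dist(sites[i][1], sites[j][1])
                b = bin_of(d)
                if b is None:
                    continue
                fams = tuple(sorted((sites[i][0], sites[j][0])))
                counts[space.signature_index(fams, (b,))] += 1
    if 3 in space.point_counts:
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    trio = (i, j, k)
                    dm = {}
                    ok = True
                    for a, b2 in itertools.combinations(trio, 2):
                        bb = bin_of(math.dist(sites[a][1], sites[b2][1]))
                        if bb is None:
                            ok = False
                            break
                        dm[frozenset((a, b2))] = bb
                    if not ok:
                        continue
                    fam_sorted = tuple(sorted(sites[s][0] for s in trio))
                    best = None
                    for perm in itertools.permutations(trio):
                        if tuple(sites[s][0] for s in perm) != fam_sorted:
                            continue
                        bt = (
                            dm[frozenset((perm[0], perm[1]))],
                            dm[frozenset((perm[0], perm[2]))],
                            dm[frozenset((perm[1], perm[2]))],
                        )
                        if best is None or bt < best:
                            best = bt
                    counts[space.signature_index(fam_sorted, best)] += 1
    return counts


def closed_form_metrics(y, p):
    """Textbook formulas on plain floats (no library calls)."""
    n = len(y)
    my, mp = sum(y) / n, sum(p) / n
    cov = sum((a - my) * (b - mp) for a, b in zip(y, p))
    vy = sum((a - my) ** 2 for a in y)
    vp = sum((b - mp) ** 2 for b in p)
    pcc = cov / math.sqrt(vy * vp)
    ss_res = sum((a - b) ** 2 for a, b in zip(y, p))
    r2 = 1 - ss_res / vy
    rmse = math.sqrt(ss_res / n)
    mae = sum(abs(a - b) for a, b in zip(y, p)) / n
    return pcc, r2, rmse, mae


def cross_product_or(n_gp, n_op, n_gn, n_on):
    """2x2 cross-product ratio (valid whenever no cell is zero)."""
    return (n_gp * n_on) / (n_op * n_gn)
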