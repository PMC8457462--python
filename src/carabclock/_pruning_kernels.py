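"""Numba-compiled inner loops of the pruning likelihood.

Imported lazily by :mod:`carabclock.seqlike`; when numba is unavailable the
caller falls back to equivalent (slower) numpy code.  Semantics are identical
to the numpy path: per-pattern rescaling shared across rate categories, with
accumulated log scalers per internal node.
"""

import math

import numba
import numpy as np

__all__ = ["update_partials", "root_loglik"]


@numba.njit(cache=True, fastmath=True)
def update_partials(pmats, partials, scalers, tip_partials, children, nodes, n_tips):
    """Recompute partials/scalers of ``nodes`` (ascending postorder indices)."""
    ncat = pmats.shape[1]
    npat = partials.shape[3]
    for oi in range(nodes.shape[0]):
        idx = nodes[oi]
        slot = idx - n_tips
        c1 = children[slot, 0]
        c2 = children[slot, 1]
        for cat in range(ncat):
            if c1 < n_tips:
                l1 = tip_partials[c1]
            else:
                l1 = partials[c1 - n_tips, cat]
            if c2 < n_tips:
                l2 = tip_partials[c2]
            else:
                l2 = partials[c2 - n_tips, cat]
            p1 = pmats[c1, cat]
            p2 = pmats[c2, cat]
            out = partials[slot, cat]
            for p in range(npat):
                x0 = l1[0, p]
                x1 = l1[1, p]
                x2 = l1[2, p]
                x3 = l1[3, p]
                y0 = l2[0, p]
                y1 = l2[1, p]
                y2 = l2[2, p]
                y3 = l2[3, p]
                for i in range(4):
                    a = p1[i, 0] * x0 + p1[i, 1] * x1 + p1[i, 2] * x2 + p1[i, 3] * x3
                    b = p2[i, 0] * y0 + p2[i, 1] * y1 + p2[i, 2] * y2 + p2[i, 3] * y3
                    out[i, p] = a * b
        for p in range(npat):
            mx = 0.0
            for cat in range(ncat):
                for i in range(4):
                    v = partials[slot, cat, i, p]
                    if v > mx:
                        mx = v
            if mx <= 0.0:
                mx = 1.0
            inv = 1.0 / mx
            for cat in range(ncat):
                for i in range(4):
                    partials[slot, cat, i, p] *= inv
            sc = math.log(mx)
            if c1 >= n_tips:
                sc += scalers[c1 - n_tips, p]
            if c2 >= n_tips:
                sc += scalers[c2 - n_tips, p]
            scalers[slot, p] = sc


@numba.njit(cache=True, fastmath=True)
def root_loglik(partials_root, scalers_root, pi, counts):
    """Sum over patterns of count * (log mean-over-categories site lik + scaler)."""
    ncat = partials_root.shape[0]
    npat = partials_root.shape[2]
    total = 0.0
    for p in range(npat):
        site = 0.0
        for cat in range(ncat):
            for i in range(4):
                site += pi[i] * partials_root[cat, i, p]
        site /= ncat
        if site <= 0.0:
            return -np.inf
        total += counts[p] * (math.log(site) + scalers_root[p])
    return total
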