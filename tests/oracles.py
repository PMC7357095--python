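"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: the SJI oracle
enumerates per-gene membership patterns; the slice-test oracle fits the
cell-means model by raw least squares and forms the LS-means contrast; the
BH oracle applies the step-up rule literally.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def sji_bruteforce(up1, down1, up2, down2) -> float:
    """SJI via exhaustive enumeration of every gene's membership pattern."""
    up1, down1, up2, down2 = map(set, (up1, down1, up2, down2))
    counts: dict[tuple[str, str], int] = {}
    for gene in up1 | down1 | up2 | down2:
        a = "up" if gene in up1 else ("down" if gene in down1 else "none")
        b = "up" if gene in up2 else ("down" if gene in down2 else "none")
        counts[(a, b)] = counts.get((a, b), 0) + 1

    def n(a, b):
        return counts.get((a, b), 0)

    def j(side_a, side_b):
        inter = n(side_a, side_b)
        size_a = sum(n(side_a, x) for x in ("up", "down", "none"))
        size_b = sum(n(x, side_b) for x in ("up", "down", "none"))
        union = size_a + size_b - inter
        return inter / union if union else 0.0

    return (j("up", "up") + j("down", "down") - j("up", "down") - j("down", "up")) / 2.0


def slice_f_bruteforce(values, subgroup_labels, indicated_flags, target_subgroup):
    """LS-means slice F test via an explicit least-squares cell-means fit.

    Returns (F, df1, df2, p) for the indicated-vs-control contrast inside
    ``target_subgroup`` using the model-wide residual mean square.
    """
    y = np.asarray(values, dtype=float)
    cells = sorted(set(zip(subgroup_labels, indicated_flags)))
    cell_index = {cell: k for k, cell in enumerate(cells)}
    X = np.zeros((len(y), len(cells)))
    for i, cell in enumerate(zip(subgroup_labels, indicated_flags)):
        X[i, cell_index[cell]] = 1.0
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = len(y) - len(cells)
    mse = float(resid @ resid) / df_resid
    c = np.zeros(len(cells))
    c[cell_index[(target_subgroup, True)]] = 1.0
    c[cell_index[(target_subgroup, False)]] = -1.0
    xtx_inv = np.linalg.inv(X.T @ X)
    estimate = float(c @ beta)
    var = mse * float(c @ xtx_inv @ c)
    f = estimate**2 / var
    return f, 1, df_resid, float(sps.f.sf(f, 1, df_resid))


def bh_stepup(p_values):
    """Benjamini-Hochberg step-up q-values, applied literally."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, p[idx] * m / (rank_from_top + 1))
        q[idx] = running_min
    return q
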