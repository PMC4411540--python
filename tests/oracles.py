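"""Independent brute-force oracles used by the tests.

These deliberately avoid numpy vectorization and any code path shared with
the package: plain double loops over sites with per-pair distance calls.
"""

import math


def naive_wcn(sites, variant, gly_rho_term="duplicate"):
    """O(n^2) double-loop evaluation of any WCN variant."""
    A = [tuple(map(float, s.alpha_pos)) for s in sites.sites]
    R = [tuple(map(float, s.rho_pos)) for s in sites.sites]
    distinct = [s.has_distinct_rho for s in sites.sites]
    n = len(A)
    values = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j == i:
                continue
            if variant == "WCN_rho_alpharho":
                total += 1.0 / math.dist(R[i], A[j]) ** 2
                if gly_rho_term == "duplicate" or distinct[j]:
                    total += 1.0 / math.dist(R[i], R[j]) ** 2
            elif variant == "WCN_alpha_alpharho":
                total += 1.0 / math.dist(A[i], A[j]) ** 2
                if gly_rho_term == "duplicate" or distinct[j]:
                    total += 1.0 / math.dist(A[i], R[j]) ** 2
            elif variant == "WCN_alpha_alpha":
                total += 1.0 / math.dist(A[i], A[j]) ** 2
            elif variant == "WCN_rho_rho":
                total += 1.0 / math.dist(R[i], R[j]) ** 2
            else:
                raise ValueError(variant)
        values.append(total)
    return values


def two_model_r2_increment(y, z, x):
    """R^2(y ~ z + x) - R^2(y ~ z) via two explicit least-squares fits."""
    import numpy as np

    y = np.asarray(y, float)

    def fit_r2(design_cols):
        X = np.column_stack([np.ones(len(y))] + design_cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        return 1.0 - (resid @ resid) / ss_tot

    return fit_r2([np.asarray(z, float), np.asarray(x, float)]) - fit_r2(
        [np.asarray(z, float)]
    )
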