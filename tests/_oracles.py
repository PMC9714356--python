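"""Independent reference implementations used to validate the package's
numerics: exact-integer Hardy-Weinberg enumeration and closed-form OLS."""

from math import factorial

import numpy as np
from scipy import stats


def hwe_enumeration_oracle(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact-integer brute force: enumerate every heterozygote count
    compatible with the observed allele counts and sum the (conditional)
    probabilities of tables no more probable than the observed one."""
    n = n_hom_minor + n_het + n_hom_major
    rare = min(2 * n_hom_minor + n_het, 2 * n_hom_major + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (rare - h) // 2
        bb = n - aa - h
        weights[h] = (
            factorial(n) // (factorial(aa) * factorial(h) * factorial(bb))
        ) * 2 ** h
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / sum(weights.values())


def ols_normal_equations_oracle(y, g, a):
    """Closed-form OLS of y on (1, g, a): dosage coefficient, its SE, t and
    the two-sided p-value from the t distribution with n - 3 df."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), g, a])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - 3
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return beta[1], se, t, p
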