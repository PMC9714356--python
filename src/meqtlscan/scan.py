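"""The SNP x CpG association scan.

For every SNP-CpG pair, ordinary least squares of the methylation beta value
on (intercept, minor-allele dosage, age) within one sample stratum. The
effect of interest is the dosage coefficient: the change in methylation beta
per additional minor-allele copy. Significance is controlled per SNP:
Benjamini-Hochberg across that SNP's CpG family, discoveries at q < alpha.

Two fitting routes exist on purpose. ``fit_pair`` fits one pair through
statsmodels OLS; ``scan`` solves the normal equations for all CpGs of a SNP
in one vectorized pass. They agree to numerical precision and are tested
against each other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DataError, GenotypeMatrix, MethylationMatrix, SampleTable

N_PARAMS = 3  # intercept, dosage, age

# record status values; only STATUS_OK records enter the FDR family
STATUS_OK = "ok"
STATUS_LOW_N = "low_n"                    # fewer than 4 complete cases
STATUS_CONSTANT_DOSAGE = "constant_dosage"  # no genotype variation in stratum
STATUS_COLLINEAR = "collinear"            # dosage collinear with age
STATUS_ZERO_VARIANCE = "zero_variance"    # methylation constant

RESULT_COLUMNS = [
    "snp_id", "cpg_id", "stratum", "beta_hat", "se", "t_stat",
    "p_value", "q_value", "n_used", "status",
]


def attempted_pairs(n_snps: int, n_cpgs: int) -> int:
    """Number of SNP-CpG pairs a full scan attempts (degenerate fits
    included in the count, excluded from testing)."""
    if n_snps < 0 or n_cpgs < 0:
        raise ValueError("feature counts must be nonnegative")
    return int(n_snps) * int(n_cpgs)


def fit_pair(methylation, dosage, age) -> dict:
    """OLS of one CpG's methylation on one SNP's dosage with age covariate.

    Samples with a missing value in any of the three vectors are dropped
    pairwise. Returns a dict with beta_hat, se, t_stat, p_value, n_used and
    a status flag; non-'ok' records carry NaN statistics (except the
    zero-variance-response case, which is beta 0 / p 1 by convention) and
    are excluded from FDR downstream.
    """
    m = np.asarray(methylation, dtype=float).ravel()
    g = np.asarray(dosage, dtype=float).ravel()
    a = np.asarray(age, dtype=float).ravel()
    if not (m.size == g.size == a.size):
        raise DataError("methylation, dosage and age must be sample-aligned")

    keep = ~(np.isnan(m) | np.isnan(g) | np.isnan(a))
    n_used = int(keep.sum())
    base = dict(beta_hat=np.nan, se=np.nan, t_stat=np.nan, p_value=np.nan,
                n_used=n_used)
    if n_used < N_PARAMS + 1:
        return {**base, "status": STATUS_LOW_N}

    m, g, a = m[keep], g[keep], a[keep]
    if np.ptp(g) == 0.0:
        return {**base, "status": STATUS_CONSTANT_DOSAGE}
    X = np.column_stack([np.ones(n_used), g, a])
    if np.linalg.matrix_rank(X) < N_PARAMS:
        return {**base, "status": STATUS_COLLINEAR}
    if np.ptp(m) == 0.0:
        return {**base, "beta_hat": 0.0, "se": 0.0, "p_value": 1.0,
                "status": STATUS_ZERO_VARIANCE}

    fit = sm.OLS(m, X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if se == 0.0:  # perfect fit: effect real, p collapses to 0
        t = np.inf * np.sign(beta)
        p = 0.0
    else:
        t = float(fit.tvalues[1])
        p = float(fit.pvalues[1])
    return dict(beta_hat=beta, se=se, t_stat=t, p_value=p, n_used=n_used,
                status=STATUS_OK)


def _scan_one_snp(Y: np.ndarray, g: np.ndarray, a: np.ndarray) -> dict:
    """Vectorized OLS of every CpG (rows of Y) on one dosage vector.

    Y is CpGs x samples and must be fully observed; callers route CpGs with
    missing values through fit_pair instead.
    """
    n = g.size
    X = np.column_stack([np.ones(n), g, a])
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y.T)              # 3 x n_cpgs
    resid = Y.T - X @ B
    dof = n - N_PARAMS
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[1, 1])
    beta = B[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isinf(t), 0.0, p)

    # constant response: by convention beta 0 / p 1, flagged untestable
    zero_var = np.ptp(Y, axis=1) == 0.0
    beta = np.where(zero_var, 0.0, beta)
    se = np.where(zero_var, 0.0, se)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, 1.0, p)
    status = np.where(zero_var, STATUS_ZERO_VARIANCE, STATUS_OK)
    return dict(beta_hat=beta, se=se, t_stat=t, p_value=p, status=status)


def scan(
    methylation: MethylationMatrix,
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    stratum: str = "all",
    alpha: float = 0.05,
    fdr_scope: str = "per_snp",
) -> pd.DataFrame:
    """Fit every SNP-CpG pair in one stratum and attach FDR q-values.

    Returns a DataFrame with one row per attempted pair (n_snps * n_cpgs
    rows) in SNP-major order; see RESULT_COLUMNS. Degenerate pairs are
    flagged via ``status`` and carry q = NaN.
    """
    shared = methylation.sample_ids.intersection(genotypes.sample_ids)
    shared = shared.intersection(samples.sample_ids)
    if len(shared) == 0:
        raise DataError("no shared sample ids across methylation, genotypes "
                        "and sample table")
    ids = samples.group_ids(stratum)
    ids = ids[ids.isin(shared)]
    if len(ids) == 0:
        raise DataError(f"stratum {stratum!r} has no usable samples")

    Y_all = methylation.values.loc[:, ids].to_numpy(dtype=float)
    G = genotypes.codes.loc[:, ids].to_numpy(dtype=float)
    age = samples.table.loc[ids, "age"].to_numpy(dtype=float)
    cpg_ids = methylation.cpg_ids
    n_cpgs = len(cpg_ids)

    frames = []
    for si, snp_id in enumerate(genotypes.snp_ids):
        g = G[si]
        keep = ~np.isnan(g)
        n_used = int(keep.sum())
        out = {
            "beta_hat": np.full(n_cpgs, np.nan),
            "se": np.full(n_cpgs, np.nan),
            "t_stat": np.full(n_cpgs, np.nan),
            "p_value": np.full(n_cpgs, np.nan),
            "status": np.full(n_cpgs, STATUS_OK, dtype=object),
        }
        n_used_arr = np.full(n_cpgs, n_used)
        gk, ak, Yk = g[keep], age[keep], Y_all[:, keep]
        if n_used < N_PARAMS + 1:
            out["status"][:] = STATUS_LOW_N
        elif np.ptp(gk) == 0.0:
            out["status"][:] = STATUS_CONSTANT_DOSAGE
        elif np.linalg.matrix_rank(
            np.column_stack([np.ones(n_used), gk, ak])
        ) < N_PARAMS:
            out["status"][:] = STATUS_COLLINEAR
        else:
            full = ~np.isnan(Yk).any(axis=1)
            if full.any():
                res = _scan_one_snp(Yk[full], gk, ak)
                for key in out:
                    out[key][full] = res[key]
            # CpGs with missing methylation: pairwise complete-case fits
            for ci in np.flatnonzero(~full):
                res = fit_pair(Yk[ci], gk, ak)
                for key in out:
                    out[key][ci] = res[key]
                n_used_arr[ci] = res["n_used"]
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snp_id,
                    "cpg_id": cpg_ids,
                    "stratum": stratum,
                    **out,
                    "q_value": np.nan,
                    "n_used": n_used_arr,
                }
            )
        )

    records = pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
    return per_snp_fdr(records, alpha=alpha, scope=fdr_scope)


def per_snp_fdr(
    records: pd.DataFrame, alpha: float = 0.05, scope: str = "per_snp"
) -> pd.DataFrame:
    """Benjamini-Hochberg step-up within each SNP's family of testable CpGs.

    Records flagged non-'ok' are excluded from the family (they carry no
    test) and keep q = NaN. ``scope='global'`` pools all records into one
    family instead. Adds/overwrites ``q_value`` and ``significant``
    (q < alpha, strict).
    """
    if scope not in ("per_snp", "global"):
        raise ValueError(f"unknown fdr scope {scope!r}")
    out = records.copy()
    out["q_value"] = np.nan
    testable = out["status"] == STATUS_OK

    def _adjust(idx: pd.Index) -> None:
        p = out.loc[idx, "p_value"].to_numpy(dtype=float)
        if p.size:
            out.loc[idx, "q_value"] = multipletests(p, method="fdr_bh")[1]

    if scope == "global":
        _adjust(out.index[testable])
    else:
        for _, grp in out[testable].groupby("snp_id", sort=False):
            _adjust(grp.index)
    out["significant"] = (out["q_value"] < alpha).fillna(False)
    return out


def significant_records(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["significant"]].reset_index(drop=True)
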