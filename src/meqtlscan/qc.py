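"""SNP-level quality control: MAF, missing rate, and an exact test of
Hardy-Weinberg equilibrium.

A SNP passes when all three hold, with strict inequalities:
MAF > 0.01, missing rate < 0.01, HWE p > 0.001 (defaults; configurable).

The HWE test is the exact conditional test: conditioning on the observed
allele counts, the probability of each possible heterozygote count is
computed and the two-sided p-value sums the probabilities of all outcomes no
more probable than the observed one. This is exact at any sample size, which
matters for small SNP panels where the chi-square approximation is poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import QcThresholds
from .containers import GenotypeMatrix, SampleTable

# relative tolerance when comparing outcome probabilities for the two-sided
# rule; absorbs float rounding of genuinely tied tables
_TIE_RTOL = 1e-12


class UndefinedMafError(ValueError):
    """MAF requested for a SNP with no called genotypes."""


def compute_maf(codes: np.ndarray | pd.Series) -> float:
    """Folded minor-allele frequency from dosage codes (NaN = missing)."""
    x = np.asarray(codes, dtype=float).ravel()
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise UndefinedMafError("all genotype codes are missing; MAF undefined")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def hwe_exact_p(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one SNP's genotype counts.

    Conditional on allele counts, P(het = h) follows the distribution of
    heterozygote counts under random mating; the p-value sums P(h) over all
    h (same parity as the minor-allele count) with P(h) <= P(observed).
    Returns a value in (0, 1].
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")

    rare = 2 * n_hom_minor + n_het
    common = 2 * n_hom_major + n_het
    if rare > common:  # fold so 'rare' really is the rarer allele
        rare, common = common, rare
    if rare == 0:
        return 1.0

    # possible heterozygote counts share the parity of the rare-allele count
    h = np.arange(rare % 2, rare + 1, 2)
    n_aa = (rare - h) // 2
    n_bb = n - n_aa - h
    # log P(h) up to the shared normalizing constant:
    #   P(h) = n! 2^h / (n_aa! h! n_bb!) * (rare! common! / (2n)!)
    logp = (
        h * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(h + 1)
        - gammaln(n_bb + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    p_obs = probs[h == n_het][0]
    p = probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def genotype_counts(codes: np.ndarray | pd.Series) -> tuple[int, int, int]:
    """(n_hom_minor, n_het, n_hom_major) from dosage codes, ignoring NaN."""
    x = np.asarray(codes, dtype=float).ravel()
    obs = x[~np.isnan(x)]
    return int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())


@dataclass
class QcResult:
    report: pd.DataFrame          # snp_id-indexed QC metrics and verdicts
    genotypes: GenotypeMatrix     # passing SNPs only, original order


def filter_snps(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    samples: SampleTable | None = None,
    hwe_group: str = "all",
) -> QcResult:
    """Apply the three SNP filters and subset to passing SNPs.

    ``hwe_group`` restricts the HWE test to one sample group (e.g. controls,
    a common convention when cases may violate equilibrium at trait loci);
    MAF and missing rate always use all samples.
    """
    thresholds = thresholds or QcThresholds()
    hwe_codes = genotypes.codes
    if hwe_group != "all":
        if samples is None:
            raise ValueError("hwe_group requires a sample table")
        ids = samples.group_ids(hwe_group)
        hwe_codes = genotypes.codes.loc[:, genotypes.codes.columns.isin(ids)]

    rows = []
    for snp_id in genotypes.snp_ids:
        codes = genotypes.codes.loc[snp_id]
        maf = compute_maf(codes)
        missing = float(codes.isna().mean())
        hwe_p = hwe_exact_p(*genotype_counts(hwe_codes.loc[snp_id]))
        reasons = []
        if not maf > thresholds.maf_min:
            reasons.append("maf")
        if not missing < thresholds.missing_max:
            reasons.append("missing")
        if not hwe_p > thresholds.hwe_p_min:
            reasons.append("hwe")
        rows.append(
            {
                "snp_id": snp_id,
                "maf": maf,
                "missing_rate": missing,
                "hwe_p": hwe_p,
                "pass": not reasons,
                "fail_reasons": ",".join(reasons),
            }
        )
    report = pd.DataFrame(rows).set_index("snp_id")
    passing = report.index[report["pass"]]
    return QcResult(report=report, genotypes=genotypes.subset_snps(passing))
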