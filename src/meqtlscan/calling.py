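"""Genotype calling from the three-peaked SNP-probe beta signal.

On a methylation array the 65 SNP tracking probes report a beta-like signal
whose distribution over samples has up to three peaks — near 0, 0.5 and 1 —
corresponding to the two homozygote classes and the heterozygote. Calling is
1-D k-means (Lloyd) with centers anchored at 0.1 / 0.5 / 0.9, followed by
minor-allele orientation so codes count copies of the minor allele.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

LOW, MID, HIGH, MISSING = 0, 1, 2, -1
_INIT_CENTERS = np.array([0.1, 0.5, 0.9])
_TOL = 1e-6
_MAX_ITER = 100
MIN_CALLABLE = 10


class LowDataError(ValueError):
    """Too few non-missing probe values to call genotypes."""


def call_genotypes(
    probe_signal: np.ndarray | pd.Series, max_cluster_distance: float = 0.2
) -> np.ndarray:
    """Cluster one SNP's probe values into genotype classes.

    Returns an int array of cluster labels per sample: 0 (low peak),
    1 (mid), 2 (high), or -1 for missing — either a missing input value or a
    sample farther than ``max_cluster_distance`` from every cluster center.
    Empty clusters are legitimate (monomorphic or two-genotype SNPs).
    """
    x = np.asarray(probe_signal, dtype=float).ravel()
    obs = ~np.isnan(x)
    if obs.sum() < MIN_CALLABLE:
        raise LowDataError(
            f"need at least {MIN_CALLABLE} non-missing probe values, "
            f"got {int(obs.sum())}"
        )
    xo = x[obs]
    if (xo < 0).any() or (xo > 1).any():
        bad = xo[(xo < 0) | (xo > 1)][0]
        raise ValueError(f"probe signal value {bad!r} outside [0, 1]")

    centers = _INIT_CENTERS.copy()
    for _ in range(_MAX_ITER):
        assign = np.argmin(np.abs(xo[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for k in range(3):
            sel = assign == k
            if sel.any():  # empty clusters keep their center
                new[k] = xo[sel].mean()
        if np.max(np.abs(new - centers)) < _TOL:
            centers = new
            break
        centers = new

    assign = np.argmin(np.abs(xo[:, None] - centers[None, :]), axis=1)
    dist = np.abs(xo - centers[assign])
    assign[dist > max_cluster_distance] = MISSING

    labels = np.full(x.shape, MISSING, dtype=int)
    labels[obs] = assign
    return labels


def orient_and_encode(
    cluster_labels: np.ndarray, allele_names: tuple[str, str] = ("B", "A")
) -> tuple[np.ndarray, str]:
    """Convert cluster labels to minor-allele dosage codes.

    ``allele_names`` gives (low-homozygote allele, high-homozygote allele).
    The high cluster's allele count is 2*n_high + n_mid; whichever allele is
    rarer becomes the minor allele and its per-sample copy number is the
    code (minor homozygote -> 2, heterozygote -> 1, other homozygote -> 0).
    An exact 0.5/0.5 tie keeps the high-cluster allele as minor.

    Returns (codes with NaN for missing, minor allele name).
    """
    lab = np.asarray(cluster_labels)
    called = lab != MISSING
    n_mid = int((lab == MID).sum())
    n_high = int((lab == HIGH).sum())
    n_called = int(called.sum())

    codes = np.full(lab.shape, np.nan)
    if n_called == 0:
        return codes, allele_names[1]

    high_freq = (2 * n_high + n_mid) / (2 * n_called)
    if high_freq <= 0.5:  # tie keeps the high cluster as minor
        codes[called] = lab[called].astype(float)
        minor = allele_names[1]
    else:
        codes[called] = 2.0 - lab[called]
        minor = allele_names[0]
    return codes, minor


def call_matrix(
    probes: pd.DataFrame,
    max_cluster_distance: float = 0.2,
    snp_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Call and orient every SNP in a probe-signal matrix (SNPs x samples)."""
    codes = np.full(probes.shape, np.nan)
    minors = []
    for i, (_, row) in enumerate(probes.iterrows()):
        labels = call_genotypes(row.to_numpy(), max_cluster_distance)
        codes[i], minor = orient_and_encode(labels)
        minors.append(minor)

    code_df = pd.DataFrame(codes, index=probes.index, columns=probes.columns)
    meta = pd.DataFrame(index=probes.index.rename("snp_id"))
    if snp_meta is not None:
        meta["chrom"] = snp_meta["chrom"]
        meta["pos"] = snp_meta["pos"]
    else:
        meta["chrom"] = "NA"
        meta["pos"] = 0
    meta["minor_allele"] = minors
    meta["call_rate"] = code_df.notna().mean(axis=1).to_numpy()
    return GenotypeMatrix(codes=code_df, snp_meta=meta)
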