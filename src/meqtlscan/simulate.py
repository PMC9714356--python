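"""Synthetic genotype + methylation data with known planted truth.

The generator emulates the data structure of a case/control 450K methylation
study in which genotypes come from the array's own SNP probes:

* biallelic genotypes drawn under Hardy-Weinberg equilibrium, encoded as
  minor-allele dosage 0/1/2;
* a SNP-probe beta signal with three peaks at 0, 0.5 and 1 (dosage/2) plus
  Gaussian probe noise, clipped to [0, 1], with optional missing entries;
* CpG methylation beta values drawn from a Beta distribution moment-matched
  to a linear predictor: per-CpG baseline + planted per-allele dosage effects
  (optionally restricted to cases or controls) + a linear age term;
* case/control labels and uniformly distributed ages.

Every planted effect is recorded in a truth table so downstream stages can be
tested for parameter recovery without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import GenotypeMatrix, MethylationMatrix, SampleTable

_EPS = 1e-6
_ALLELES = np.array(["A", "C", "G", "T"])

# Bimodal mixture of Beta shapes used when no explicit baseline shape is
# given: most array CpGs sit near 0 or 1 with a smaller intermediate class.
_BASELINE_MIXTURE = (
    (0.4, (2.0, 18.0)),   # hypomethylated
    (0.4, (18.0, 2.0)),   # hypermethylated
    (0.2, (8.0, 8.0)),    # intermediate
)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    snp_probes: pd.DataFrame          # SNP-probe beta signal, NaN = masked
    genotype_truth: GenotypeMatrix    # generating dosages (no missingness)
    methylation: MethylationMatrix
    samples: SampleTable
    truth: pd.DataFrame               # snp_id, cpg_id, delta_per_allele, stratum


def _draw_baseline_shapes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG Beta shape parameters (a_j, b_j) for the baseline."""
    if cfg.baseline_beta_params is not None:
        a = np.full(cfg.n_cpgs, cfg.baseline_beta_params[0])
        b = np.full(cfg.n_cpgs, cfg.baseline_beta_params[1])
        return a, b
    probs = np.array([w for w, _ in _BASELINE_MIXTURE])
    comp = rng.choice(len(_BASELINE_MIXTURE), size=cfg.n_cpgs, p=probs)
    shapes = np.array([s for _, s in _BASELINE_MIXTURE])
    return shapes[comp, 0], shapes[comp, 1]


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one seeded dataset; identical config + seed gives identical
    output arrays.

    Raises
    ------
    ValueError
        If a planted effect pushes the expected (pre-clip) methylation beta
        outside [0, 1] for more than 1% of samples at its CpG.
    """
    rng = np.random.default_rng(cfg.seed)
    n, s, c = cfg.n_samples, cfg.n_snps, cfg.n_cpgs

    sample_ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id")
    snp_ids = pd.Index([f"snp_{i + 1:04d}" for i in range(s)], name="snp_id")
    cpg_ids = pd.Index([f"cg{i + 1:08d}" for i in range(c)], name="cpg_id")

    # --- sample metadata -------------------------------------------------
    is_case = rng.random(n) < cfg.case_fraction
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    samples = SampleTable(
        pd.DataFrame(
            {"group": np.where(is_case, "case", "control"), "age": age},
            index=sample_ids,
        )
    )

    # --- genotypes under HWE ---------------------------------------------
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=s)
    dosage = rng.binomial(2, freqs[:, None], size=(s, n)).astype(float)

    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(s)])
    snp_meta = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, size=s).astype(str),
            "pos": rng.integers(1, 200_000_000, size=s),
            "minor_allele": _ALLELES[allele_idx[:, 0]],
            "call_rate": np.ones(s),
        },
        index=snp_ids,
    )
    genotype_truth = GenotypeMatrix(
        codes=pd.DataFrame(dosage, index=snp_ids, columns=sample_ids),
        snp_meta=snp_meta,
    )

    # --- SNP-probe signal: peaks at dosage/2 plus probe noise -------------
    signal = dosage / 2.0 + rng.normal(0.0, cfg.probe_noise_sd, size=(s, n))
    np.clip(signal, 0.0, 1.0, out=signal)
    if cfg.missing_probe_rate > 0.0:
        mask = rng.random((s, n)) < cfg.missing_probe_rate
        signal[mask] = np.nan
    snp_probes = pd.DataFrame(signal, index=snp_ids, columns=sample_ids)

    # --- methylation: Beta noise around a linear predictor ----------------
    shape_a, shape_b = _draw_baseline_shapes(cfg, rng)
    baseline = rng.beta(shape_a, shape_b)          # per-CpG baseline level
    precision = shape_a + shape_b                  # per-CpG Beta precision

    age_std = (age - age.mean()) / (age.std() or 1.0)
    age_slope = rng.normal(0.0, cfg.age_effect_sd, size=c)
    mu = baseline[:, None] + age_slope[:, None] * age_std[None, :]

    case_ind = is_case.astype(float)
    truth_rows = []
    for eff in cfg.effect_table:
        if eff.stratum == "all":
            ind = 1.0
        elif eff.stratum == "case_only":
            ind = case_ind
        else:
            ind = 1.0 - case_ind
        mu[eff.cpg_index] += eff.delta_per_allele * dosage[eff.snp_index] * ind
        in_range = (mu[eff.cpg_index] >= 0.0) & (mu[eff.cpg_index] <= 1.0)
        if in_range.mean() < 0.99:
            raise ValueError(
                "effect_table: planted effect at "
                f"({eff.snp_index}, {eff.cpg_index}) drives the expected beta "
                f"outside [0, 1] for {(~in_range).mean():.1%} of samples"
            )
        truth_rows.append(
            (snp_ids[eff.snp_index], cpg_ids[eff.cpg_index],
             eff.delta_per_allele, eff.stratum)
        )

    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    # moment match: mean mu, precision nu -> Beta(mu*nu, (1-mu)*nu)
    nu = precision[:, None]
    beta_vals = rng.beta(mu * nu, (1.0 - mu) * nu)

    cpg_meta = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, size=c).astype(str),
            "pos": rng.integers(1, 200_000_000, size=c),
        },
        index=cpg_ids,
    )
    methylation = MethylationMatrix(
        values=pd.DataFrame(beta_vals, index=cpg_ids, columns=sample_ids),
        cpg_meta=cpg_meta,
    )

    truth = pd.DataFrame(
        truth_rows, columns=["snp_id", "cpg_id", "delta_per_allele", "stratum"]
    )
    return SimulatedDataset(
        snp_probes=snp_probes,
        genotype_truth=genotype_truth,
        methylation=methylation,
        samples=samples,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all simulated tables as TSV/BED into ``out_dir``.

    Returns a mapping of logical names to the written paths.
    """
    from . import io as mio  # local import: io depends on containers only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": out / "probes.tsv",
        "genotypes_truth": out / "genotypes_truth.tsv",
        "methylation": out / "methylation.tsv",
        "samples": out / "samples.tsv",
        "snp_bed": out / "snps.bed",
        "cpg_bed": out / "cpgs.bed",
        "truth": out / "truth.tsv",
    }
    mio.write_matrix(ds.snp_probes, paths["probes"])
    mio.write_matrix(ds.genotype_truth.codes, paths["genotypes_truth"], genotype=True)
    mio.write_matrix(ds.methylation.values, paths["methylation"])
    mio.write_sample_table(ds.samples, paths["samples"])
    mio.write_bed(ds.genotype_truth.snp_meta, paths["snp_bed"])
    mio.write_bed(ds.methylation.cpg_meta, paths["cpg_bed"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
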