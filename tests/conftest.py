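import pytest

from meqtlscan.config import PlantedEffect, SimulationConfig
from meqtlscan.simulate import simulate_dataset


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    """Moderate dataset with one shared and one case-only planted effect.

    Symmetric intermediate-methylation baseline so effect sizes translate
    directly into detectable shifts.
    """
    return SimulationConfig(
        n_samples=400,
        n_snps=6,
        n_cpgs=40,
        allele_freq_range=(0.2, 0.4),
        probe_noise_sd=0.03,
        baseline_beta_params=(5.0, 5.0),
        effect_table=[
            PlantedEffect(snp_index=0, cpg_index=0, delta_per_allele=-0.06),
            PlantedEffect(
                snp_index=1, cpg_index=1, delta_per_allele=0.06,
                stratum="case_only",
            ),
        ],
        seed=20260926,
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return simulate_dataset(planted_config)
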