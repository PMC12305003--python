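import numpy as np
import pytest

from epievolve.methylation_stats import DesignTable, SampleInfo
from epievolve.synthetic_data import SimulationConfig, simulate_experiment
from epievolve.types import MethylationSite


@pytest.fixture(scope="session")
def small_experiment():
    """One small simulated experiment shared by read-only tests."""
    return simulate_experiment(SimulationConfig(seed=42, n_contigs=4))


@pytest.fixture
def design_4v4():
    """4 vs 4 F25 replicates (OWA vs AM) plus founders."""
    samples = {}
    for i in range(1, 5):
        samples[f"OWA_r{i}"] = SampleInfo("OWA", "F25", i)
        samples[f"AM_r{i}"] = SampleInfo("AM", "F25", i)
        samples[f"F0_r{i}"] = SampleInfo("AM", "F0", i)
    return DesignTable(samples)


def make_beta_binomial_sites(rng, design, mu_by_line, phi, coverage, n_sites,
                             prefix="s"):
    """Sites with group means given per line; F0 samples use the AM mean."""
    conc = (1.0 - phi) / phi
    sites = []
    for j in range(n_sites):
        site = MethylationSite(f"{prefix}{j}", "c1", j, {})
        for sid, info in design:
            mu = mu_by_line[info.line]
            if callable(mu):
                mu = mu()
            n = int(rng.poisson(coverage)) + 1
            if phi > 0:
                p = rng.beta(mu * conc, (1.0 - mu) * conc)
            else:
                p = mu
            site.counts[sid] = (int(rng.binomial(n, p)), n)
        sites.append(site)
    return sites


@pytest.fixture
def bb_site_factory():
    return make_beta_binomial_sites
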