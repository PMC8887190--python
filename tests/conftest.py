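"""Shared fixtures: small seeded simulation configs and their products."""

import pytest

from cthbench import (
    SimConfig,
    build_reference,
    estimate_fractions_constrained,
    generate_purified_profiles,
    make_phenotype,
    mix_profiles,
    sample_fractions,
    spike_dmcs,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config: fast, but with every moving part of the default."""
    return SimConfig(
        n_cpgs=3000, n_samples=60, n_cases=30, n_dmcs=100,
        markers_per_type=20, seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One full small simulation: profiles, pheno, truth, fractions, bulk."""
    cfg = small_config
    profiles = generate_purified_profiles(cfg)
    pheno = make_phenotype(cfg)
    spiked, truth = spike_dmcs(profiles, pheno, cfg)
    fractions = sample_fractions(cfg.n_samples, cfg)
    fractions.index = spiked.sample_ids
    bulk = mix_profiles(spiked, fractions, cfg.meas_sd,
                        cfg.rng("mix_profiles"))
    return {
        "config": cfg, "profiles": profiles, "pheno": pheno,
        "spiked": spiked, "truth": truth, "fractions": fractions,
        "bulk": bulk,
    }


@pytest.fixture(scope="session")
def small_reference(small_sim):
    return build_reference(small_sim["spiked"],
                           small_sim["config"].markers_per_type,
                           small_sim["config"].marker_delta)


@pytest.fixture(scope="session")
def small_estimate(small_sim, small_reference):
    return estimate_fractions_constrained(small_sim["bulk"], small_reference)
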