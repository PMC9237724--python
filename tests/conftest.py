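"""Shared fixtures: simulated panels and loadings reused across test modules.

The expensive scenarios are session-scoped so each is simulated once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import sumdeconv as sd


@dataclass
class SimBundle:
    """A simulated panel with its loadings and configuration."""

    config: sd.SimConfig
    sim: sd.PanelSim
    loadings: sd.LoadingsTable


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    """Fast three-population scenario for unit-level checks."""
    config = sd.SimConfig(
        n_variants=10_000,
        n_pops=3,
        fst=(0.05, 0.05, 0.1),
        n_ref_per_pop=100,
        n_cohort=10_000,
        alpha_true=(0.5, 0.3, 0.2),
        n_pcs=4,
        seed=42,
    )
    sim = sd.simulate_panel(config)
    loadings = sd.build_loadings(sim.genotypes, sim.panel, config.n_pcs, seed=config.seed)
    return SimBundle(config=config, sim=sim, loadings=loadings)


@pytest.fixture(scope="session")
def headline_bundle() -> SimBundle:
    """The reference noisy-recovery scenario: four populations, two of them
    closely related, 100,000 SNPs, 200 reference individuals per group."""
    config = sd.SimConfig(seed=1)  # defaults hold the scenario parameters
    sim = sd.simulate_panel(config)
    loadings = sd.build_loadings(sim.genotypes, sim.panel, config.n_pcs, seed=config.seed)
    return SimBundle(config=config, sim=sim, loadings=loadings)


@pytest.fixture(scope="session")
def small_files(small_bundle, tmp_path_factory):
    """The small scenario written out in the file dialects the CLI reads."""
    root = tmp_path_factory.mktemp("small_files")
    cohort = sd.simulate_cohort_sumstats(
        small_bundle.sim.panel,
        small_bundle.sim.panel.freqs,
        small_bundle.config.alpha_true,
        n_cohort=None,
        seed=7,
    )
    paths = {
        "sumstats": root / "sumstats.tsv",
        "panel": root / "panel.tsv",
        "loadings": root / "loadings.tsv",
        "loadings_unit": root / "loadings_unit.tsv",
    }
    sd.write_freq_table(cohort, paths["sumstats"])
    sd.write_panel(small_bundle.sim.panel, paths["panel"])
    sd.write_loadings(small_bundle.loadings, paths["loadings"])
    # same loadings with unit correction factors, for exactness identities
    unit = sd.LoadingsTable(
        chrom=small_bundle.loadings.chrom,
        pos=small_bundle.loadings.pos,
        a1=small_bundle.loadings.a1,
        a2=small_bundle.loadings.a2,
        loadings=small_bundle.loadings.loadings,
        correction=np.ones(small_bundle.loadings.n_pcs),
        center=small_bundle.loadings.center,
    )
    sd.write_loadings(unit, paths["loadings_unit"])
    return paths
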