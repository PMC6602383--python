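"""Shared fixtures: small synthetic cohorts built once per session."""

import numpy as np
import pytest

from methcortex import synthdata as sd


@pytest.fixture(scope="session")
def small_manifest():
    design = sd.SyntheticDesign(
        n_probes=1000, n_chromosomes=4, probe_spacing_bp=500, seed=11
    )
    return design, sd.generate_manifest(design)


@pytest.fixture(scope="session")
def cortex_cohort():
    """Two-region case/control cohort with spiked DMPs and DMRs."""
    rng = np.random.default_rng(42)
    design = sd.SyntheticDesign(
        n_probes=2000,
        n_chromosomes=4,
        probe_spacing_bp=150,
        n_donors_per_group={"CTL": 15, "iASD": 15},
        regions=("PFC", "TC"),
        noise_sd=0.03,
        donor_sd=0.02,
        seed=42,
    )
    manifest = sd.generate_manifest(design)
    design = design.with_(
        spiked_dmps=sd.plant_dmps(manifest, 30, (0.05, 0.10), diagnoses=("iASD",), rng=rng),
        spiked_dmrs=sd.plant_dmrs(manifest, 2, 5, 0.08, rng=rng),
    )
    beta, (m, u), pheno, truth = sd.generate_cohort(design, manifest)
    return design, manifest, beta, (m, u), pheno, truth


@pytest.fixture(scope="session")
def full_cohort():
    """Three regions, three groups, composition + clock + batch effects."""
    rng = np.random.default_rng(7)
    design = sd.SyntheticDesign(
        n_probes=3000,
        n_chromosomes=6,
        probe_spacing_bp=800,
        n_donors_per_group={"CTL": 12, "iASD": 12, "dup15q": 4},
        regions=("PFC", "TC", "CB"),
        noise_sd=0.03,
        donor_sd=0.02,
        batch_effects={"bankB": 0.02, "bankC": -0.015},
        seed=7,
    )
    manifest = sd.generate_manifest(design)
    design = design.with_(
        cell_ref=sd.make_cell_reference(manifest, rng=rng),
        clock=sd.make_synthetic_clock(manifest, rng=rng),
        spiked_dmps=sd.plant_dmps(manifest, 20, (0.06, 0.10), rng=rng),
    )
    beta, (m, u), pheno, truth = sd.generate_cohort(design, manifest)
    return design, manifest, beta, (m, u), pheno, truth
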