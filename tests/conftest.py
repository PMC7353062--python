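"""Shared fixtures: genome scaffolding and simulated cohorts.

Expensive simulated objects (control cohorts, the bin panel) are
session-scoped and reused across test modules; everything is seeded.
"""

import warnings

import pytest

import plasmacnv as pc
from plasmacnv.genome_model import Chromosome, GenomeBuild
from plasmacnv.mfastseq import build_reference


@pytest.fixture(scope="session")
def build():
    return pc.default_build()


@pytest.fixture(scope="session")
def arms(build):
    return pc.make_arms(build)


@pytest.fixture(scope="session")
def bins(build):
    return pc.make_bins(build)


@pytest.fixture(scope="session")
def toy_build():
    return GenomeBuild(
        "toy",
        (
            Chromosome("c1", 2_500_000, 1_200_000),
            Chromosome("c2", 1_000_000, 400_000),
        ),
    )


@pytest.fixture(scope="session")
def fgfr1(build):
    return pc.load_gene_annotations()["FGFR1"]


@pytest.fixture(scope="session")
def arm_controls(arms):
    """35 tumor-free arm-count profiles at the arm-stage default depth."""
    cfg = pc.SimulationConfig(total_reads=100_000, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pc.simulate_control_cohort(35, cfg, arms, kind="arm")


@pytest.fixture(scope="session")
def arm_reference(arm_controls):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference(arm_controls)


@pytest.fixture(scope="session")
def bin_panel(bins):
    """10 tumor-free bin-count profiles at the sWGS default depth."""
    return pc.simulate_control_cohort(
        10, pc.SimulationConfig(seed=11), bins, kind="bin"
    )


@pytest.fixture(scope="session")
def noise_free_control(bins):
    return pc.simulate_bin_counts(
        pc.TumorGenotype(), pc.SimulationConfig(noise=False, seed=1), bins
    )
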