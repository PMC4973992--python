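import numpy as np
import pytest

from sigsel.design import StudyDesign
from sigsel.genotypes import GenotypeMatrix, call_genotypes
from sigsel.simulate import SimConfig, simulate_experiment


@pytest.fixture
def balanced_design():
    """2 lines x 2 replicates x 2 samples."""
    return StudyDesign(
        samples=tuple(f"s{i}" for i in range(8)),
        line=np.repeat([0, 1], 4),
        replicate=np.tile(np.repeat([0, 1], 2), 2),
    )


@pytest.fixture
def study_design_40():
    """The paper-shaped design: 2 lines x 2 replicates x 10 samples."""
    return StudyDesign(
        samples=tuple(f"s{i}" for i in range(40)),
        line=np.repeat([0, 1], 20),
        replicate=np.tile(np.repeat([0, 1], 10), 2),
    )


def small_genotypes(design, n_loci=20, seed=0, chrom="chr1"):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(design.n_samples, n_loci)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 10 * n_loci), size=n_loci, replace=False))
    return GenotypeMatrix(
        dosage, [chrom] * n_loci, pos, design.samples, design=design
    )


@pytest.fixture
def random_genotypes(study_design_40):
    return small_genotypes(study_design_40, n_loci=30, seed=11)


@pytest.fixture(scope="session")
def selected_experiment():
    """A selection experiment reused by several suites (seeded, small)."""
    cfg = SimConfig(
        n_chromosomes=1,
        loci_per_chromosome=150,
        n_causal_loci=2,
        heritability=0.6,
        n_generations_selected=20,
        n_generations_total=25,
        families_per_line=8,
        seed=42,
    )
    experiment, reads = simulate_experiment(cfg)
    return experiment, reads


@pytest.fixture(scope="session")
def selected_genotypes(selected_experiment):
    experiment, reads = selected_experiment
    return call_genotypes(reads, design=experiment.design)
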