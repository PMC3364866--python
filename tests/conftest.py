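import numpy as np
import pytest

from suprapop.genotypes import MISSING, GenotypeMatrix
from suprapop.synth import PanelConfig, SpeciesRecipe


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """Three species, four loci, hand-checkable genotypes."""
    genos = np.array(
        [
            # l1 l2 l3 l4
            [0, 1, 2, MISSING],
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [2, 2, MISSING, 0],
            [2, 2, 2, 0],
            [0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(6)],
        group_labels=["A", "A", "A", "B", "B", "C"],
        locus_ids=["l1", "l2", "l3", "l4"],
        genotypes=genos,
        localities=["x"] * 6,
    )


def tiny_panel_config(seed: int = 0, **overrides) -> PanelConfig:
    """A fast, down-scaled panel recipe for repeated-seed trend tests."""
    species = (
        SpeciesRecipe("focal", 800, 0, 0.0, 40, 0.04),
        SpeciesRecipe("near", 100, 300, 0.002, 10, 0.15),
        SpeciesRecipe("far", 100, 600, 0.0, 10, 0.22),
    )
    defaults = dict(
        panel_size=80,
        n_candidate_loci=400,
        focal_species="focal",
        ascertainment_sample_size=15,
        species=species,
        n_hybrids=1,
        hybrid_parents=("focal", "near"),
        seed=seed,
    )
    defaults.update(overrides)
    return PanelConfig(**defaults)
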