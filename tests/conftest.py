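import pytest

import scisote as sc
from scisote.simulate import truth_alignments_in_memory


@pytest.fixture(scope="session")
def toy_reference():
    return sc.build_toy_reference(1, n_chromosomes=1, n_genes=6, n_te_loci=20)


@pytest.fixture(scope="session")
def small_design(toy_reference):
    return sc.default_design(
        toy_reference,
        seed=2,
        cells_per_stage=3,
        stages=("A", "B"),
        n_chimera_pairs=2,
        chimera_mean=1.0,
        truncation_p3=0.2,
        truncation_p5=0.1,
    )


@pytest.fixture(scope="session")
def small_simulation(toy_reference, small_design):
    reads, truth, segments = sc.simulate_molecules(toy_reference, small_design)
    return reads, truth, segments


@pytest.fixture(scope="session")
def pipeline_result(toy_reference, small_design, small_simulation):
    reads, truth, segments = small_simulation
    return sc.run_pipeline(
        toy_reference,
        reads,
        truth_alignments_in_memory(segments),
        set(small_design.whitelist),
        small_design.cell_stage,
        classify_orfs_per_molecule=True,
    )
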