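import numpy as np
import pytest

from ribopause import occupancy, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded genome + footprint simulation with planted stalls."""
    config = simulate.SimConfig(
        seed=7,
        n_genes=60,
        depth=100_000,
        codon_length_range=(60, 150),
        stall_specs=[simulate.StallSpec(n_sites=20)],
    )
    genome = simulate.generate_genome(config)
    sim = simulate.simulate_footprints(genome, emit_reads=True)
    return genome, sim


def make_matrix(gene_vectors, sample_id="s"):
    """PSiteCountMatrix from {gene: CDS count vector}; flanks zero-padded."""
    counts = {}
    for gene, cds in gene_vectors.items():
        cds = np.asarray(cds, dtype=np.int64)
        vec = np.zeros(occupancy.window_length(len(cds)), dtype=np.int64)
        vec[occupancy.cds_slice(len(cds))] = cds
        counts[gene] = vec
    return occupancy.PSiteCountMatrix(sample_id=sample_id, counts=counts)
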