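"""Determinism, construction invariants and statistical structure of the
synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ribopause import annotation, simulate
from ribopause.occupancy import N_UPSTREAM, cds_slice
from ribopause.simulate import (
    ConfigurationError,
    ScreenConfig,
    SimConfig,
    SpikeConfig,
    StallSpec,
    generate_genome,
    simulate_footprints,
    simulate_screen,
    simulate_spikein,
)


class TestGenomeGeneration:
    def test_fixed_seed_gives_identical_files(self, tmp_path):
        config = SimConfig(seed=7, n_genes=40, stall_specs=[StallSpec(n_sites=10)])
        outs = []
        for run in ("a", "b"):
            genome = generate_genome(config)
            paths = annotation.write_gene_models(
                genome.models, genome.chromosomes, tmp_path / run
            )
            outs.append(
                {k: p.read_bytes() for k, p in paths.items()}
            )
        assert outs[0] == outs[1]

    def test_generated_cds_have_no_internal_stops(self):
        genome = generate_genome(SimConfig(seed=11, n_genes=50, stall_specs=[]))
        for m in genome.models.values():
            assert m.cds_sequence.startswith("ATG")
            assert m.protein.endswith("*")
            assert "*" not in m.protein[:-1]
            assert len(m.cds_sequence) % 3 == 0

    def test_stall_residues_follow_spec_weights(self):
        spec = StallSpec(
            n_sites=30, p_site_residues={"K": 1.0}, a_site_residues={"G": 1.0}
        )
        genome = generate_genome(SimConfig(seed=2, n_genes=40, stall_specs=[spec]))
        for row in genome.truth.stall_sites.itertuples():
            protein = genome.models[row.gene_id].protein
            assert protein[row.codon_index - 1] == "K"
            assert protein[row.codon_index] == "G"

    def test_stalls_fall_within_testable_body(self):
        genome = generate_genome(
            SimConfig(seed=3, n_genes=50, stall_specs=[StallSpec(n_sites=50)])
        )
        for row in genome.truth.stall_sites.itertuples():
            n = genome.models[row.gene_id].n_codons
            assert 21 <= row.codon_index <= n - 20

    def test_round_robin_chromosome_assignment(self):
        genome = generate_genome(
            SimConfig(seed=4, n_genes=16, n_chromosomes=4, stall_specs=[])
        )
        chroms = [m.chromosome for m in genome.models.values()]
        assert chroms[:5] == ["chr01", "chr02", "chr03", "chr04", "chr01"]

    def test_too_short_length_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(codon_length_range=(30, 100))


class TestFootprints:
    def test_fixed_seed_gives_identical_matrices(self):
        config = SimConfig(seed=5, n_genes=30, depth=50_000, stall_specs=[])
        genome = generate_genome(config)
        a = simulate_footprints(genome)
        b = simulate_footprints(genome)
        for sample in a.matrices:
            for gene in a.matrices[sample].counts:
                np.testing.assert_array_equal(
                    a.matrices[sample].counts[gene], b.matrices[sample].counts[gene]
                )

    def test_depth_is_conserved_exactly(self):
        config = SimConfig(seed=6, n_genes=30, depth=80_000, stall_specs=[])
        sim = simulate_footprints(generate_genome(config))
        for m in sim.matrices.values():
            assert m.total() == 80_000

    def test_infinite_dispersion_gives_uniform_codon_counts(self):
        # dispersion -> inf, no stalls, equal expression: within-gene counts
        # should pass a chi-square uniformity test for >= 95% of genes
        config = SimConfig(
            seed=8,
            n_genes=100,
            depth=2_000_000,
            dispersion=np.inf,
            expression_log2_sd=0.0,
            codon_length_range=(100, 200),
            stall_specs=[],
            utr_weight=0.0,
        )
        sim = simulate_footprints(generate_genome(config))
        m = sim.matrices["euploid_rep1"]
        rejected = 0
        for gene in m.counts:
            cds = m.cds_counts(gene)
            p = sps.chisquare(cds).pvalue
            rejected += p < 0.01
        assert rejected / len(m.counts) <= 0.05

    def test_dosage_fold_reflected_in_median_gene_ratio(self):
        config = SimConfig(
            seed=9,
            n_genes=120,
            depth=1_000_000,
            n_chromosomes=6,
            duplicated_chromosome="chr02",
            dosage_fold=2.0,
            stall_specs=[],
        )
        genome = generate_genome(config)
        sim = simulate_footprints(genome)
        e = sim.matrices["euploid_rep1"]
        a = sim.matrices["aneuploid_rep1"]
        ratios = {}
        for gene, model in genome.models.items():
            ce, ca = e.counts[gene].sum(), a.counts[gene].sum()
            ratios.setdefault(model.chromosome, []).append(
                (ca / a.total()) / (ce / e.total())
            )
        med = {c: np.median(v) for c, v in ratios.items()}
        # proportion ratios are depressed by the extra duplicated mass, but
        # the duplicated/unaffected contrast must equal the dosage fold
        assert med["chr02"] / med["chr01"] == pytest.approx(2.0, rel=0.05)
        assert med["chr03"] / med["chr01"] == pytest.approx(1.0, rel=0.05)

    def test_read_starts_sit_12nt_upstream_of_true_psite(self, small_sim):
        genome, sim = small_sim
        reads = sim.read_starts
        models = genome.models
        for row in reads.sample(500, random_state=0).itertuples():
            m = models[row.true_gene]
            codon_offset = 3 * (row.true_ext - N_UPSTREAM)
            if m.strand == "+":
                assert row.pos == (m.cds_start - 1) + codon_offset - 12
            else:
                assert row.pos == (m.cds_end - 1) - codon_offset + 12


class TestSpikein:
    def test_zero_noise_factors_are_exact(self):
        config = SpikeConfig(
            noise_cv=0.0,
            n_aneuploids=0,
            timepoints=("log",),
            n_replicates=2,
            true_scale_factors=[1.0, 0.5],
        )
        sim = simulate_spikein(config, seed=1)
        spikes = sim.counts.loc[sim.spike_genes]
        s1, s2 = spikes.columns[:2]
        np.testing.assert_allclose(spikes[s2], 0.5 * spikes[s1])

    def test_reference_factor_must_be_one(self):
        config = SpikeConfig(
            n_aneuploids=0,
            timepoints=("log",),
            n_replicates=2,
            true_scale_factors=[2.0, 1.0],
        )
        with pytest.raises(ConfigurationError):
            simulate_spikein(config, seed=1)

    def test_defect_genes_recorded_and_subset_of_repressed(self):
        sim = simulate_spikein(SpikeConfig(), seed=2)
        truth = sim.truth
        assert len(truth.silencing_defect_genes) == 100
        assert set(truth.silencing_defect_genes) <= set(truth.repressed_genes)
        assert not set(truth.silencing_defect_genes) & set(sim.spike_genes)

    def test_determinism(self):
        a = simulate_spikein(SpikeConfig(), seed=3)
        b = simulate_spikein(SpikeConfig(), seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestScreen:
    def test_determinism(self):
        a = simulate_screen(ScreenConfig(n_genes=500), seed=4)
        b = simulate_screen(ScreenConfig(n_genes=500), seed=4)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_hit_classes_perturb_correct_timepoints(self):
        config = ScreenConfig(n_genes=400, nb_dispersion=0.0, depth=4_000_000)
        sim = simulate_screen(config, seed=5)
        counts = sim.counts
        hits = sim.truth.screen_hits.set_index("gene_id")["class"]

        def mean_ratio(gene, tp):
            a = counts.loc[gene, [f"aneuploid_{tp}_rep{r}" for r in (1, 2, 3)]].mean()
            p = counts.loc[gene, [f"aneuploid_pool_rep{r}" for r in (1, 2, 3)]].mean()
            return a / p

        for gene, cls in hits.items():
            if cls == "early_benefit":
                assert mean_ratio(gene, "d1") > 4
                assert mean_ratio(gene, "d28") > 4
            else:
                assert mean_ratio(gene, "d1") < 2
                assert mean_ratio(gene, "d28") > 4

    def test_planted_hits_disjoint(self):
        sim = simulate_screen(ScreenConfig(n_genes=300), seed=6)
        hits = sim.truth.screen_hits
        assert hits["gene_id"].is_unique
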