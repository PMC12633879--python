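"""Synthetic data with the statistical structure the analyses assume.

Four generators, all deterministic under a fixed seed:

* ``generate_genome`` — intronless yeast-like gene models on a configurable
  number of chromosomes, with stall sites planted at chosen P-/A-site
  residues (lysine/asparagine and glycine/glutamate by default, the residue
  classes associated with ribosome stalling).
* ``simulate_footprints`` — per-codon P-site counts for euploid and
  aneuploid replicate samples. Each gene carries a Dirichlet-drawn codon
  profile shared by all samples (the profile is a property of the gene);
  condition effects act only at planted stall codons, whose profile weight
  is multiplied by the stall fold in the affected condition. Gene-level
  read mass follows lognormal expression times length, with a dosage
  multiplier on the duplicated chromosome in aneuploid samples. An optional
  read-start emitter places 5' ends exactly 12 nt upstream of the true
  P site for testing the offset logic.
* ``simulate_spikein`` — RNA counts for a euploid plus several aneuploid
  strains across timepoints, with foreign spike-in genes scaled by known
  per-sample factors and a planted "silencing defect" gene set that fails
  to shut off in the aneuploids.
* ``simulate_screen`` — negative-binomial barcode counts for a pooled
  fitness screen (pool / day-1 / day-28, euploid vs aneuploid, triplicate)
  with planted early-benefit and lifespan-specific hit genes.

Ground truth for every planted perturbation is returned in a
:class:`TruthRecord` so downstream callers can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .annotation import GeneModel, translate
from .occupancy import (
    BODY_TRIM,
    MIN_CODONS,
    N_UPSTREAM,
    PSiteCountMatrix,
    window_length,
)

EUPLOID = "euploid"
ANEUPLOID = "aneuploid"

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
#: residue -> tuple of synonymous codons (standard code)
CODONS_BY_RESIDUE: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_RESIDUE.setdefault(_aa, tuple())
    CODONS_BY_RESIDUE[_aa] += (_codon,)
CODONS_BY_RESIDUE["*"] = STOP_CODONS


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StallSpec:
    """Planted ribosome-stall sites.

    ``fold`` multiplies the stall codon's occupancy weight in the affected
    condition. P-site (position 0) and A-site (position +1) residues are
    drawn from the given weight maps; the defaults reproduce the residue
    classes enriched at stall sites (K/N at the P site, G/E at the A site).
    ``placement_alpha/beta`` parameterise a Beta distribution over relative
    position within the gene body; (1, 1) is uniform, alpha < beta skews
    stalls toward the 5' end.
    """

    n_sites: int = 200
    fold: float = 8.0
    affected_condition: str = ANEUPLOID
    p_site_residues: Mapping[str, float] = field(
        default_factory=lambda: {"K": 0.5, "N": 0.5}
    )
    a_site_residues: Mapping[str, float] = field(
        default_factory=lambda: {"G": 0.5, "E": 0.5}
    )
    placement_alpha: float = 1.0
    placement_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ConfigurationError("stall fold must exceed 1")
        if self.affected_condition not in (EUPLOID, ANEUPLOID):
            raise ConfigurationError("affected_condition must be euploid|aneuploid")


@dataclass(frozen=True)
class SpikeConfig:
    """Spike-in RNA-seq simulation.

    Spike counts in the reference sample equal their base abundances; every
    other sample's spikes are base x scale factor x lognormal noise of the
    given coefficient of variation, so the reference factor is exactly 1.
    Experimental genes: a repressed set shuts off at quiescent timepoints in
    every strain, except the planted silencing-defect subset which stays
    high in the aneuploids only.
    """

    n_spike_genes: int = 50
    true_scale_factors: Sequence[float] | Mapping[str, float] | None = None
    noise_cv: float = 0.1
    n_genes: int = 2000
    n_repressed_genes: int = 500
    n_defect_genes: int = 100
    n_aneuploids: int = 4
    timepoints: Sequence[str] = ("log", "d1")
    n_replicates: int = 2
    repression_log2: float = -5.0  # euploid quiescent silencing
    defect_log2: float = 4.0  # how far defect genes stay above euploid
    biological_cv: float = 0.2
    spike_log2_mean: float = 8.0
    spike_log2_sd: float = 1.0
    gene_log2_mean: float = 7.0
    gene_log2_sd: float = 1.5


@dataclass(frozen=True)
class ScreenConfig:
    """Pooled barcode screen: pool/d1/d28, euploid vs aneuploid, triplicate."""

    n_genes: int = 5000
    n_early_hits: int = 10  # enriched at d1 and d28 in the aneuploid
    n_late_hits: int = 10  # enriched at d28 only
    effect_log2: float = 3.0
    n_replicates: int = 3
    timepoints: Sequence[str] = ("pool", "d1", "d28")
    strains: Sequence[str] = (EUPLOID, ANEUPLOID)
    nb_dispersion: float = 0.1
    depth: int = 2_000_000
    abundance_log2_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Master configuration for the ribosome-profiling simulation."""

    seed: int = 0
    n_genes: int = 300
    codon_length_range: tuple[int, int] = (150, 450)
    n_chromosomes: int = 8
    duplicated_chromosome: str | None = "chr01"
    dosage_fold: float = 2.0
    expression_log2_mean: float = 0.0
    expression_log2_sd: float = 1.0
    dispersion: float = 5.0  # Dirichlet concentration per codon
    depth: int = 2_000_000
    n_replicates: int = 2
    stall_specs: Sequence[StallSpec] = field(default_factory=lambda: (StallSpec(),))
    utr_weight: float = 0.05  # relative footprint weight of flanking codons
    spike: SpikeConfig | None = None
    screen: ScreenConfig | None = None

    def __post_init__(self) -> None:
        lo, hi = self.codon_length_range
        if lo < MIN_CODONS:
            raise ConfigurationError(
                f"codon_length_range must start at >= {MIN_CODONS} codons"
            )
        if hi < lo:
            raise ConfigurationError("codon_length_range must be (lo, hi) with hi >= lo")
        if self.dosage_fold < 1:
            raise ConfigurationError("dosage_fold must be >= 1")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        total_sites = sum(s.n_sites for s in self.stall_specs)
        if total_sites > self.n_genes:
            raise ConfigurationError(
                "more planted stall sites than genes (one stall per gene)"
            )

    def chromosome_labels(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class TruthRecord:
    """Ground truth for every planted perturbation."""

    stall_sites: pd.DataFrame | None = None  # gene_id, codon_index, fold, condition,...
    gene_table: pd.DataFrame | None = None  # gene_id, chromosome, log2_expression
    spike_factors: dict[str, float] | None = None
    silencing_defect_genes: list[str] | None = None
    repressed_genes: list[str] | None = None
    screen_hits: pd.DataFrame | None = None  # gene_id, class

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.stall_sites is not None:
            self.stall_sites.to_csv(outdir / "truth_stalls.tsv", sep="\t", index=False)
        if self.gene_table is not None:
            self.gene_table.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        if self.spike_factors is not None:
            pd.Series(self.spike_factors, name="scale_factor").rename_axis(
                "sample"
            ).to_csv(outdir / "truth_spike_factors.tsv", sep="\t")
        if self.silencing_defect_genes is not None:
            pd.Series(self.silencing_defect_genes, name="gene_id").to_csv(
                outdir / "truth_silencing_defect.tsv", sep="\t", index=False
            )
        if self.screen_hits is not None:
            self.screen_hits.to_csv(outdir / "truth_screen_hits.tsv", sep="\t", index=False)


@dataclass
class Genome:
    models: dict[str, GeneModel]
    chromosomes: dict[str, str]
    truth: TruthRecord
    config: SimConfig


def _draw_weighted(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _codon_for_residue(rng: np.random.Generator, residue: str) -> str:
    options = CODONS_BY_RESIDUE[residue]
    return options[rng.integers(len(options))]


def generate_genome(config: SimConfig) -> Genome:
    """Build gene models, chromosome sequences and stall-site truth."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.codon_length_range
    chrom_labels = config.chromosome_labels()
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)

    # assign stall sites: at most one planted stall per gene, genes disjoint
    stall_gene_ids = rng.permutation(config.n_genes)
    stall_rows = []
    cursor = 0
    stall_by_gene: dict[int, tuple[StallSpec, int]] = {}
    for spec in config.stall_specs:
        for _ in range(spec.n_sites):
            gi = int(stall_gene_ids[cursor])
            cursor += 1
            n = int(lengths[gi])
            rel = rng.beta(spec.placement_alpha, spec.placement_beta)
            codon = BODY_TRIM + 1 + int(rel * (n - 2 * BODY_TRIM - 1))
            codon = min(max(codon, BODY_TRIM + 1), n - BODY_TRIM)
            stall_by_gene[gi] = (spec, codon)

    models: dict[str, GeneModel] = {}
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_labels}
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_labels}
    bases = np.array(list("ACGT"))
    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        n = int(lengths[gi])
        codons = [
            SENSE_CODONS[j]
            for j in rng.integers(len(SENSE_CODONS), size=n - 2)
        ]
        codons.insert(0, "ATG")
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        if gi in stall_by_gene:
            spec, stall_codon = stall_by_gene[gi]
            p_res = _draw_weighted(rng, spec.p_site_residues)
            a_res = _draw_weighted(rng, spec.a_site_residues)
            codons[stall_codon - 1] = _codon_for_residue(rng, p_res)
            codons[stall_codon] = _codon_for_residue(rng, a_res)
            stall_rows.append(
                {
                    "gene_id": gene_id,
                    "codon_index": stall_codon,
                    "fold": spec.fold,
                    "condition": spec.affected_condition,
                    "p_site_residue": p_res,
                    "a_site_residue": a_res,
                }
            )
        cds = "".join(codons)
        chrom = chrom_labels[gi % config.n_chromosomes]
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = "".join(bases[rng.integers(4, size=rng.integers(80, 201))])
        chrom_parts[chrom].append(spacer)
        chrom_pos[chrom] += len(spacer)
        start = chrom_pos[chrom] + 1  # 1-based
        genomic = cds if strand == "+" else _revcomp(cds)
        chrom_parts[chrom].append(genomic)
        chrom_pos[chrom] += len(cds)
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome=chrom,
            strand=strand,
            cds_start=start,
            cds_end=start + len(cds) - 1,
            cds_sequence=cds,
            protein=translate(cds),
        )
    for chrom in chrom_labels:  # trailing spacer so downstream windows fit
        tail = "".join(bases[rng.integers(4, size=100)])
        chrom_parts[chrom].append(tail)
    chromosomes = {c: "".join(parts) for c, parts in chrom_parts.items()}

    stall_df = pd.DataFrame(
        stall_rows,
        columns=[
            "gene_id",
            "codon_index",
            "fold",
            "condition",
            "p_site_residue",
            "a_site_residue",
        ],
    )
    gene_table = pd.DataFrame(
        {
            "gene_id": list(models),
            "chromosome": [m.chromosome for m in models.values()],
            "n_codons": [m.n_codons for m in models.values()],
        }
    )
    truth = TruthRecord(stall_sites=stall_df, gene_table=gene_table)
    return Genome(models=models, chromosomes=chromosomes, truth=truth, config=config)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# footprints


@dataclass
class FootprintSim:
    matrices: dict[str, PSiteCountMatrix]  # sample_id -> matrix
    sample_sheet: pd.DataFrame  # sample, condition, replicate
    read_starts: pd.DataFrame | None  # read-level records with P-site truth
    truth: TruthRecord


def _gene_profiles(
    genome: Genome, config: SimConfig, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Per-condition codon profiles; Dirichlet draw shared across conditions,
    stall folds applied multiplicatively in the affected condition."""
    stall_lookup = {
        row.gene_id: row
        for row in genome.truth.stall_sites.itertuples()
    }
    profiles: dict[str, dict[str, np.ndarray]] = {}
    for gene_id, model in genome.models.items():
        n = model.n_codons
        w = np.full(window_length(n), config.utr_weight)
        w[N_UPSTREAM : N_UPSTREAM + n] = 1.0
        if np.isinf(config.dispersion):
            p = w / w.sum()
        else:
            p = rng.dirichlet(config.dispersion * w)
        by_condition = {EUPLOID: p, ANEUPLOID: p}
        if gene_id in stall_lookup:
            row = stall_lookup[gene_id]
            boosted = p.copy()
            boosted[N_UPSTREAM + int(row.codon_index) - 1] *= float(row.fold)
            by_condition = dict(by_condition)
            by_condition[row.condition] = boosted / boosted.sum()
        profiles[gene_id] = by_condition
    return profiles


def simulate_footprints(
    genome: Genome,
    config: SimConfig | None = None,
    emit_reads: bool = False,
    psite_offset_nt: int = 12,
) -> FootprintSim:
    """Per-sample P-site count matrices (optionally with read-start records).

    Gene read mass is proportional to 2^N(mu, sd) x gene length, doubled
    (``dosage_fold``) on the duplicated chromosome in aneuploid samples;
    within-gene allocation is Dirichlet-multinomial around the shared gene
    profile with stall folds applied in the affected condition.
    """
    config = config or genome.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_ids = list(genome.models)
    n_codons = np.array([genome.models[g].n_codons for g in gene_ids])
    log2_expr = rng.normal(
        config.expression_log2_mean, config.expression_log2_sd, size=len(gene_ids)
    )
    base_mass = 2.0**log2_expr * n_codons
    profiles = _gene_profiles(genome, config, rng)

    on_dup = np.array(
        [
            genome.models[g].chromosome == config.duplicated_chromosome
            for g in gene_ids
        ]
    )
    truth = replace_gene_table(genome.truth, gene_ids, genome, log2_expr)

    matrices: dict[str, PSiteCountMatrix] = {}
    sheet_rows = []
    read_rows: list[pd.DataFrame] = []
    for condition in (EUPLOID, ANEUPLOID):
        mass = base_mass * np.where(
            on_dup & (condition == ANEUPLOID), config.dosage_fold, 1.0
        )
        gene_p = mass / mass.sum()
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_rep{rep}"
            sheet_rows.append((sample, condition, rep))
            gene_reads = rng.multinomial(config.depth, gene_p)
            counts: dict[str, np.ndarray] = {}
            for gi, gene_id in enumerate(gene_ids):
                p = profiles[gene_id][condition]
                counts[gene_id] = rng.multinomial(int(gene_reads[gi]), p)
            matrices[sample] = PSiteCountMatrix(sample_id=sample, counts=counts)
            if emit_reads:
                read_rows.append(
                    _emit_read_starts(genome, counts, sample, psite_offset_nt)
                )
    read_starts = (
        pd.concat(read_rows, ignore_index=True) if emit_reads else None
    )
    sample_sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "condition", "replicate"]
    )
    return FootprintSim(
        matrices=matrices,
        sample_sheet=sample_sheet,
        read_starts=read_starts,
        truth=truth,
    )


def replace_gene_table(
    truth: TruthRecord, gene_ids, genome: Genome, log2_expr
) -> TruthRecord:
    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": [genome.models[g].chromosome for g in gene_ids],
            "n_codons": [genome.models[g].n_codons for g in gene_ids],
            "log2_expression": log2_expr,
        }
    )
    return TruthRecord(
        stall_sites=truth.stall_sites,
        gene_table=gene_table,
        spike_factors=truth.spike_factors,
        silencing_defect_genes=truth.silencing_defect_genes,
        repressed_genes=truth.repressed_genes,
        screen_hits=truth.screen_hits,
    )


def _emit_read_starts(
    genome: Genome,
    counts: Mapping[str, np.ndarray],
    sample: str,
    offset_nt: int,
) -> pd.DataFrame:
    """Read-start records whose 5' ends sit exactly ``offset_nt`` upstream of
    the first nucleotide of the true P-site codon (strand-aware)."""
    recs = {"chromosome": [], "strand": [], "pos": [], "true_gene": [], "true_ext": []}
    for gene_id, vec in counts.items():
        model = genome.models[gene_id]
        nz = np.nonzero(vec)[0]
        for ext in nz:
            k = int(vec[ext])
            codon_offset_nt = 3 * (int(ext) - N_UPSTREAM)
            if model.strand == "+":
                psite0 = (model.cds_start - 1) + codon_offset_nt
                pos5 = psite0 - offset_nt
            else:
                psite0 = (model.cds_end - 1) - codon_offset_nt
                pos5 = psite0 + offset_nt
            recs["chromosome"].extend([model.chromosome] * k)
            recs["strand"].extend([model.strand] * k)
            recs["pos"].extend([pos5] * k)
            recs["true_gene"].extend([gene_id] * k)
            recs["true_ext"].extend([int(ext)] * k)
    df = pd.DataFrame(recs)
    df.insert(0, "read_id", [f"{sample}_r{i}" for i in range(len(df))])
    df.insert(1, "sample", sample)
    return df


# ---------------------------------------------------------------------------
# spike-in RNA-seq


@dataclass
class SpikeinSim:
    counts: pd.DataFrame  # genes (incl. spikes) x samples
    spike_genes: list[str]
    sample_sheet: pd.DataFrame  # sample, strain, timepoint, replicate
    reference_sample: str
    truth: TruthRecord


def simulate_spikein(config: SpikeConfig, seed: int = 0) -> SpikeinSim:
    """RNA count table with spike-in genes of known per-sample scale factors.

    Strains: one euploid plus ``n_aneuploids`` aneuploids, each sampled at
    the configured timepoints in replicate. The repressed gene set drops by
    ``repression_log2`` at quiescent (non-log) timepoints in every strain;
    the planted silencing-defect subset instead stays ``defect_log2`` above
    the euploid level in aneuploid strains only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    strains = [EUPLOID] + [f"aneuploid{i + 1}" for i in range(config.n_aneuploids)]
    samples = [
        f"{strain}_{tp}_rep{r}"
        for strain in strains
        for tp in config.timepoints
        for r in range(1, config.n_replicates + 1)
    ]
    sheet = pd.DataFrame(
        [
            (f"{strain}_{tp}_rep{r}", strain, tp, r)
            for strain in strains
            for tp in config.timepoints
            for r in range(1, config.n_replicates + 1)
        ],
        columns=["sample", "strain", "timepoint", "replicate"],
    )
    reference = samples[0]

    if config.true_scale_factors is None:
        factors = {s: float(np.exp(rng.normal(0.0, 0.25))) for s in samples}
        factors[reference] = 1.0
    elif isinstance(config.true_scale_factors, Mapping):
        factors = {s: float(config.true_scale_factors[s]) for s in samples}
    else:
        if len(config.true_scale_factors) != len(samples):
            raise ConfigurationError(
                f"need {len(samples)} scale factors, got {len(config.true_scale_factors)}"
            )
        factors = {s: float(f) for s, f in zip(samples, config.true_scale_factors)}
    if factors[reference] != 1.0:
        raise ConfigurationError("scale factor of the reference sample must be 1")

    genes = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    spikes = [f"spike{i + 1:04d}" for i in range(config.n_spike_genes)]
    repressed = list(genes[: config.n_repressed_genes])
    defect = list(genes[: config.n_defect_genes])  # defect subset of repressed

    base = 2.0 ** rng.normal(config.gene_log2_mean, config.gene_log2_sd, config.n_genes)
    spike_base = 2.0 ** rng.normal(
        config.spike_log2_mean, config.spike_log2_sd, config.n_spike_genes
    )
    sigma_bio = float(np.sqrt(np.log1p(config.biological_cv**2)))
    sigma_spike = float(np.sqrt(np.log1p(config.noise_cv**2)))

    repressed_mask = np.isin(genes, repressed)
    defect_mask = np.isin(genes, defect)
    data = {}
    for sample, strain, tp, _ in sheet.itertuples(index=False):
        log2_shift = np.zeros(config.n_genes)
        if tp != "log":
            log2_shift[repressed_mask] = config.repression_log2
            if strain != EUPLOID:
                log2_shift[defect_mask] = config.repression_log2 + config.defect_log2
        mean = base * 2.0**log2_shift * factors[sample]
        noise = (
            np.exp(rng.normal(0.0, sigma_bio, config.n_genes) - sigma_bio**2 / 2)
            if sigma_bio > 0
            else 1.0
        )
        expr = mean * noise
        if sample == reference:
            spike_counts = spike_base.copy()
        else:
            spike_noise = (
                np.exp(
                    rng.normal(0.0, sigma_spike, config.n_spike_genes)
                    - sigma_spike**2 / 2
                )
                if sigma_spike > 0
                else 1.0
            )
            spike_counts = spike_base * factors[sample] * spike_noise
        data[sample] = np.concatenate([expr, spike_counts])
    counts = pd.DataFrame(data, index=pd.Index(genes + spikes, name="gene_id"))
    truth = TruthRecord(
        spike_factors=factors,
        silencing_defect_genes=defect,
        repressed_genes=repressed,
    )
    return SpikeinSim(
        counts=counts,
        spike_genes=spikes,
        sample_sheet=sheet,
        reference_sample=reference,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# barcode screen


@dataclass
class ScreenSim:
    counts: pd.DataFrame  # genes x samples
    sample_sheet: pd.DataFrame  # sample, strain, timepoint, replicate
    truth: TruthRecord


def simulate_screen(config: ScreenConfig, seed: int = 0) -> ScreenSim:
    """Negative-binomial barcode counts with planted aneuploid-specific hits.

    Early-benefit hits are enriched at day 1 and day 28 in the aneuploid;
    lifespan-specific hits at day 28 only. Euploid pools are unperturbed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    genes = [f"orf{i + 1:05d}" for i in range(config.n_genes)]
    hit_idx = rng.choice(
        config.n_genes, size=config.n_early_hits + config.n_late_hits, replace=False
    )
    early = sorted(genes[i] for i in hit_idx[: config.n_early_hits])
    late = sorted(genes[i] for i in hit_idx[config.n_early_hits :])
    early_mask = np.isin(genes, early)
    late_mask = np.isin(genes, late)

    weights = 2.0 ** rng.normal(0.0, config.abundance_log2_sd, config.n_genes)
    data = {}
    sheet_rows = []
    for strain in config.strains:
        for tp in config.timepoints:
            mult = np.ones(config.n_genes)
            if strain == ANEUPLOID:
                if tp in ("d1", "d28"):
                    mult[early_mask] = 2.0**config.effect_log2
                if tp == "d28":
                    mult[late_mask] = 2.0**config.effect_log2
            props = weights * mult
            props = props / props.sum()
            mu = config.depth * props
            for rep in range(1, config.n_replicates + 1):
                sample = f"{strain}_{tp}_rep{rep}"
                sheet_rows.append((sample, strain, tp, rep))
                if config.nb_dispersion == 0:
                    data[sample] = rng.poisson(mu)
                else:
                    r = 1.0 / config.nb_dispersion
                    data[sample] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    hits = pd.DataFrame(
        {
            "gene_id": early + late,
            "class": ["early_benefit"] * len(early) + ["lifespan_specific"] * len(late),
        }
    )
    truth = TruthRecord(screen_hits=hits)
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "strain", "timepoint", "replicate"]
    )
    return ScreenSim(counts=counts, sample_sheet=sheet, truth=truth)
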