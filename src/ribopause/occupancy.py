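"""Footprint-to-codon occupancy: P-site assignment, normalization, filters.

Each gene's count vector covers an extended window in whole codons:
24 upstream codons (-72 nt from the ATG), the CDS codons 1..n (codon 1 =
ATG, codon n = stop), and 20 downstream codons (+60 nt past the stop).
The gene body used for normalization and filtering is CDS codons
21..n-20 inclusive, so genes need at least 41 codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

#: codons of flanking window kept on each side of the CDS
N_UPSTREAM = 24  # -72 nt in whole codons
N_DOWNSTREAM = 20  # +60 nt in whole codons
#: codons trimmed from each CDS end to define the gene body
BODY_TRIM = 20
MIN_CODONS = 2 * BODY_TRIM + 1  # shortest gene with a non-empty body

DEFAULT_PSITE_OFFSET = 12  # nt from the footprint 5' end to the P site
DEFAULT_MIN_BODY_READS = 50


def window_length(n_codons: int) -> int:
    return N_UPSTREAM + n_codons + N_DOWNSTREAM


def body_slice(n_codons: int) -> slice:
    """Extended-index slice of gene-body codons (CDS codons 21..n-20)."""
    if n_codons < MIN_CODONS:
        raise ValueError(f"gene body undefined for {n_codons} codons (< {MIN_CODONS})")
    return slice(N_UPSTREAM + BODY_TRIM, N_UPSTREAM + n_codons - BODY_TRIM)


def cds_slice(n_codons: int) -> slice:
    return slice(N_UPSTREAM, N_UPSTREAM + n_codons)


def codon_to_ext(codon_index: int) -> int:
    """CDS codon number (1-based) -> extended array index."""
    return N_UPSTREAM + codon_index - 1


@dataclass
class PSiteCountMatrix:
    """Per-gene P-site counts over the extended codon window for one sample."""

    sample_id: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def n_codons(self, gene_id: str) -> int:
        return len(self.counts[gene_id]) - N_UPSTREAM - N_DOWNSTREAM

    def cds_counts(self, gene_id: str) -> np.ndarray:
        return self.counts[gene_id][cds_slice(self.n_codons(gene_id))]

    def body_counts(self, gene_id: str) -> np.ndarray:
        return self.counts[gene_id][body_slice(self.n_codons(gene_id))]

    def body_total(self, gene_id: str) -> int:
        return int(self.body_counts(gene_id).sum())

    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def genes(self) -> list[str]:
        return list(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: gene_id, ext_index, codon_index, count."""
        rows = []
        for gene_id, vec in self.counts.items():
            n = len(vec) - N_UPSTREAM - N_DOWNSTREAM
            codon = np.arange(len(vec)) - N_UPSTREAM + 1  # CDS codon numbers
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_id,
                        "ext_index": np.arange(len(vec)),
                        "codon_index": codon,
                        "n_codons": n,
                        "count": vec,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str) -> "PSiteCountMatrix":
        counts = {}
        for gene_id, grp in frame.groupby("gene_id", sort=False):
            grp = grp.sort_values("ext_index")
            counts[gene_id] = grp["count"].to_numpy(dtype=np.int64)
        return cls(sample_id=sample_id, counts=counts)


@dataclass(frozen=True)
class OccupancyTrace:
    """Pseudocounted, gene-body-normalized occupancy for one gene."""

    gene_id: str
    occupancy: np.ndarray  # extended window, positive reals
    body_mean: float  # denominator: mean (count + pseudocount) over the body

    @property
    def n_codons(self) -> int:
        return len(self.occupancy) - N_UPSTREAM - N_DOWNSTREAM

    @property
    def cds(self) -> np.ndarray:
        return self.occupancy[cds_slice(self.n_codons)]


@dataclass
class AssignmentResult:
    matrix: PSiteCountMatrix
    n_assigned: int  # gene-assignments (a read may hit overlapping genes)
    n_reads_assigned: int
    n_dropped: int  # in-genome reads whose P site missed every window
    n_unknown_chromosome: int
    assignments: pd.DataFrame | None = None  # read_index, gene_id, ext_index


def _window_trees(models: Mapping[str, GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in models.values():
        if m.strand == "+":
            start0 = (m.cds_start - 1) - 3 * N_UPSTREAM
            end0 = (m.cds_end - 1) + 3 * N_DOWNSTREAM + 1
        else:
            start0 = (m.cds_start - 1) - 3 * N_DOWNSTREAM
            end0 = (m.cds_end - 1) + 3 * N_UPSTREAM + 1
        trees.setdefault((m.chromosome, m.strand), IntervalTree()).addi(
            start0, end0, m
        )
    return trees


def _transcript_offset(model: GeneModel, psite0: int) -> int:
    """nt offset of a genomic P-site position from the gene's ATG."""
    if model.strand == "+":
        return psite0 - (model.cds_start - 1)
    return (model.cds_end - 1) - psite0


def assign_psites(
    read_starts: pd.DataFrame,
    models: Mapping[str, GeneModel],
    offset_nt: int = DEFAULT_PSITE_OFFSET,
    sample_id: str = "sample",
    track_assignments: bool = False,
) -> AssignmentResult:
    """Sum P sites per extended codon for every overlapping gene.

    ``read_starts`` needs columns ``chromosome``, ``strand`` and ``pos``
    (0-based genomic coordinate of the read 5' end). The P site sits
    ``offset_nt`` into the read: +offset on the plus strand, -offset on the
    minus strand. Reads on chromosomes absent from the models are dropped
    with a warning; reads whose P site misses every gene window are counted
    as dropped. A read overlapping several gene windows is counted once per
    gene.
    """
    required = {"chromosome", "strand", "pos"}
    if not required.issubset(read_starts.columns):
        raise ValueError(f"read_starts must have columns {sorted(required)}")
    trees = _window_trees(models)
    known_chroms = {m.chromosome for m in models.values()}
    matrix = PSiteCountMatrix(
        sample_id=sample_id,
        counts={
            g: np.zeros(window_length(m.n_codons), dtype=np.int64)
            for g, m in models.items()
        },
    )
    n_assigned = n_reads_assigned = n_dropped = n_unknown = 0
    records: list[tuple[int, str, int]] = []
    chroms = read_starts["chromosome"].to_numpy()
    strands = read_starts["strand"].to_numpy()
    pos = read_starts["pos"].to_numpy(dtype=np.int64)
    psite = np.where(strands == "+", pos + offset_nt, pos - offset_nt)
    for i in range(len(read_starts)):
        if chroms[i] not in known_chroms:
            n_unknown += 1
            continue
        tree = trees.get((chroms[i], strands[i]))
        hits = tree[int(psite[i])] if tree is not None else ()
        hit_any = False
        for interval in hits:
            model = interval.data
            offset = _transcript_offset(model, int(psite[i]))
            ext = N_UPSTREAM + offset // 3
            matrix.counts[model.gene_id][ext] += 1
            n_assigned += 1
            hit_any = True
            if track_assignments:
                records.append((i, model.gene_id, ext))
        if hit_any:
            n_reads_assigned += 1
        else:
            n_dropped += 1
    if n_unknown:
        warnings.warn(
            f"{n_unknown} reads on chromosomes absent from the gene models were dropped",
            stacklevel=2,
        )
    assignments = (
        pd.DataFrame(records, columns=["read_index", "gene_id", "ext_index"])
        if track_assignments
        else None
    )
    return AssignmentResult(
        matrix=matrix,
        n_assigned=n_assigned,
        n_reads_assigned=n_reads_assigned,
        n_dropped=n_dropped,
        n_unknown_chromosome=n_unknown,
        assignments=assignments,
    )


def read_starts_from_sam(path: str) -> pd.DataFrame:
    """5' read starts from a SAM/BAM file (primary alignments only)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r") as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            strand = "-" if read.is_reverse else "+"
            pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            rows.append((read.query_name, read.reference_name, strand, pos))
    return pd.DataFrame(rows, columns=["read_id", "chromosome", "strand", "pos"])


def frame_distribution(
    read_starts: pd.DataFrame,
    models: Mapping[str, GeneModel],
    offset_nt: int = DEFAULT_PSITE_OFFSET,
) -> np.ndarray:
    """Fractions of P sites in frames 0/1/2 relative to the CDS of the genes hit.

    Only P sites falling inside a CDS (matching strand) are scored; the three
    fractions sum to 1.
    """
    trees = _window_trees(models)
    frames = np.zeros(3, dtype=np.int64)
    chroms = read_starts["chromosome"].to_numpy()
    strands = read_starts["strand"].to_numpy()
    pos = read_starts["pos"].to_numpy(dtype=np.int64)
    psite = np.where(strands == "+", pos + offset_nt, pos - offset_nt)
    for i in range(len(read_starts)):
        tree = trees.get((chroms[i], strands[i]))
        if tree is None:
            continue
        for interval in tree[int(psite[i])]:
            model = interval.data
            offset = _transcript_offset(model, int(psite[i]))
            if 0 <= offset < model.cds_length:
                frames[offset % 3] += 1
    total = frames.sum()
    if total == 0:
        raise ValueError("no P sites fell within any CDS")
    return frames / total


def normalize_occupancy(
    matrix: PSiteCountMatrix, pseudocount: float = 1.0
) -> tuple[dict[str, OccupancyTrace], dict[str, str]]:
    """Pseudocounted gene-body-normalized occupancy traces.

    occupancy(c) = (count(c) + pseudocount) / mean over body codons of
    (count + pseudocount). Genes shorter than 41 codons have no body and are
    skipped with a reason.
    """
    traces: dict[str, OccupancyTrace] = {}
    skipped: dict[str, str] = {}
    for gene_id, vec in matrix.counts.items():
        n = len(vec) - N_UPSTREAM - N_DOWNSTREAM
        if n < MIN_CODONS:
            skipped[gene_id] = f"too_short ({n} codons < {MIN_CODONS})"
            continue
        body = vec[body_slice(n)]
        body_mean = float((body + pseudocount).mean())
        traces[gene_id] = OccupancyTrace(
            gene_id=gene_id,
            occupancy=(vec + pseudocount) / body_mean,
            body_mean=body_mean,
        )
    return traces, skipped


def filter_genes(
    matrix: PSiteCountMatrix, min_body_reads: int = DEFAULT_MIN_BODY_READS
) -> set[str]:
    """Genes with at least ``min_body_reads`` raw reads in the gene body."""
    kept = set()
    for gene_id in matrix.counts:
        n = matrix.n_codons(gene_id)
        if n < MIN_CODONS:
            continue
        if matrix.body_total(gene_id) >= min_body_reads:
            kept.add(gene_id)
    return kept


def retained_intersection(
    matrices: Iterable[PSiteCountMatrix],
    min_body_reads: int = DEFAULT_MIN_BODY_READS,
) -> set[str]:
    """Analysis gene set: intersection of per-sample retained sets."""
    sets = [filter_genes(m, min_body_reads) for m in matrices]
    if not sets:
        return set()
    return set.intersection(*sets)


def chromosome_dosage(
    euploid: PSiteCountMatrix,
    aneuploid: PSiteCountMatrix,
    gene_to_chromosome: Mapping[str, str],
    genes: Iterable[str] | None = None,
    center: bool = True,
) -> pd.Series:
    """Per-chromosome median fold difference of gene-body read share.

    Per gene: (aneuploid body reads / aneuploid total body reads) divided by
    the same quantity in the euploid. With ``center=True`` (default) the
    per-gene ratios are divided by the genome-wide median ratio, so that a
    chromosome duplicated k-fold reads out near k and unaffected chromosomes
    near 1 regardless of how much total read mass the duplication adds.
    """
    if genes is None:
        genes = [g for g in euploid.counts if g in aneuploid.counts]
    genes = [g for g in genes if euploid.n_codons(g) >= MIN_CODONS]
    tot_e = sum(euploid.body_total(g) for g in genes)
    tot_a = sum(aneuploid.body_total(g) for g in genes)
    if tot_e == 0 or tot_a == 0:
        raise ValueError("no gene-body reads in one of the samples")
    ratios, chroms = [], []
    for g in genes:
        be, ba = euploid.body_total(g), aneuploid.body_total(g)
        if be == 0:
            continue
        ratios.append((ba / tot_a) / (be / tot_e))
        chroms.append(gene_to_chromosome[g])
    ratio = pd.Series(ratios, index=pd.Index(chroms, name="chromosome"))
    if center:
        ratio = ratio / ratio.median()
    return ratio.groupby(level=0).median().rename("median_fold")
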