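"""Gene models, proteome backgrounds and annotation I/O.

Builds validated single-exon gene models from GFF3 + FASTA, applying the
exclusion rules the pausing analysis assumes: genes must start with an
annotated ATG, carry no introns (no split CDS), have a length divisible by
three and contain no internal stop codon. Coordinates are 1-based inclusive
as in GFF3; minus-strand CDS are reverse-complemented before translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_SYMBOL = "*"
#: 20 amino acids plus the stop symbol, the alphabet of every flank matrix.
SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY") + (STOP_SYMBOL,)


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One single-exon protein-coding gene."""

    gene_id: str
    chromosome: str
    strand: str
    cds_start: int  # 1-based inclusive, genomic
    cds_end: int  # 1-based inclusive, genomic
    cds_sequence: str
    protein: str  # standard-code translation, terminal stop as '*'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if len(self.cds_sequence) % 3 != 0:
            raise AnnotationError(f"{self.gene_id}: CDS length not divisible by 3")
        if len(self.protein) != self.n_codons:
            raise AnnotationError(f"{self.gene_id}: protein length != codon count")

    @property
    def n_codons(self) -> int:
        """Number of codons including the stop codon."""
        return len(self.cds_sequence) // 3

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)


@dataclass(frozen=True)
class Proteome:
    """Per-gene proteins plus background residue frequencies (21 symbols)."""

    proteins: Mapping[str, str]
    counts: Mapping[str, int]
    total: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {s: self.counts[s] / self.total for s in SYMBOLS}


def translate(cds: str) -> str:
    """Standard-code translation; stop codons become '*'."""
    return str(Seq(cds).translate(table=1))


def _check_model_sequence(gene_id: str, cds: str) -> str | None:
    """Return an exclusion reason for a CDS, or None if it is usable."""
    if len(cds) % 3 != 0:
        return "length_not_divisible_by_3"
    if not cds.upper().startswith("ATG"):
        return "no_atg"
    protein = translate(cds)
    if STOP_SYMBOL in protein[:-1]:
        return "internal_stop"
    return None


def load_gene_models(
    gff3_path: str | Path, fasta_path: str | Path
) -> tuple[dict[str, GeneModel], pd.DataFrame]:
    """Build gene models from a GFF3 and genome FASTA.

    Returns ``(models, exclusions)`` where exclusions is a table of
    gene_id/reason pairs (reasons: ``intron`` for multi-segment CDS,
    ``no_atg``, ``length_not_divisible_by_3``, ``internal_stop``).
    Out-of-bounds coordinates raise, naming the offending feature.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    excluded: list[tuple[str, str]] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        cds_parts = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
        if not cds_parts:
            excluded.append((gene_id, "no_cds"))
            continue
        if len(cds_parts) > 1:
            excluded.append((gene_id, "intron"))
            continue
        part = cds_parts[0]
        if part.seqid not in seqs:
            raise AnnotationError(f"{gene_id}: unknown sequence {part.seqid!r}")
        chrom_seq = seqs[part.seqid]
        if part.start < 1 or part.end > len(chrom_seq):
            raise AnnotationError(
                f"CDS of {gene_id} ({part.seqid}:{part.start}-{part.end}) "
                f"exceeds sequence bounds (length {len(chrom_seq)})"
            )
        cds = chrom_seq[part.start - 1 : part.end]
        if part.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        reason = _check_model_sequence(gene_id, cds)
        if reason is not None:
            excluded.append((gene_id, reason))
            continue
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome=part.seqid,
            strand=part.strand,
            cds_start=part.start,
            cds_end=part.end,
            cds_sequence=cds,
            protein=translate(cds),
        )
    exclusions = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return models, exclusions


def build_proteome(
    models: Mapping[str, GeneModel] | Mapping[str, str],
    scope: Iterable[str] | None = None,
) -> Proteome:
    """Background residue frequencies over the chosen gene scope.

    ``scope`` restricts the background to a subset of gene ids (e.g. the
    measured genes); default is every model supplied. Frequencies are raw
    occurrence counts over all residues (stop symbol included) divided by
    the total residue count.
    """
    ids = list(models) if scope is None else list(scope)
    if not ids:
        raise AnnotationError("empty gene scope for proteome background")
    proteins: dict[str, str] = {}
    for gid in ids:
        entry = models[gid]
        proteins[gid] = entry.protein if isinstance(entry, GeneModel) else str(entry)
    counts = dict.fromkeys(SYMBOLS, 0)
    for protein in proteins.values():
        for residue in protein:
            counts[residue] += 1
    total = sum(counts.values())
    return Proteome(proteins=proteins, counts=counts, total=total)


# ---------------------------------------------------------------------------
# writers


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene + CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models.values():
            common = (m.chromosome, "ribopause", m.cds_start, m.cds_end, m.strand)
            fh.write(
                f"{common[0]}\t{common[1]}\tgene\t{common[2]}\t{common[3]}\t.\t"
                f"{common[4]}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{common[0]}\t{common[1]}\tCDS\t{common[2]}\t{common[3]}\t.\t"
                f"{common[4]}\t0\tID=cds-{m.gene_id};Parent={m.gene_id}\n"
            )


def write_gene_models(
    models: Mapping[str, GeneModel],
    chromosomes: Mapping[str, str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genome FASTA, CDS FASTA, protein FASTA and GFF3 to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "cds": outdir / "cds.fa",
        "protein": outdir / "proteome.fa",
        "gff3": outdir / "genes.gff3",
    }
    write_fasta(chromosomes, paths["genome"])
    write_fasta({g: m.cds_sequence for g, m in models.items()}, paths["cds"])
    write_fasta({g: m.protein for g, m in models.items()}, paths["protein"])
    write_gff3(models, paths["gff3"])
    return paths
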