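"""Readers, writers and ortholog-cluster resolution.

External formats: aligned CDS FASTA (header grammar ``genome|gene``), the
gene membership TSV (``gene_id, genome_id, essential, drug_target, ko_id``),
GO ontologies as OBO 1.2 and annotations as GAF 2.x, plus TSV/JSON report
output.  Many-to-many ortholog clusters are reduced to one-to-one pairs by
reciprocal best hits under a deterministic global protein alignment score
(BLOSUM62, gap open −11 / extend −1), which replaces an external BLAST
dependency while preserving the reciprocal-best-hit decision structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from functools import cache
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

ALIGNMENT_ALPHABET = frozenset("ACGTN-")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class AlignmentFormatError(ValueError):
    """Malformed alignment (ragged rows, bad symbols, bad headers)."""


class FrameError(ValueError):
    """Alignment length is not a multiple of 3."""


class TableParseError(ValueError):
    """Malformed line in a tabular input, with line number in the message."""


class AmbiguityError(ValueError):
    """The reference genome of a cluster has more than one member."""


@dataclass
class CodonAlignment:
    """One gene's aligned coding sequences across strains.

    Rows are over {A,C,G,T,-,N}, equal length, a multiple of 3;
    ``reference_row`` indexes the reference-genome sequence.
    """

    gene_id: str
    genome_ids: list[str]
    rows: list[str]
    reference_row: int

    def __post_init__(self):
        if len(self.rows) < 2:
            raise AlignmentFormatError(
                f"{self.gene_id}: alignment needs at least 2 rows")
        if len(self.genome_ids) != len(self.rows):
            raise AlignmentFormatError(
                f"{self.gene_id}: {len(self.genome_ids)} genome ids for "
                f"{len(self.rows)} rows")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"{self.gene_id}: unequal row lengths {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(
                f"{self.gene_id}: alignment length {length} is not a "
                "multiple of 3")
        for genome, row in zip(self.genome_ids, self.rows):
            bad = set(row) - ALIGNMENT_ALPHABET
            if bad:
                raise AlignmentFormatError(
                    f"{self.gene_id}/{genome}: illegal symbols {sorted(bad)}")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise AlignmentFormatError(
                f"{self.gene_id}: duplicate genome ids")
        if not 0 <= self.reference_row < len(self.rows):
            raise AlignmentFormatError(
                f"{self.gene_id}: reference_row {self.reference_row} out of "
                "range")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3


def read_codon_alignment(path, reference_genome: str) -> CodonAlignment:
    """Read one aligned-CDS FASTA cluster; headers are ``genome|gene``."""
    genome_ids: list[str] = []
    gene_ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise AlignmentFormatError(
                f"{path}: header {rec.id!r} does not follow 'genome|gene'")
        genome_ids.append(parts[0])
        gene_ids.append(parts[1])
        rows.append(str(rec.seq).upper())
    if reference_genome not in genome_ids:
        raise KeyError(
            f"{path}: reference genome {reference_genome!r} absent")
    ref = genome_ids.index(reference_genome)
    return CodonAlignment(gene_id=gene_ids[ref], genome_ids=genome_ids,
                          rows=rows, reference_row=ref)


def write_codon_alignment(aln: CodonAlignment, path,
                          gene_ids: Optional[Mapping[str, str]] = None) -> None:
    """Write a cluster back to FASTA with ``genome|gene`` headers."""
    with open(path, "w") as fh:
        for genome, row in zip(aln.genome_ids, aln.rows):
            gene = (gene_ids or {}).get(genome, aln.gene_id)
            fh.write(f">{genome}|{gene}\n{row}\n")


# -- protein scoring and reciprocal best hits --------------------------------

@cache
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def score_protein_pair(a: str, b: str) -> float:
    """Global protein alignment score (BLOSUM62, affine gaps −11/−1).

    Symmetric; a sequence's self-score is maximal among equal-length
    partners.  Used as the similarity underlying reciprocal-best-hit
    ortholog resolution.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty protein sequence")
    for seq in (a, b):
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"illegal amino acids {sorted(bad)}")
    return float(_aligner().score(a, b))


@dataclass
class OrthologCluster:
    """Members per genome of one ortholog cluster; possibly many-to-many.

    ``members`` maps genome id to a list of ``(gene_id, protein_sequence)``.
    """

    cluster_id: str
    members: dict[str, list[tuple[str, str]]]
    reference_genome: str

    def __post_init__(self):
        if self.reference_genome not in self.members:
            raise KeyError(
                f"{self.cluster_id}: reference genome "
                f"{self.reference_genome!r} absent")
        for genome, mem in self.members.items():
            if not mem:
                raise ValueError(
                    f"{self.cluster_id}/{genome}: genome with no members")


def _best_hit(query_seq: str,
              candidates: Iterable[tuple[str, str]],
              scorer: Callable[[str, str], float]) -> tuple[str, str]:
    """Highest-scoring candidate; score ties broken by smallest gene_id."""
    best = None
    best_key = None
    for gene_id, seq in candidates:
        score = scorer(query_seq, seq)
        key = (-score, gene_id)
        if best_key is None or key < best_key:
            best_key = key
            best = (gene_id, seq)
    assert best is not None
    return best


def resolve_duplicates(cluster: OrthologCluster,
                       scorer: Callable[[str, str], float] = score_protein_pair,
                       ) -> dict[str, str]:
    """Reduce a many-to-many cluster to one gene per genome via RBH.

    The reference genome must hold exactly one member.  For each other
    genome the reference's best hit is kept only if that hit's own best hit
    across all other genomes' members is the reference gene; genomes
    without a reciprocal best hit are dropped (logged).  Score ties break
    lexicographically by gene_id.
    """
    ref_members = cluster.members[cluster.reference_genome]
    if len(ref_members) != 1:
        raise AmbiguityError(
            f"{cluster.cluster_id}: reference genome has "
            f"{len(ref_members)} members")
    ref_gene, ref_seq = ref_members[0]
    mapping = {cluster.reference_genome: ref_gene}
    for genome in sorted(cluster.members):
        if genome == cluster.reference_genome:
            continue
        forward_gene, forward_seq = _best_hit(
            ref_seq, cluster.members[genome], scorer)
        pool = [(gid, seq)
                for other, mem in cluster.members.items()
                if other != genome
                for gid, seq in mem]
        back_gene, _ = _best_hit(forward_seq, pool, scorer)
        if back_gene == ref_gene:
            mapping[genome] = forward_gene
        else:
            logger.info("cluster %s: genome %s dropped (best hit %s is not "
                        "reciprocal; %s prefers %s)", cluster.cluster_id,
                        genome, forward_gene, forward_gene, back_gene)
    return mapping


# -- gene membership table ---------------------------------------------------

GENE_TABLE_COLUMNS = ("gene_id", "genome_id", "essential", "drug_target",
                      "ko_id")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    is_essential: bool
    is_drug_target: bool
    ko_id: Optional[str] = None


@dataclass
class GeneTable:
    """Per-gene membership flags (essential / drug target) and KO group."""

    records: list[GeneRecord]

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            key = (rec.gene_id, rec.genome_id)
            if key in seen:
                raise ValueError(f"duplicate gene {key} in gene table")
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.gene_id, r.genome_id, int(r.is_essential),
              int(r.is_drug_target), r.ko_id or "")
             for r in self.records],
            columns=list(GENE_TABLE_COLUMNS))

    def ko_map(self) -> dict[str, str]:
        return {r.gene_id: r.ko_id for r in self.records if r.ko_id}


def read_gene_table(path) -> GeneTable:
    """Read the gene membership TSV; malformed lines raise with a line number."""
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(GENE_TABLE_COLUMNS):
            raise TableParseError(
                f"{path} line 1: expected columns "
                f"{list(GENE_TABLE_COLUMNS)}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(GENE_TABLE_COLUMNS):
                raise TableParseError(
                    f"{path} line {lineno}: expected "
                    f"{len(GENE_TABLE_COLUMNS)} columns, got {len(parts)}")
            gene_id, genome_id, essential, drug_target, ko_id = parts
            if essential not in {"0", "1"} or drug_target not in {"0", "1"}:
                raise TableParseError(
                    f"{path} line {lineno}: flags must be 0/1")
            records.append(GeneRecord(gene_id, genome_id,
                                      essential == "1", drug_target == "1",
                                      ko_id or None))
    return GeneTable(records)


def write_gene_table(table: GeneTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# -- ontology and annotations ------------------------------------------------

def read_obo(path):
    """Read an OBO 1.2 ontology into a :class:`~evorate.go_enrichment.GoDag`.

    Only is_a and part_of edges are retained; a cycle among them raises
    ``ValueError``.
    """
    import obonet

    from .go_enrichment import GoDag

    graph = obonet.read_obo(str(path))
    return GoDag.from_obonet(graph)


def read_gaf(path, dag=None) -> tuple[dict[str, set[str]], int]:
    """Read GAF 2.x direct annotations (columns 2 and 5).

    Returns ``(annotations, n_skipped)``; lines citing a term absent from
    ``dag`` (when given) are skipped with a warning and tallied.
    Structurally malformed lines raise with a line number.
    """
    annotations: dict[str, set[str]] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise TableParseError(
                    f"{path} line {lineno}: fewer than 5 columns")
            obj, term = parts[1], parts[4]
            if not term.startswith("GO:"):
                raise TableParseError(
                    f"{path} line {lineno}: {term!r} is not a GO id")
            if dag is not None and term not in dag.graph:
                logger.warning("%s line %d: unknown GO term %s skipped",
                               path, lineno, term)
                skipped += 1
                continue
            annotations.setdefault(obj, set()).add(term)
    return annotations, skipped


def write_report(tables: Mapping[str, pd.DataFrame], out_dir,
                 provenance: Optional[dict] = None) -> None:
    """Write each table as ``<name>.tsv`` plus an optional provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if provenance is not None:
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")


__all__ = [
    "CodonAlignment", "OrthologCluster", "GeneRecord", "GeneTable",
    "AlignmentFormatError", "FrameError", "TableParseError", "AmbiguityError",
    "read_codon_alignment", "write_codon_alignment", "score_protein_pair",
    "resolve_duplicates", "read_gene_table", "write_gene_table", "read_obo",
    "read_gaf", "write_report", "GENE_TABLE_COLUMNS",
]
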