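"""Ground-truthed synthetic study generator.

Emulates the inputs of a strain-level evolutionary-rate study: per-gene
clusters of closely related coding sequences evolved from a shared ancestor
under class-specific purifying selection, a gene membership table, KO
assignments for the drug-target class, and a toy GO DAG with annotations
concentrated in the slowly evolving classes.

Selection is modelled as acceptance thinning: proposed single-base changes
are always accepted when synonymous, accepted with probability min(1, ω)
when nonsynonymous, and rejected outright when they would create a stop
codon.  Counted pN/pS is then approximately proportional to ω, which is all
the pipeline needs to recover the ordinal pattern drug targets ≪ essential
< background.  Evolution is a star topology — each row descends
independently from the ancestor — matching the closely-related-strain
polymorphism setting.  Default class sizes (1000/300/35) are a scaled-down
version of an E. coli-like genome (≈4294 background / 771 essential / 41
targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .go_enrichment import GoDag
from .io_formats import (CodonAlignment, GeneRecord, GeneTable,
                         write_codon_alignment, write_gene_table)
from .selection_stats import STOP_CODONS, translate_codon

_BASES = "ACGT"
_SENSE_CODONS = tuple(c for c in
                      (a + b + c for a in _BASES for b in _BASES
                       for c in _BASES)
                      if c not in STOP_CODONS)

# toy ontology used by every simulated study
ROOT_TERM = "GO:0000001"
SLOW_TERM = "GO:0000002"          # designated marker of slow classes
SLOW_CHILD_TERM = "GO:0000004"    # child of SLOW_TERM, exercises propagation
OTHER_TERM = "GO:0000003"

_BASE_SLOW_PROB = 0.08   # chance a background gene carries the slow term
_OTHER_PROB = 0.30       # chance any gene carries the unrelated term


@dataclass
class SimulationConfig:
    """Study conditions for one simulated species.

    ``omega_*`` are acceptance probabilities for nonsynonymous proposals —
    the true per-class selection intensity the pipeline must recover, with
    drug targets under the strongest constraint.
    ``expected_subs_per_codon`` is the expected number of proposed
    single-base changes per codon per branch.
    ``slow_term_enrichment`` multiplies the odds that a target/essential
    gene carries the designated slow GO term.
    """

    n_background: int = 1000
    n_essential: int = 300
    n_targets: int = 35
    omega_background: float = 0.6
    omega_essential: float = 0.3
    omega_targets: float = 0.1
    expected_subs_per_codon: float = 0.2
    gene_length_codons: Union[int, tuple[int, int]] = 300
    rows_per_cluster: int = 2
    slow_term_enrichment: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_background, self.n_essential, self.n_targets) < 0:
            raise ValueError("class sizes must be non-negative")
        if self.rows_per_cluster < 2:
            raise ValueError("clusters need at least 2 rows")
        if self.expected_subs_per_codon < 0:
            raise ValueError("expected_subs_per_codon must be >= 0")
        if self.slow_term_enrichment < 1:
            raise ValueError("slow_term_enrichment must be >= 1")
        n_classes = sum(n > 0 for n in (self.n_background, self.n_essential,
                                        self.n_targets))
        if n_classes < 2:
            raise ValueError("at least two classes must be non-empty")


def random_cds(length_codons: int, seed) -> str:
    """Uniform random coding sequence: ATG then uniform sense codons."""
    if length_codons < 1:
        raise ValueError("length must be >= 1 codon")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    tail = rng.integers(0, len(_SENSE_CODONS), size=length_codons - 1)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in tail)


def evolve(seq: str, omega: float, expected_subs_per_codon: float, seed
           ) -> tuple[str, int, int]:
    """Evolve a coding sequence under acceptance-thinned selection.

    Proposes Poisson(expected_subs_per_codon × n_codons) single-base
    changes at uniform positions to uniform alternative bases, applied
    sequentially.  Changes creating stop codons are rejected; synonymous
    changes are always accepted; nonsynonymous changes are accepted with
    probability min(1, omega).  Returns the derived sequence and the exact
    accepted nonsynonymous and synonymous counts.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    chars = list(seq)
    length = len(chars)
    n_codons = length // 3
    n_proposals = int(rng.poisson(expected_subs_per_codon * n_codons))
    n_accepted = s_accepted = 0
    for _ in range(n_proposals):
        site = int(rng.integers(length))
        old = chars[site]
        alternatives = [b for b in _BASES if b != old]
        new = alternatives[int(rng.integers(3))]
        start = site - site % 3
        codon = "".join(chars[start:start + 3])
        mutant = codon[:site - start] + new + codon[site - start + 1:]
        if mutant in STOP_CODONS:
            continue
        if translate_codon(codon) == translate_codon(mutant):
            chars[site] = new
            s_accepted += 1
        elif omega >= 1 or rng.random() < omega:
            chars[site] = new
            n_accepted += 1
    return "".join(chars), n_accepted, s_accepted


def toy_go_dag() -> GoDag:
    """Four-term molecular-function toy ontology with a designated slow term."""
    terms = {
        ROOT_TERM: ("molecular_function", "molecular_function"),
        SLOW_TERM: ("conserved core machinery activity", "molecular_function"),
        SLOW_CHILD_TERM: ("conserved catalytic subunit activity",
                          "molecular_function"),
        OTHER_TERM: ("generic binding", "molecular_function"),
    }
    edges = [
        (SLOW_TERM, ROOT_TERM, "is_a"),
        (SLOW_CHILD_TERM, SLOW_TERM, "is_a"),
        (OTHER_TERM, ROOT_TERM, "is_a"),
    ]
    return GoDag.build(terms, edges)


@dataclass
class SimulatedStudy:
    """Everything one pipeline run needs, plus the ground truth."""

    config: SimulationConfig
    alignments: list[CodonAlignment]
    gene_table: GeneTable
    ko_map: dict[str, str]
    dag: GoDag
    annotations: dict[str, set[str]]
    truth: pd.DataFrame  # gene_id, true_class, true_omega, n_accepted, s_accepted
    ancestors: dict[str, str] = field(default_factory=dict)
    per_row_counts: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)


def _gene_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    length = config.gene_length_codons
    if isinstance(length, int):
        return length
    low, high = length
    return int(rng.integers(low, high + 1))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate a complete single-species study from one seed.

    Per gene: an ancestral CDS is drawn, then ``rows_per_cluster`` strain
    sequences are evolved independently from it with the class ω.  The gene
    table carries the true class flags (reference genome only); drug
    targets each receive a KO id; GO annotations put the designated slow
    term on target/essential genes with odds multiplied by
    ``slow_term_enrichment``.  All randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genome_ids = [f"G{i}" for i in range(config.rows_per_cluster)]
    classes = [
        ("adt", config.n_targets, config.omega_targets, True, True),
        ("ess", config.n_essential, config.omega_essential, True, False),
        ("bg", config.n_background, config.omega_background, False, False),
    ]
    alignments: list[CodonAlignment] = []
    records: list[GeneRecord] = []
    ko_map: dict[str, str] = {}
    annotations: dict[str, set[str]] = {}
    truth_rows = []
    ancestors: dict[str, str] = {}
    per_row_counts: dict[str, list[tuple[int, int]]] = {}

    slow_odds = _BASE_SLOW_PROB / (1 - _BASE_SLOW_PROB)
    enriched_odds = slow_odds * config.slow_term_enrichment
    p_slow_enriched = enriched_odds / (1 + enriched_odds)

    ko_counter = 0
    for prefix, n_genes, omega, essential, target in classes:
        for i in range(n_genes):
            gene_id = f"{prefix}{i:04d}"
            length = _gene_length(config, rng)
            ancestor = random_cds(length, rng)
            rows = []
            row_counts = []
            total_n = total_s = 0
            for _ in range(config.rows_per_cluster):
                derived, acc_n, acc_s = evolve(
                    ancestor, omega, config.expected_subs_per_codon, rng)
                rows.append(derived)
                row_counts.append((acc_n, acc_s))
                total_n += acc_n
                total_s += acc_s
            alignments.append(CodonAlignment(
                gene_id=gene_id, genome_ids=list(genome_ids), rows=rows,
                reference_row=0))
            ancestors[gene_id] = ancestor
            per_row_counts[gene_id] = row_counts
            ko_id = None
            if target:
                ko_counter += 1
                ko_id = f"ko:K{20000 + ko_counter:05d}"
                ko_map[gene_id] = ko_id
            records.append(GeneRecord(gene_id, genome_ids[0],
                                      essential, target, ko_id))
            terms: set[str] = set()
            p_slow = p_slow_enriched if (essential or target) \
                else _BASE_SLOW_PROB
            if rng.random() < p_slow:
                terms.add(SLOW_CHILD_TERM if rng.random() < 0.5
                          else SLOW_TERM)
            if rng.random() < _OTHER_PROB:
                terms.add(OTHER_TERM)
            if terms:
                annotations[gene_id] = terms
            truth_rows.append((gene_id,
                               {"adt": "ADT", "ess": "ESS",
                                "bg": "ALL"}[prefix],
                               omega, total_n, total_s))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "true_class", "true_omega", "n_accepted", "s_accepted"])
    return SimulatedStudy(config=config, alignments=alignments,
                          gene_table=GeneTable(records), ko_map=ko_map,
                          dag=toy_go_dag(), annotations=annotations,
                          truth=truth, ancestors=ancestors,
                          per_row_counts=per_row_counts)


# -- serialisation in the exact formats the readers consume ------------------

def _write_obo(dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.graph.nodes):
            data = dag.graph.nodes[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', '')}\n")
            fh.write(f"namespace: {data.get('namespace', '')}\n")
            for _, parent, edge in sorted(
                    dag.graph.out_edges(term, data=True),
                    key=lambda e: e[1]):
                relation = edge.get("relation", "is_a")
                if relation == "is_a":
                    fh.write(f"is_a: {parent} ! {dag.name(parent)}\n")
                else:
                    fh.write(f"relationship: {relation} {parent} "
                             f"! {dag.name(parent)}\n")
            fh.write("\n")


def _write_gaf(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                cols = ["SIM", gene, gene, "", term, "SIM:ref", "IEA", "",
                        "F", "", "", "protein", "taxon:0", "20120101",
                        "SIM", "", ""]
                fh.write("\t".join(cols) + "\n")


def write_study(study: SimulatedStudy, out_dir) -> Path:
    """Write a simulated study in the formats the readers consume.

    Layout: ``alignments/<gene>.fasta``, ``genes.tsv``, ``ko.tsv``,
    ``toy.obo``, ``toy.gaf`` and ``truth.tsv``.  Deterministic: the same
    study writes byte-identical files.
    """
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    for aln in study.alignments:
        write_codon_alignment(aln, out / "alignments" / f"{aln.gene_id}.fasta")
    write_gene_table(study.gene_table, out / "genes.tsv")
    with open(out / "ko.tsv", "w") as fh:
        fh.write("gene_id\tko_id\n")
        for gene in sorted(study.ko_map):
            fh.write(f"{gene}\t{study.ko_map[gene]}\n")
    _write_obo(study.dag, out / "toy.obo")
    _write_gaf(study.annotations, out / "toy.gaf")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


__all__ = [
    "SimulationConfig", "SimulatedStudy", "random_cds", "evolve",
    "simulate_study", "toy_go_dag", "write_study",
    "ROOT_TERM", "SLOW_TERM", "SLOW_CHILD_TERM", "OTHER_TERM",
]
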