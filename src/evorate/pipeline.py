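"""End-to-end orchestration: simulate/load → estimate → compare → rank → enrich.

One run covers one or more species (species is a column, not a loop in the
caller); pN/pS is the primary statistic and dN/dS can be computed alongside
with its own independently adjusted test family.  Divergence estimates from
genes failing the four-gamete recombination screen are excluded from dN/dS
comparisons and summaries but kept for pN/pS.  Every run writes a
provenance block (config hash, seed, library versions, filter-step counts)
sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .go_enrichment import enrichment_to_frame, propagate_annotations, \
    term_for_term
from .group_stats import adjust_comparisons, compare_groups, \
    comparisons_to_frame, partition_genes
from .io_formats import GeneTable, read_codon_alignment, read_gaf, \
    read_gene_table, read_obo, write_report
from .ranking import ko_summary_to_frame, percentile_rank, ranking_to_frame, \
    select_slowest, summarize_ko_groups
from .selection_stats import count_gene_polymorphisms, dnds_ng86, \
    estimates_to_frame, four_gamete_screen
from .synthetic_data import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

STATISTICS = ("pnps", "dnds", "both")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input source: either ``simulation`` or the input paths
    (``alignments_dir`` + ``genes_path``; ontology/annotation paths enable
    the enrichment stage).
    """

    simulation: Optional[SimulationConfig] = None
    alignments_dir: Optional[str] = None
    genes_path: Optional[str] = None
    obo_path: Optional[str] = None
    gaf_path: Optional[str] = None
    reference_genome: str = "G0"
    species: str = "sim"
    statistic: str = "pnps"
    fdr_family: str = "per-species"
    slow_fraction: float = 0.10
    bootstrap_resamples: int = 2000
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        from_paths = self.alignments_dir is not None
        if from_paths == (self.simulation is not None):
            raise ValueError(
                "supply exactly one of simulation config or input paths")
        if from_paths and self.genes_path is None:
            raise ValueError("input paths need genes_path")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        if self.fdr_family not in ("per-species", "all-species"):
            raise ValueError("fdr_family must be per-species or all-species")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # where output lands does not alter the science
        return d


@dataclass
class RunReport:
    """Tables plus provenance for one run."""

    estimates: pd.DataFrame
    comparisons: pd.DataFrame
    ranking: pd.DataFrame
    ko_summary: pd.DataFrame
    enrichment: pd.DataFrame
    provenance: dict
    truth: Optional[pd.DataFrame] = None

    def write(self, out_dir) -> Path:
        tables = {
            "estimates": self.estimates,
            "comparisons": self.comparisons,
            "ranking": self.ranking,
            "ko_summary": self.ko_summary,
            "enrichment": self.enrichment,
        }
        if self.truth is not None:
            tables["truth"] = self.truth
        write_report(tables, out_dir, provenance=self.provenance)
        return Path(out_dir)


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        study = simulate_study(config.simulation)
        return (study.alignments, study.gene_table, study.ko_map,
                study.dag, study.annotations, study.truth)
    alignments = []
    for path in sorted(Path(config.alignments_dir).glob("*.fasta")):
        alignments.append(
            read_codon_alignment(path, config.reference_genome))
    gene_table = read_gene_table(config.genes_path)
    ko_map = gene_table.ko_map()
    dag = read_obo(config.obo_path) if config.obo_path else None
    annotations: dict[str, set[str]] = {}
    if config.gaf_path and dag is not None:
        annotations, n_skipped = read_gaf(config.gaf_path, dag)
        if n_skipped:
            logger.warning("%d GAF lines skipped", n_skipped)
    return alignments, gene_table, ko_map, dag, annotations, None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and return (optionally write) the report.

    Stage order: estimate per-gene statistics, partition gene sets, run the
    Mann–Whitney comparisons with a jointly BY-adjusted family per
    statistic, rank genes genome-wide, summarise KO groups, and test the
    slowest decile for GO term over-representation.
    """
    alignments, gene_table, ko_map, dag, annotations, truth = \
        _load_inputs(config)
    if not alignments:
        raise ValueError("no alignments to analyse")
    species = config.species
    filter_counts: dict[str, int] = {"genes_input": len(alignments)}

    pnps_estimates = [count_gene_polymorphisms(a) for a in alignments]
    usable_pnps = {e.gene_id: e.ratio for e in pnps_estimates if e.usable}
    filter_counts["pnps_usable"] = len(usable_pnps)
    all_estimates = list(pnps_estimates)

    dnds_ratios: dict[str, float] = {}
    if config.statistic in ("dnds", "both"):
        dnds_estimates = []
        n_flagged = 0
        for aln in alignments:
            _, flagged = four_gamete_screen(aln)
            pair = aln
            if len(aln.rows) > 2:
                other = next(i for i in range(len(aln.rows))
                             if i != aln.reference_row)
                pair = dataclasses.replace(
                    aln,
                    genome_ids=[aln.genome_ids[aln.reference_row],
                                aln.genome_ids[other]],
                    rows=[aln.rows[aln.reference_row], aln.rows[other]],
                    reference_row=0)
            est = dnds_ng86(pair)
            est.recombination_flagged = flagged
            n_flagged += flagged
            dnds_estimates.append(est)
            if est.usable and not flagged:
                dnds_ratios[est.gene_id] = est.ratio
        filter_counts["dnds_usable"] = len(dnds_ratios)
        filter_counts["dnds_recombination_flagged"] = n_flagged
        all_estimates += dnds_estimates

    partition = partition_genes(GeneTable(
        [r for r in gene_table.records
         if r.genome_id == gene_table.records[0].genome_id]))

    comparisons = []
    families = []
    if config.statistic in ("pnps", "both"):
        families.append(("pnps", usable_pnps))
    if config.statistic in ("dnds", "both"):
        families.append(("dnds", dnds_ratios))
    for stat_name, ratios in families:
        family = compare_groups(ratios, partition, species=species,
                                bootstrap_resamples=config.bootstrap_resamples,
                                seed=config.seed)
        # per-species and all-species coincide for a single-species run;
        # adjustment is always joint across the family produced here
        family = adjust_comparisons(family)
        frame = comparisons_to_frame(family)
        frame.insert(0, "statistic", stat_name)
        comparisons.append(frame)
    comparisons_frame = pd.concat(comparisons, ignore_index=True) \
        if comparisons else pd.DataFrame()

    ranking_source = usable_pnps if config.statistic != "dnds" \
        else dnds_ratios
    ranked = percentile_rank(sorted(ranking_source.items()))
    slow = select_slowest(ranked, config.slow_fraction)
    filter_counts["study_set"] = len(slow)

    ko_summary = ko_summary_to_frame(summarize_ko_groups(
        ko_map, {config.reference_genome: ranking_source}))

    if dag is not None and annotations:
        propagated = propagate_annotations(annotations, dag)
        population = {r.gene_id for r in gene_table.records}
        enrichment = term_for_term(set(slow), population, propagated, dag)
        enrichment_frame = enrichment_to_frame(enrichment)
    else:
        enrichment_frame = enrichment_to_frame([])

    provenance = {
        "config": _jsonable(config.to_dict()),
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonable(config.to_dict()),
                       sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"evorate": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "filter_counts": filter_counts,
        "set_counts": partition.counts(),
    }
    report = RunReport(estimates=estimates_to_frame(all_estimates),
                       comparisons=comparisons_frame,
                       ranking=ranking_to_frame(ranked),
                       ko_summary=ko_summary,
                       enrichment=enrichment_frame,
                       provenance=provenance,
                       truth=truth)
    if config.out_dir:
        report.write(config.out_dir)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


__all__ = ["RunConfig", "RunReport", "run_pipeline", "STATISTICS"]
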