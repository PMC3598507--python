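"""GO term over-representation among the slowest-evolving genes.

The simulator plants a designated 'conserved core machinery' GO term
preferentially on slow classes; the enrichment stage should recover it
with a small hypergeometric p in the slowest decile.
"""

from evorate import (SimulationConfig, count_gene_polymorphisms,
                     percentile_rank, propagate_annotations, select_slowest,
                     simulate_study, term_for_term)

study = simulate_study(SimulationConfig(
    n_background=400, n_essential=120, n_targets=25,
    gene_length_codons=150, seed=19))

estimates = [count_gene_polymorphisms(a) for a in study.alignments]
ratios = {e.gene_id: e.ratio for e in estimates if e.usable}
ranked = percentile_rank(sorted(ratios.items()))
slow = set(select_slowest(ranked, 0.10))
population = {r.gene_id for r in study.gene_table.records}

propagated = propagate_annotations(study.annotations, study.dag)
results = term_for_term(slow, population, propagated, study.dag)

print(f"{'term':<12} {'p':>10} {'study':>6} {'pop':>6}  description")
for r in results:
    print(f"{r.term_id:<12} {r.p_value:>10.2e} "
          f"{r.study_fraction:>6.3f} {r.population_fraction:>6.3f}  "
          f"{r.description}")
print("\nThe planted slow-class terms rise to the top with study "
      "fractions well above their population fractions.")
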