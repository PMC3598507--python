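"""Estimate pN/pS and dN/dS for a single gene alignment.

Builds a two-strain codon alignment with two synonymous and one
nonsynonymous difference, then prints both counting statistics.
"""

from evorate import CodonAlignment, count_gene_polymorphisms, dnds_ng86

# 10 codons; differences: codon 2 AAA->AAG (syn), codon 4 GGG->GGA (syn),
# codon 6 TTT->GTT (nonsyn, Phe->Val)
reference = "ATG AAA CCC GGG ACT TTT CTG GAA CGT TAA".replace(" ", "")
strain = "ATG AAG CCC GGA ACT GTT CTG GAA CGT TAA".replace(" ", "")

aln = CodonAlignment(gene_id="demo", genome_ids=["ref", "strain1"],
                     rows=[reference, strain], reference_row=0)

poly = count_gene_polymorphisms(aln)
print(f"pN/pS: n={poly.n_count:.1f} s={poly.s_count:.1f} "
      f"ratio={poly.ratio:.3f} (codons used: {poly.n_codons_used})")

div = dnds_ng86(aln)
print(f"dN/dS: Nd={div.n_count:.1f} Sd={div.s_count:.1f} "
      f"omega={div.ratio:.3f}")

print("A ratio below 1 indicates purifying selection: nonsynonymous "
      "changes are being removed faster than synonymous ones accumulate.")
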