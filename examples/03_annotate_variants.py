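"""Annotate coding consequences and truncation of a nonsense variant.

Projects variants onto transcript models and emits the simplified
single-letter notation used in mapping-study tables: c.31C>T / p.R11* for a
premature stop in codon 11, with the truncation statistics of the product.
"""

from autozyg import (
    SimConfig,
    VariantRecord,
    annotate_best,
    annotate_consequence,
    build_reference,
    cds_to_genomic,
    truncation_stats,
)

config = SimConfig(seed=1)
reference = build_reference(config)
tx = reference.designated

# the planted causal substitution: C>T at spliced CDS position 31
variant = VariantRecord(tx.chrom, cds_to_genomic(31, tx), "C", "T")
cons = annotate_consequence(variant, tx)
retained, full, frac = truncation_stats(cons, tx)

print(f"variant {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} on {tx.id}")
print(f"  class:   {cons.effect_class}")
print(f"  cDNA:    {cons.cdna_notation}")
print(f"  protein: {cons.protein_notation}  (codon {cons.codon_index})")
print(f"  truncation: {retained} of {full} residues retained "
      f"({100 * frac:.1f}% of the product)")
# CGA (Arg) -> TGA (stop) at codon 11 truncates the 1121-residue product
# after its first ten residues: a near-complete loss of the protein.
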