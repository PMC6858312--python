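"""Simulate a small labeled cohort and build its five-group feature matrix.

Prints the matrix shape and the block layout: per-gene mutation counts,
two mutation rates, six substitution-spectrum proportions, 96 trinucleotide-
context signature proportions, and per-gene copy-number log2 ratios.
"""

import oncotyper as ot

config = ot.default_config("tiny")  # 3 cancer types x 30 samples
variants, cnv, labels, truth = ot.simulate_cohort(config)
schema = ot.schema_for(config)
matrix = ot.assemble_matrix(variants, cnv, labels, schema)

print(f"cohort: {len(labels)} samples, {len(variants)} variants, "
      f"{len(labels.labels)} cancer types")
print(f"feature matrix: {matrix.values.shape[0]} samples x {matrix.values.shape[1]} features")
for block in ("profile", "rates", "spectra", "signatures", "scna"):
    sl = schema.block_slice(block)
    print(f"  {block:<10} columns {sl.start:>4}..{sl.stop - 1:>4}")

sample = matrix.samples[0]
rates = matrix.block("rates")[0]
print(f"\nsample {sample} ({labels.mapping[sample]}): "
      f"{rates[0]:.2f} SNVs+indels per Mb, "
      f"{100 * rates[1]:.1f}% of genes mutated")
# The spectra row is a probability vector over C>A..T>G; the dominant entry
# reflects the type's planted mutational signature.
spectra = matrix.block("spectra")[0]
top = max(zip(ot.SPECTRUM_NAMES, spectra), key=lambda t: t[1])
print(f"dominant substitution class: {top[0]} ({100 * top[1]:.1f}% of SNVs)")
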