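"""Simulate a small synthetic NIPT cohort and look at its structure.

Each sample is a set of 40 bp read-start positions drawn from the
maternal/fetal mixture profile; the metadata records the generating ("true")
fetal fraction and the conventional chrY-dosage estimate computed from the
sample's own reads.
"""

import numpy as np

import cfnipt as cf

genome = cf.default_genome()
spec = cf.CohortSpec(n_samples=8, reads_per_sample=100_000, rng_seed=7)
cohort = cf.simulate_cohort(spec, genome)

print("sample      true_ff  ff_chrY  chrY_reads  fetal_locus_reads")
for frags, meta in cohort:
    locus = sum(frags.count_in(iv) for iv in genome.planted_fetal_regions)
    print(f"{meta.sample_id}  {meta.true_ff:7.3f}  {meta.ff_chrY:7.3f}  "
          f"{frags.chrom_count('chrY'):10d}  {locus:17d}")

# chrY reads ~ 0.05 * ff * n_reads, so ff_chrY tracks true_ff; reads in the
# planted fetal-specific loci scale the same way because only the fetal
# profile puts mass there.
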