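"""Generate a synthetic factorial RNA-seq dataset and write it to disk.

The design mirrors a 2x2 cross of leukemic status (non-CML vs CML) and
genotype (wt vs KO): four conditions (wt, KO, CP, BC) with five samples
each, negative-binomial counts, and a 655-gene planted informative set.
"""

import statemi as sm

config = sm.SimulationConfig(seed=1)
dataset = sm.generate_counts(config)
dataset.gene_sets = sm.generate_gene_sets(dataset, n_decoys=2, decoy_size=655, seed=2)
dataset.write("scratch/example_dataset")

print(f"counts: {dataset.counts.shape[0]} genes x {dataset.counts.shape[1]} samples")
print(dataset.annotation.groupby(["leukemic", "genotype"]).size().to_string())
truth = dataset.truth
print(f"planted set: {truth['in_planted_set'].sum()} genes "
      f"({(truth['in_planted_set'] & truth['genotype_responsive']).sum()} responsive "
      f"on the genotype axis)")
print("gene sets written:", ", ".join(dataset.gene_sets.names()))
# The planted set is the 'metabolism-like' informative set the analysis
# should detect; the decoys are size-matched random negative controls.
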