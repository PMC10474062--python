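"""Per-gene mutual information and the set-vs-rest MI-density test.

Expression is discretized into 3 equal-frequency bins fitted on the
pooled centered values of all genes; per gene, I(X:Y) = H(X) + H(Y) -
H(X,Y) in bits measures how much the gene's binned expression tells us
about the condition label. The one-sided rank-sum test asks whether the
planted set's MI distribution is shifted above the remaining genes'.
"""

import statemi as sm

dataset = sm.generate_counts(sm.SimulationConfig(seed=1))
norm = sm.mean_center(sm.normalize_log(dataset.counts))
planted = dataset.gene_sets[sm.PLANTED_SET_NAME]

for contrast in ("CP_vs_BC", "wt_vs_KO"):
    profile = sm.compute_mi_profile(norm, dataset.annotation, contrast)
    b = profile.binning.boundaries
    dens = sm.compare_mi_density(profile, planted)
    print(f"[{contrast}] bin boundaries ({b[0]:.3f}, {b[1]:.3f}); "
          f"median MI set {dens.median_set:.3f} vs rest {dens.median_rest:.3f} bits; "
          f"one-sided rank-sum p = {dens.p_one_sided:.3g}")
# A small p means the planted set is denser in condition information
# than the remaining transcriptome - the synthetic analogue of a
# metabolism gene set distinguishing chronic-phase from blast-crisis
# leukemic stem cells.
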