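"""Marker quality control and IBD allele dosages.

Filters markers on minor-allele frequency and missingness, deduplicates
co-located markers, and computes the expected number of central-parent
allele copies per DH line from the two-state origin HMM (Haldane map
function).  These dosages are the regressors of the parental QTL model.
"""

from mppme import (
    QtlTruth, SimConfig, compute_ibd_all_crosses, dedupe_positions,
    qc_markers, simulate_experiment,
)

exp = simulate_experiment(SimConfig(
    n_parents=4, cross_sizes=50, n_chromosomes=2, chrom_length_cM=80.0,
    marker_density=0.2, n_environments=2, seed=11,
))

geno = qc_markers(exp.geno, maf_min=0.05, miss_max=0.10)
geno = dedupe_positions(geno, exp.gmap)
print(f"{len(exp.geno.markers)} markers simulated, "
      f"{len(geno.markers)} retained after QC")

ibd = compute_ibd_all_crosses(geno, exp.gmap, exp.crosses)
cross = exp.crosses.crosses[0]
res = ibd[cross]
print(f"\ncross {cross} (parents {exp.crosses.cross_parents[cross]}):")
print("expected central-parent allele copies, first 5 lines x 6 markers:")
print(res.p1_copies.iloc[:5, :6].round(3).to_string())
print()
print("Values near 2 mean the line inherited that region from the central")
print("parent, near 0 from the peripheral parent; intermediate values")
print("reflect uncertainty between informative markers. Each line's")
print("central + peripheral copies always sum to 2.")
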