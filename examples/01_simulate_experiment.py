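"""Simulate a NAM multi-environment experiment with a planted QTL.

Builds a small nested association mapping population (3 crosses of DH
lines sharing the central parent P0), phenotyped in two environments
under an augmented p-rep layout, with one QTL acting only in the second
environment.
"""

from mppme import QtlTruth, SimConfig, simulate_experiment

config = SimConfig(
    n_parents=4,            # central parent + 3 peripheral parents
    cross_sizes=50,         # DH lines per cross
    n_chromosomes=2,
    chrom_length_cM=80.0,
    marker_density=0.2,     # markers per cM
    n_environments=2,
    qtls=[
        QtlTruth(
            chromosome=1, position_cM=40.0,
            # allele substitution effects (dt/ha per allele copy) per
            # peripheral parent, [environment 1, environment 2]:
            effects={"P1": [0.0, 8.0], "P2": [0.0, 8.0], "P3": [0.0, 8.0]},
        )
    ],
    seed=11,
)
exp = simulate_experiment(config)

print(f"map: {len(exp.gmap.markers)} markers on "
      f"{len(exp.gmap.chromosomes())} chromosomes")
print(f"population: {len(exp.geno.individuals)} DH lines in "
      f"{len(exp.crosses.crosses)} crosses, central parent "
      f"{exp.crosses.central_parent}")
print(f"plots: {len(exp.plots.data)} across environments "
      f"{exp.plots.environments}")
print()
print(exp.plots.data.head().to_string(index=False))
print()
print("Each plot row carries genotype, cross, environment, replicate,")
print("block, a check flag and the trait value (dt/ha). One third of the")
print("entries are replicated twice; every block contains a check plot.")
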