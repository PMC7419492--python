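"""Full QTL detection with the joint multi-environment model (M3).

Runs the complete procedure — SIM scan, cofactor selection (50 cM
spacing), CIM scan, candidate selection (20 cM spacing), backward
elimination at -log10(p) = 4 — with the parental allele coding under the
compound-symmetry + environment-cross-specific-error covariance.
"""

from mppme import QtlTruth, SimConfig, detect_qtls, simulate_experiment

exp = simulate_experiment(SimConfig(
    n_parents=4, cross_sizes=50, n_chromosomes=2, chrom_length_cM=80.0,
    marker_density=0.2, n_environments=2,
    qtls=[QtlTruth(1, 40.0, effects={"P1": [0.0, 8.0], "P2": [0.0, 8.0],
                                     "P3": [0.0, 8.0]})],
    seed=11,
))

res = detect_qtls(
    exp.gmap, exp.geno, exp.crosses, exp.plots,
    method="M3", allele_model="parental",
)

print(f"cofactors selected from the SIM scan: {res.cofactors}")
print(f"candidate QTLs from the CIM scan:     {res.candidates}")
print(f"\nfinal model after backward elimination "
      f"({len(res.model.qtls)} QTL):")
for q in res.model.qtls:
    print(f"\n  chromosome {q.chromosome} at {q.position_cM:.1f} cM, "
          f"W = {q.wald.W:.1f} on {q.wald.df} df "
          f"(-log10 p = {q.wald.neglog10p:.1f})")
    print(q.effects.round(2).to_string(index=False))
print()
print("Effects are allele substitutions (dt/ha per allele copy) relative")
print("to the central parent, estimated separately per environment. The")
print("planted QTL (chr 1, 40 cM; effect 8 in E2 only) shows near-zero")
print("E1 effects and strong E2 effects — a QTL-by-environment")
print("interaction that an across-environment analysis would average away.")
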