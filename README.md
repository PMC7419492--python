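# mppme

QTL detection in **m**ulti-**p**arent **p**opulations tested in
**m**ultiple **e**nvironments.

Plant-genetics experiments increasingly phenotype nested association
mapping (NAM) populations — many biparental crosses sharing one central
parent — in several environments. The common practice of scanning genotype
means averaged across environments hides QTL-by-environment (QTL×E)
interaction, while separate per-environment scans ignore the genetic
covariance created by scoring the same genotype everywhere. This package
implements a family of mixed-model analyses that treat the multi-parent
and the multi-environment structure jointly, for breeders and
quantitative geneticists working with DH-based NAM or similar
multi-cross designs.

## Models

Four detection methods, each usable with three allele codings
(parental IBD dosages, ancestral haplotype classes, bi-allelic SNP):

* **M1** — QTL scan on genotype BLUEs computed across environments:
  `Ḡ_ic = μ + C_c + x_ia β_a + ε_ic`, with cross-specific error
  variances. Main effects only; QTL×E is invisible.
* **M2** — the same model fitted separately on each environment's BLUEs.
* **M3** — the within-environment BLUE vectors stacked and analysed
  jointly: `Ḡ_ice = μ + E_e + C_ce + x_ia β_ae + GE_ice + ε_ice`, with a
  compound-symmetry (CS) genotype covariance linking environments and
  environment-cross-specific error variances (ECSE).
* **M4** — the one-stage version of M3 on raw plot data, adding random
  replicate and block effects of the augmented p-rep field layout.

The QTL term `x_ia` counts expected allele copies: IBD posteriors from a
two-state origin HMM (Haldane map function) for the parental model,
summed within locally clustered ancestral classes for the ancestral
model, or the SNP minor-allele dosage. Effects `β_a(e)` are deviations
from the central parent's allele. Significance is the Wald chi-square of
the allele block (`n_a − 1` df for main effects, `N_e (n_a − 1)` df for
environment-specific effects); detection uses a SIM scan for cofactors
(≥ 50 cM apart), a CIM scan, greedy QTL selection (≥ 20 cM) and backward
elimination at −log10 p = 4.

When a QTL shows QTL×E, its per-environment effects can be decomposed
against an environmental covariate Z (e.g. precipitation):
`β_ae = β_a + Z_e γ_a + δ_ae`, giving per-allele sensitivities γ and
homozygous allele contrasts `−2(β_a + Z γ_a)` in trait units.

A NAM simulator (Poisson crossovers, no interference; augmented p-rep
layouts; planted QTL effects, optionally covariate-driven) makes the
whole pipeline testable against known truth.

## Worked example

```python
from mppme import QtlTruth, SimConfig, detect_qtls, simulate_experiment

exp = simulate_experiment(SimConfig(
    n_parents=4, cross_sizes=50, n_chromosomes=2, chrom_length_cM=80.0,
    marker_density=0.2, n_environments=2,
    qtls=[QtlTruth(1, 40.0, effects={"P1": [0.0, 8.0], "P2": [0.0, 8.0],
                                     "P3": [0.0, 8.0]})],
    seed=11,
))
res = detect_qtls(exp.gmap, exp.geno, exp.crosses, exp.plots,
                  method="M3", allele_model="parental")
for q in res.model.qtls:
    print(q.chromosome, q.position_cM, round(q.wald.neglog10p, 1))
    print(q.effects.round(2))
```

The planted QTL (chromosome 1, 40 cM, 8 dt/ha per allele copy in E2
only) is recovered one marker away at 50.0 cM with W = 107.9 on 6 df
(−log10 p ≈ 20.3), and the final model prints per-allele
per-environment substitution effects:

```
  allele environment  estimate    se
      P1          E1     -1.49  1.29
      P1          E2      7.17  1.34
      P2          E1      1.92  1.71
      P2          E2      9.53  1.67
      P3          E1      1.80  1.13
      P3          E2     10.06  1.67
```

— E1 effects within two standard errors of zero, E2 effects near the
planted value: the QTL×E pattern that an across-environment analysis
(M1) would flatten into an average of about 4.

The `examples/` directory holds one narrative script per capability
(simulation, marker QC and IBD dosages, stage-one BLUEs, detection,
environmental sensitivity). A thin CLI mirrors the pipeline:
`mppme simulate | qc | ibd | blues | scan | sensitivity`.

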