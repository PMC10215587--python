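# gamcross

Bayesian bivariate gametic models for detecting parent-of-origin
(imprinting) effects on litter size in a reciprocal cross between two
founder populations.

## The problem

When two populations E and R are crossed in both directions (E sire ×
R dam = "ER" sows; R sire × E dam = "RE" sows), differences in the
performance of the reciprocal F1 sows can arise from genomic
imprinting: the same allele combination contributes differently
depending on whether it was transmitted through a sperm or an egg.
`gamcross` quantifies this by modelling, for each founder origin, the
*gametic* effects of transmitted haploid genomes in both roles and
estimating the correlation between their paternal and maternal
versions.  In the absence of imprinting that correlation is 1; a
correlation below 1 is evidence that parental origin matters.

For one litter-size trait (total number born or number born alive) the
records split by cross direction:

```
y_ER = X_ER b_ER + B_ER s_ER + Z_ER p_E + W_ER m_R + e_ER
y_RE = X_RE b_RE + B_RE s_RE + Z_RE p_R + W_RE m_E + e_RE
```

with fixed effects `b` (parity, herd–year–season), permanent sow
environment `s ~ N(0, I σ²_s)` per cross, and per-origin gametic
effects with prior `(p_O; m_O) ~ N(0, V_O ⊗ G_O)`, where

```
V_O = [[σ²_pO, σ_pmO], [σ_pmO, σ²_mO]],     O ∈ {E, R}
```

and `G_O` is the gametic relationship matrix over all of origin O's
gametes, built from phased SNP alleles as `G = M M' / Σ_j q_j(1−q_j)`
with `M[i,j] = x_ij − q_j` (`x` the A2 indicator, `q` the origin
population's A2 frequency).  The paternal–maternal gametic correlation
`r_pm = σ_pm / √(σ²_p σ²_m)` is the target of inference; all
(co)variance priors are flat and the model is fitted by Gibbs
sampling.

The package also provides the supporting stages such an analysis
needs: the SNP QC cascade (call rate → monomorphic → per-population
MAF), consensus voting over multiple haplotype-phasing scenarios, and
a synthetic-data generator that emulates the full study design so the
whole pipeline can be validated by parameter recovery.

## Worked example

```python
import numpy as np
from gamcross import (CrossDesign, McmcConfig, build_design,
                      run_chain, simulate_dataset, summarize)

design = CrossDesign(n_sires_E=10, n_dams_E=20, n_sires_R=10,
                     n_dams_R=25, n_er_sows=60, n_re_sows=60)
data = simulate_dataset(n_founders_E=30, n_founders_R=30, n_snp=500,
                        design=design, seed=1)
GE, GR = data["grm"]["E"], data["grm"]["R"]
print(np.diag(GE.values).mean())          # 1.000 — unit expected diagonal

md = build_design(data["phenotypes"], GE.index, GR.index, trait="tnb")
samples = run_chain(md, GE, GR, McmcConfig(n_iter=20000, burn_in=4000,
                                           thin=10, seed=2))
print(summarize(samples).loc[["sigma2_pE", "sigma2_e_ER", "r_pmE"],
                             ["mean", "sd", "p_gt0"]])
```

Typical output:

```
              mean     sd  p_gt0
parameter
sigma2_pE    0.243  0.209  1.000
sigma2_e_ER  3.970  0.349  1.000
r_pmE        0.084  0.597  0.574
```

`sigma2_pE` is the paternal gametic variance of origin E (generated at
0.206), `sigma2_e_ER` the ER residual variance (generated at 4.296),
and `r_pmE` the paternal–maternal gametic correlation with its
posterior probability of being positive.  At this reduced data size
the correlation posterior is wide — see `docs/methods.md` for what is
and is not identifiable at which scale.

The same pipeline is scriptable from the shell:

```bash
gamcross simulate --seed 1 --out-dir work/
gamcross qc --ped-e work/founders_E.ped --map-e work/founders_E.map \
            --ped-r work/founders_R.ped --map-r work/founders_R.map \
            --out work/qc.json
gamcross consensus work/scenario_*.tsv --min-agree 7 --out work/consensus.tsv
gamcross fit --phenotypes work/phenotypes.csv --grm-e work/grm_E.tsv \
             --grm-r work/grm_R.tsv --trait tnb --seed 2 --out work/samples.csv
gamcross summarize --samples work/samples.csv --out work/summary.json
```

or end to end via `gamcross run --config pipeline.yaml`.

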