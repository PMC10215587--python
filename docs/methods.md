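# Methods

## Model

`gamcross` fits a bivariate gametic model to repeated litter-size
records of F1 sows from a reciprocal cross between founder populations
E and R.  Records are split by cross direction; for one trait,

    y_ER = X_ER b_ER + B_ER s_ER + Z_ER p_E + W_ER m_R + e_ER
    y_RE = X_RE b_RE + B_RE s_RE + Z_RE p_R + W_RE m_E + e_RE

* `b`: fixed effects — parity (5 levels, fifth-and-later pooled) and
  herd–year–season, both per cross, plus a per-cross mean.
* `s`: permanent sow-environment effects, `N(0, σ²_s)` with a
  cross-specific variance, capturing non-genetic covariance among a
  sow's repeated litters.
* `p_O`, `m_O`: gametic effects of origin `O ∈ {E, R}`.  Every gamete
  of origin O — the paternal gamete of each ER sow and the maternal
  gamete of each RE sow for O = E, and conversely for O = R — carries
  *two* latent values, one per parental role, with prior
  `(p_O; m_O) ~ N(0, V_O ⊗ G_O)`:
  `Var(p) = σ²_p G`, `Var(m) = σ²_m G`, `Cov(p, m) = σ_pm G`.
  Only the role matching the gamete's cross is connected to records.
* `e`: residuals with cross-specific variances.

The inferential target is the paternal–maternal gametic correlation
per origin, `r_pm = σ_pm / √(σ²_p σ²_m)`, computed from every stored
draw of `V_O`.  `r_pm = 1` is the no-imprinting expectation; values
below 1 indicate that a gamete's effect depends on the parent that
transmitted it.

### Identifiability of σ_pm

Paternal-role values are observed (through data) only on one side of
the design and maternal-role values only on the other, so σ_pm is
identified exclusively through relatedness between the two sides of
`G_O`: an E-origin gamete in an ER sow informs the paternal role,
and a *related* E-origin gamete in an RE sow informs the maternal
role.  Without cross-side relatives the correlation is structurally
unidentifiable.  This drives both the synthetic design (below) and
the honest expectations for recovery tests.

## Gametic relationship matrices

For each origin, haploid allele vectors of all gametes (ER block
first, then RE, so the cross-side block is contiguous) are centered by
the origin population's A2 frequencies, `M[i,j] = x_ij − q_j`, and

    G = M M' / Σ_j q_j (1 − q_j).

With the generating frequencies this scaling gives `E[diag G] = 1`,
and pedigree expectations are reproduced: gametes transmitted by a
shared parent average 0.50, gametes whose parents are full sibs 0.25
(both audited in the tests and by `scripts/acceptance.py`).  The
coding is invariant to relabelling A1/A2 at any locus.  Frequencies
are estimated from the purebred panels (configurably from pooled
gametes) and clipped away from 0/1 by a floor of 0.01 before entering
denominators.  Positions left unassigned by the phasing consensus are
imputed at the centered mean 0, the unbiased contribution.

## Gibbs sampler

All (co)variance priors are flat; fixed effects have flat priors with
the first parity and first herd–year–season level of each cross
constrained to zero (a per-cross mean absorbs the reference cell —
without it nothing in the model could absorb the phenotype mean).

Full conditionals:

* Location effects: scalar Gaussian conditionals, updated single-site
  (Gauss–Seidel) in a fixed sweep; a `sweep_order="random"` flag
  permutes the order of the three location banks per iteration
  (affects mixing only).  The inner loops are numba-compiled; the
  bookkeeping matrix `Q = G⁻¹ U V⁻¹` is updated incrementally so a
  full gametic sweep costs O(n²) per origin.
* Scalar variances (`σ²_s`, `σ²_e` per cross): scaled inverse-χ² with
  scale = sum of squares and df = n − 2, the flat-prior convention;
  the df offset is configurable (`scalar_dof_offset`).
* `V_O`: inverse-Wishart with scale `S_u = U' G⁻¹ U` and
  df = n_gametes − 3 (flat on `V`); offset configurable
  (`wishart_dof_offset`).  Both conventions are validated against
  brute-force quadrature posteriors on small toys (KS < 0.05 at 50k
  draws) in the test suite.

`G` is Cholesky-factorized with escalating diagonal jitter (×10 steps
from 10⁻¹⁰ to a 10⁻² cap) when numerically singular.  Residuals are
maintained incrementally and recomputed exactly every 500 iterations
to stop float drift.  All randomness flows from one seeded generator,
so runs are bit-reproducible.  Chain defaults (200k iterations, 20k
burn-in, thin 10) are scaled down from the reference analysis's 10M/1M
and further reduced in tests (10–50k) to desk scale.

Degenerate inputs are flagged rather than silently accepted: zero
sums of squares warn and draw from a floor scale, non-PD Wishart
scales get a relative ridge, zero variances make `r_pm` NaN with a
warning, divergence (non-finite or exploding residual variance)
aborts with the iteration number.

## Synthetic-data generator

The generator emulates the structure the model assumes, at the scale
of the motivating study (defaults: 38 E sires × 139 R dams → 203 ER
sows; 38 R sires × 92 E dams → 125 RE sows; variances at the
litter-size magnitudes — gametic ≈ 0.2, permanent environment
0.14/0.36, residual 4.3/4.8, means ≈ 8.8):

* Founder haplotypes are locus-independent Bernoulli(q), with q per
  population uniform on [maf_low, maf_high] (defaults 0.05–0.5).  No
  linkage disequilibrium: the relationship formula uses no map
  information, so linkage is irrelevant to the inference target.
* Gamete transmission is a per-locus uniform pick between the
  parent's two haplotypes (free recombination).
* Sire and dam pools within a founder population overlap by default
  (`share_parent_pools`): a founder can appear as sire of ER sows and
  dam of RE sows.  This is the generator's stand-in for the pedigree
  relatedness between purebred boars and sows in a real herd; it
  creates the cross-side half-sib links that make σ_pm estimable.
  Real purebred panels are sex-separated but related through
  ancestors, which the single-generation founder design cannot
  represent.
* Records per sow are uniform on 3–8 (≈ 5.5 mean, near the study's
  5.6–6.2); the parity of a sow's k-th record is min(k, 5);
  herd–year–season is a uniform categorical (34 levels by default)
  with normal level effects (SD 0.3, as is typical for management
  groups on the litter-size scale).  These distributions are not
  reported in the study; the defaults are stand-ins.
* Gametic effects are drawn from `N(0, V ⊗ G)` with the realized
  genomic `G`, exactly the model prior.  Paternal–maternal gametic
  covariances default to correlation 0.5 — a neutral midpoint between
  the no-imprinting (r = 1) and full-imprinting (r = 0) regimes.
* TNB and NBA are generated independently with their own parameters
  and effects; the model fits them in separate runs.
* QC and consensus fixtures: `corrupt_genotypes` plants disjoint SNP
  subsets that are forced monomorphic, just-below-threshold rare, or
  below the call-rate threshold, returning the per-SNP ground truth;
  `make_phasing_scenarios` swaps parental origin per (sow, SNP) with
  a per-scenario flip rate (swaps are invisible at homozygous loci).

What passing recovery tests on this generator shows: the sampler
correctly inverts the model it states, at study-like magnitudes and
desk-scale sizes.  What it does not show: robustness to linkage
disequilibrium, phasing error surviving consensus, multi-generation
pedigree structure, genotyping error, or selection — none of which
the generator produces.

## QC and consensus conventions

* Filters apply sequentially — call rate < 0.90, monomorphic,
  MAF < 0.05 in population E, then in population R — and each SNP is
  attributed to the first filter it fails, giving a single-fate
  partition of the panel.
* Call rate pools all genotyped individuals (both purebred panels and
  any crossbreds supplied); "monomorphic" means pooled MAF exactly 0,
  distinct from the per-population rare filters.  Whether the original
  analysis included crossbreds in the MAF filters is not stated; here
  it is explicit and configurable.
* Consensus votes per (sow, SNP) on the ordered (paternal, maternal)
  allele pair; the modal assignment is retained iff it reaches
  `min_agree` scenarios (default 7 of 9).  Ties at the threshold are
  dropped and logged.  Similitude between two scenarios is the
  fraction of jointly assigned positions with identical ordered
  assignments; the reported retention is position-level, with a
  SNP-level (retained-in-all-sows) variant alongside, since either
  counting is defensible.

## Posterior reporting

Means, SDs, shortest (HPD) 95% intervals, `P(value > 0)` — the tail
probability used to judge a positive gametic correlation — an
autocorrelation-based effective sample size (arviz bulk estimator)
and a Geweke drift z (first 10% vs last 50%, segment SEs from segment
ESS).  HPD is a reporting addition; the reference analysis prints
only means, SDs and tail probabilities.  Densities are Gaussian-KDE
(Silverman bandwidth, overridable) normalized by trapezoid on a fixed
grid.

## Validation experiments and problem sizes

The test suite runs at sizes chosen for a desk machine:

* Relationship audits: 200 replicate pairs × 1000 loci (MC SE ≈
  0.003); tolerance 3 MC standard errors.
* Conditional-vs-quadrature: 12-record toy, 50k draws, KS < 0.05.
* Parameter recovery: 10 replicates of 120 sows/cross × 800 SNPs,
  10k-iteration chains; 95% HPD intervals must cover each of the 8
  variance components in ≥ 8/10 replicates.
* Correlation identifiability: 60 sows/cross × 500 SNPs at study
  variance magnitudes, 50k-iteration chains, correlation-one truth
  versus a σ_pm = 0 twin.  The ordering of the two posterior means is
  required in every replicate.  Note the *level* of the posterior
  mean under correlation-one truth is information-limited at this
  size: an exact marginal-likelihood calculation (grid posterior of r
  with all other parameters fixed at truth) puts the attainable
  posterior mean at ≈ 0.2–0.5 with residual variance ≈ 4.3, however
  strong the cross-side relatedness; with residual variance ≈ 0.3 the
  same machinery recovers r ≈ 0.8.  The recovery-level test therefore
  documents the full-information target rather than a property this
  data size can exhibit.

## Known limitations

* Single-generation founders; no pedigree-based (expected) gametic
  relationships and no blending with genomic ones.
* Single-site location updates are the only sampler path; a blocked
  (joint mixed-model-equation) update would mix faster on strongly
  confounded designs but is not implemented.
* No REML alternative, no multi-trait covariance between TNB and NBA,
  no locus-level imprinting scans.
* The exact prior-degrees-of-freedom conventions of other Gibbs
  implementations vary; ours are stated above and configurable, and
  conclusions at realistic chain lengths are insensitive to ±1 df.
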