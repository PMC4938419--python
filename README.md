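# hiergst

Hierarchical Bayesian GST partitioning and outlier detection for replicated
population pairs.

## The problem

Local adaptation along repeated environmental contrasts — here low versus
high elevation, sampled as population pairs at several study sites across a
species' range — leaves a signature in locus-specific genetic
differentiation: loci under divergent selection between elevations are more
differentiated than the neutral background, loci under homogenizing
selection less. Detecting that signature across sites requires a model that
separates the replicated elevation effect from the nested neutral structure
(clusters of sites, sub-clusters within clusters) that drift and migration
alone create.

`hiergst` implements a two-step Bayesian scan for diploid bi-allelic SNP
data, together with the forward simulator and power harness used to
validate it, a simplified single-site variant, and an F_IS-corrected
genotype–environment association (GEA) test.

## The model

**Step 1 — allele frequencies and pairwise GST.** Per population *i* and
locus *m*, the reference-allele count follows
n<sub>i,m</sub> ~ Bin(p<sub>i,m</sub>, N<sub>i,m</sub>) with a β(1,1) prior
on p<sub>i,m</sub>; the posterior is the conjugate
Beta(n+1, N−n+1), sampled exactly. Frequency uncertainty is propagated into
Nei's fixation index for every population pair (i,j):

    H_T = (p_i + p_j)(q_i + q_j) / 2
    H_S = p_i q_i + p_j q_j
    G_ST = (H_T − H_S) / H_T

summarised per locus × pair by the posterior median.

**Step 2 — partitioning logit-GST.** A hierarchical linear model
partitions logit(G_ST) into genome-wide and locus-specific effects:

    logit(G_ST(i,j),m) ~ N(mean_(i,j),m , τ_R)
    mean_(i,j),m = μ_G + k_Clus(i,j) μ_Clus + k_SubClus(i,j) μ_SubClus
                   + k_Elev(i,j) (μ_Elev + θ_Elev(m))

where k_Clus, k_SubClus, k_Elev indicate pairs spanning different clusters,
different sub-clusters of one cluster, and different elevations. Priors:
μ_G ~ N(0, τ_G = 10⁻⁴); μ_Clus, μ_SubClus, μ_Elev ~ N(0, τ) with
τ ~ Gamma(0.01, 0.01); θ_Elev(m) ~ N(0, τ_m = 10⁻⁴) under the sum-to-zero
constraint Σ_m θ_Elev(m) = 0; τ_R ~ Gamma(0.01, 0.01). The posterior is
explored by blocked Gibbs sampling (all conditionals are conjugate).

**Outlier calling.** A normal law is fitted a posteriori to the per-locus
posterior medians of θ_Elev; each locus receives a two-tailed probability.
Upper-tail loci at the 1% threshold are candidates for divergent selection
replicated across sites; lower-tail loci sit below the neutral background
(homogenizing selection or rare variants). Detection performance against
simulation truth is scored as FDR = V/R and FNR = T/(m−R).

The single-site model (SBM) drops the structure terms and fits
logit(G_ST,m) ~ N(μ_G + θ_m, τ_R) for one population pair.

## Worked example

Simulate 16 populations (2 clusters × 2 sub-clusters × 2 sites × 2
elevations, N = 200 diploids, 100 loci) with loci 1–5 under divergent
selection at s = 0.5, then run the full scan:

```python
import hiergst as hg

cfg = hg.scenario_from_table2("divergent", 5, 0.5, seed=7)
sim = hg.simulate(cfg)
ds, dropped = hg.filter_monomorphic(sim.dataset)
gst = hg.gst_median_matrix(ds, n_samples=2000, seed=8)
fit = hg.HierarchicalGstModel(gst, sim.hierarchy).fit(
    n_iter=2000, n_burnin=1000, seed=9
)
print(fit.summary().head(8).to_string(index=False))
calls = fit.call_outliers(alpha=0.01)
print("outliers at 1%:", calls.flagged)
pm = hg.score_calls(calls, sim.selected_loci)
print(f"V={pm.V} R={pm.R} T={pm.T} m={pm.m} FDR={pm.fdr} FNR={pm.fnr}")
```

Output:

```
  parameter    median     ci2.5    ci97.5     rhat
       mu_g -5.446513 -5.524446 -5.370604 0.999522
    mu_clus  1.571784  1.497614  1.652719 0.999038
 mu_subclus  1.053173  0.960790  1.132097 0.999752
    mu_elev  0.320748  0.266266  0.380834 0.999283
      tau_r  0.364940  0.355897  0.374043 0.999188
   tau_clus  0.174185  0.000310  2.066713 1.000054
tau_subclus  0.434265  0.000910  4.563550 0.999444
   tau_elev  3.754589  0.005761 41.857917 0.999725
outliers at 1%: ['L001', 'L003', 'L004', 'L005', 'L002']
V=0 R=5 T=0 m=100 FDR=0.0 FNR=0.0
```

The genome-wide medians recover the migration hierarchy (cluster effect >
sub-cluster effect > elevation effect on the logit scale), and the five
selected loci — and only those — are flagged at the 1% threshold, giving
zero false-discovery and false-non-discovery rates.

A command-line interface exposes the same pipeline as verbs
(`hiergst simulate | gst | hbm | sbm | outliers | gea | power | pipeline`);
`hiergst pipeline` writes every artifact plus a machine-readable run
manifest.

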