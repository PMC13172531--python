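# oe-asym

Quantitative pipeline for studying **asymmetric histone inheritance in
olfactory stem cells**. After injury, the quiescent horizontal basal
cells (HBCs) of the olfactory epithelium re-enter the cell cycle, and a
substantial fraction of their divisions partition histones, the fate
regulator p63, and transcriptionally engaged RNA polymerase II unequally
between the two sister-chromatid sets. This package implements the
computational core of that analysis as a tested, reusable library with
matched synthetic-data generators, for researchers quantifying
asymmetric divisions from imaging or paired single-cell RNA-seq data.

## What it computes

**Injury-response ODE model** (`oe_asym.regen_ode`). HBC cell-cycle
fractions H1 (G1), H2 (S), H3 (G2/M) and differentiated-cell abundance
D evolve as

    dH1/dt = -k1 H1 + k3 H3        dH2/dt = k1 H1 - k2 H2
    dH3/dt =  k2 H2 - k3 H3        dD/dt  = k3 H3 - gamma D

with Hill feedback k1 = k_max / (1 + (D/K)^h) and an activation delay
tau after injury. H2 is fitted to p63+/EdU+ time courses by multi-start
least squares (defaults: k_max = 2.27/d, K = 0.4, h = 2,
gamma = 0.06/d, tau = 0.8 d; k2 = 1.33/d and k3 = 6/d fixed by the
measured 18 h S phase and 4 h G2/M).

**Sister-chromatid partitioning mixture** (`oe_asym.division_mixture`).
Per telophase cell, intensities X1, X2 are N(1, sigma) (symmetric, prob.
p_s) or N(1 -/+ p_b, sigma) (asymmetric); the observable is
r = max(X1,X2)/min(X1,X2). Parameters are estimated by the method of
simulated moments against the sample (mean, CV, skewness) of r, and the
bias converts to an RNA Pol II binding-affinity ratio
(1 + p_b)/(1 - p_b).

**Telophase image quantification** (`oe_asym.image_quant`).
Background-subtracted integrated intensity per chromatid set on 16-bit
z-stacks (the ImageJ RawIntDen rule), the 1.5-fold asymmetry cutoff,
division-angle classification (perpendicular 60-90°, parallel 0-30°),
and Spearman rank colocalization.

**Paired daughter-cell expression** (`oe_asym.pair_expression`). QC
(>10,000 genes, ≤5% mitochondrial reads, pairs never split), ERCC
spike-in size-factor normalization, and per-pair fold-ratio asymmetry
calls (ANY queried gene ≥ 1.5-fold).

**Synthetic data** (`oe_asym.synthetic`) generates every input above
with stored ground truth for recovery testing.

See `docs/methods.md` for model assumptions, defaults and numerics.

## Worked example

Simulate 5,000 telophase cells at the fitted mixture parameters and
summarize the ratio distribution:

```sh
$ oe-asym mixture simulate --p-s 0.45 --p-b 0.23 --sigma 0.09 -n 5000 --seed 7 -o ratios.tsv
n=5000 mean=1.385 cv=0.225 skewness=0.623
```

The mean fold difference between sister chromatids is ~1.4 with CV ~0.22
and positive skewness — the right-tailed, bimodal signature of a
symmetric population mixed with ~55% asymmetric divisions. Fitting the
observed statistics recovers the generating regime:

```sh
$ oe-asym mixture fit --mean 1.4 --cv 0.21 --skew 0.58 --seed 1 -o mixfit.json
{
 "p_s": 0.37,
 "p_b": 0.215,
 "sigma": 0.09,
 ...
 "affinity_ratio": 1.5477707006369428,
 "p_asym": 0.63
}
```

i.e. roughly half of divisions are asymmetric with a ~1.5-1.6-fold
RNA Pol II binding-affinity bias toward one chromatid (at the published
point estimate p_b = 0.23 the implied ratio is 1.6, a 60% increase).

Paired daughter-cell calling end to end on a synthetic 48-pair plate
with 15 truly asymmetric pairs:

```sh
$ oe-asym synth pairs --n-pairs 48 --asym-fraction 0.3125 --seed 0 -o pairs
$ oe-asym pairs call --counts pairs/counts.tsv --meta pairs/meta.tsv --genes H3f3a,H3f3b -o calls.tsv
15/48 pairs asymmetric (31.2%, Wilson 95% CI 19.9-45.3%)
```

All 15 planted pairs — and no others — cross the 1.5-fold cutoff after
ERCC normalization. The injury-response trajectory is one command:

```sh
$ oe-asym regen simulate --tmax 7 -o traj.tsv
wrote 141 time points to traj.tsv
```

which holds the basal state (H2 = 6.5%) until tau = 0.8 d and then
peaks in S-phase fraction around day 2, as seen in vivo.

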