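# Methods

This note records the models implemented in `oe_asym`, the assumptions
behind them, the defaults and why, and what the synthetic-data tests do
and do not demonstrate.

## Injury-response ODE model (`oe_asym.regen_ode`)

Horizontal basal cells (HBCs) are partitioned into cell-cycle
compartments: H1 (G1), H2 (S), H3 (G2/M), as fractions of the HBC pool,
plus a differentiated-cell abundance D (arbitrary units):

    dH1/dt = -k1 H1 + k3 H3
    dH2/dt =  k1 H1 - k2 H2
    dH3/dt =  k2 H2 - k3 H3
    dD/dt  =  k3 H3 - gamma D,     k1 = k_max / (1 + (D/K)^h)

Assumptions: every division returns one daughter to G1 and emits one
differentiated cell (so H1+H2+H3 is exactly conserved — the solver
asserts drift < 1e-8); regeneration feedback acts only on the G1->S rate
through a decreasing Hill function of D; injury at t = 0 is followed by
an activation delay tau during which all compartments stay at their
basal values. H2 is the observable compared with p63+/EdU+ fractions.

Defaults (per day unless noted): k2 = 1.33 (S phase 1/k2 ~ 18 h) and
k3 = 6 (G2/M 4 h) are pinned by direct single-cell measurements and held
fixed during fitting; k_max = 2.27, K = 0.4 a.u., h = 2, gamma = 0.06,
tau = 0.8 d are the values estimated from the in vivo EdU time course.
D is dimensionless with K on the same scale (the only anchor for its
units).

The basal initial condition sets H2 to the observed basal S fraction
(6.5%), H3 = (k2/k3) H2 by S->G2/M flux balance, H1 as the remainder,
and D = 0. The H1/H3 split is not directly measured; flux balance is the
state consistent with a quasi-steady basal cycle and the measured phase
durations. It is overridable.

Numerics: adaptive explicit Runge-Kutta (RK45), rtol 1e-8 / atol 1e-10;
the delay is implemented by holding the state on [0, tau) and starting
the integration at tau. Against the closed-form matrix-exponential
solution of the linear (K -> infinity) subsystem the solver agrees to
better than 1e-6.

Fitting: unweighted least squares of model H2 against observed
fractions (a binomially weighted option exists but is off — the data
enter as plain fractions). Multi-start local trust-region least squares:
16 Latin-hypercube starts over k_max in (0, 10], K in (0, 5], gamma in
(0, 2], tau in [0, max observed day]; the Hill coefficient is optimized
over the integer grid {1, 2, 3, 4}. Best objective wins; exact ties go
to the smaller parameter vector. Runs whose near-optimal solutions
disagree grossly in k_max or tau are flagged non-identifiable.

Identifiability caveat: with daily sampling over one week and ~300
scored cells per day, k_max is only weakly identified — it is strongly
collinear with tau (r ~ 0.95) and K (r ~ -0.90), and its linearized
standard error at the default parameters is ~0.85/day (about 37% of
2.27) even for an efficient weighted estimator. The delay tau, by
contrast, is well identified (SE ~ 0.1 d). Recovery tests on synthetic
time courses therefore constrain tau tightly but k_max only loosely;
point estimates of k_max from a single time course should be read with
that variance in mind.

## Sister-chromatid partitioning mixture (`oe_asym.division_mixture`)

At telophase the two sister-chromatid sets of one cell carry intensities
X1, X2 of a quantified signal (histone, p63, phosphorylated RNA Pol II).
A division is symmetric with probability p_s, in which case
X1, X2 ~ N(1, sigma) independently (sigma is technical measurement
noise); otherwise it is asymmetric and X1 ~ N(1 - p_b, sigma),
X2 ~ N(1 + p_b, sigma), where p_b is the binding bias toward one
chromatid. The observable is r = max(X1, X2)/min(X1, X2) >= 1.

Statistics: the summary of a ratio sample is (mean, CV, skewness). CV
uses the population (1/n) standard deviation and skewness the
standardized third central moment g1 = m3 / m2^{3/2}; the n-1 convention
is available as an option. Confidence intervals are percentile
bootstrap over cells (default 1000 resamples). Zero-variance samples
yield CV = 0 and skewness 0 with a degeneracy flag.

Estimation is by the method of simulated moments: candidate parameters
are scored by the squared distance between simulated and target
(mean, CV, skewness), each coordinate standardized by the observed 95%
bootstrap half-widths (0.08, 0.03, 0.45) so the three moments carry
comparable weight. Each candidate is simulated with 5,000 cells reusing
one fixed pool of common random numbers, making the objective a
deterministic, nearly smooth function of the parameters; the search is
a coarse grid (p_s step 0.05 on [0,1], p_b step 0.02 on [0,0.5], sigma
step 0.02 on (0,0.3]) refined once around the optimum (steps 0.01 /
0.005 / 0.005). Candidates statistically indistinguishable from the
optimum that span a wide parameter range trigger a non-identifiability
flag — e.g. a purely symmetric target leaves p_b completely free.

Negative or zero intensity draws (possible since the Gaussians are
unbounded) are redrawn and counted in the simulator; at the fitted
noise level the event has negligible probability (~1e-10), and a redraw
fraction above 1% is treated as an error. Inside the common-random-
number objective such draws are excluded from the statistics instead.

Derived summaries: affinity ratio (1+p_b)/(1-p_b), its percent
increase, and the asymmetric-division probability 1 - p_s.

## Telophase image quantification (`oe_asym.image_quant`)

Integrated intensity follows the standard ImageJ "RawIntDen" workflow
on unscaled 16-bit z-stacks: per slice, the sum of gray values inside
the chromatid-set ROI minus the mean background gray value times the
ROI pixel count, summed over slices. Background is estimated per slice
by default (a global-stack option exists); negative per-slice values
are clamped to zero and counted. ROIs are inputs — the package does no
segmentation; the synthetic generator supplies ground-truth masks.
Coordinates are 0-based (z, y, x).

Asymmetry: ratio = max/min of the two totals; ratio >= 1.5 is called
asymmetric (boundary inclusive — a documented choice; the cutoff is a
configurable constant). The call is scale invariant.

Division angle: computed in the 2D projection plane as the acute angle
between the basal-membrane line and the chromatid-centroid axis;
60-90 deg is perpendicular, 0-30 deg parallel, and 30-60 deg
intermediate (excluded from the two-class tally).

Colocalization: Spearman rank correlation over the shared ROI pixels
(average ranks for ties; 3D over the ROI by default, single-slice ROIs
work identically), +1 / 0 / -1 for perfect / no / inverse
correspondence. Constant channels are flagged undefined.

## Paired daughter-cell expression (`oe_asym.pair_expression`)

QC keeps cells with strictly more than 10,000 detected genes and at
most a 5% mitochondrial read fraction (cells strictly above 5% are
eliminated); a pair losing either member is dropped whole, so
downstream analysis only ever sees complete pairs.

ERCC normalization: every cell receives the same spike-in amount, so
per-cell ERCC totals measure capture/sequencing efficiency. Size
factor = ERCC total / geometric mean of ERCC totals (the geometric-mean
anchor keeps the overall scale stable; a total-ratio variant is
available); normalized value = count / size factor. Normalization is
idempotent and equalizes ERCC totals exactly.

Pair calls: per queried gene (default H3f3a and H3f3b, the two genes
encoding histone H3.3), the ratio is max/min of the two normalized
values. If either member is below one normalized unit a pseudocount of
1 is added to both (dropout protection; configurable); a gene at zero
in both members is undefined for that pair and excluded. A pair is
asymmetric when ANY queried gene reaches the 1.5-fold cutoff (an
ALL-gene rule is available). Summaries report asymmetric/symmetric
fractions with a Wilson 95% interval.

## Synthetic data (`oe_asym.synthetic`)

Each generator emits data in the exact shape its analysis stage
consumes, plus a `SyntheticTruth` record; regeneration from the same
seed is bit-identical.

* EdU time courses: true fractions are the ODE model's H2 sampled daily
  over days 0-7; counts are Binomial(300, fraction) per day — the
  scored-cell design of the in vivo experiment. On this daily grid the
  S-phase peak falls on day 2. (On a dense grid the continuous peak sits
  near day 1.45; daily sampling is what the experiment sees.)
* Ratio datasets: direct draws from the mixture model with latent
  branch labels stored.
* Z-stacks: two separable 3D Gaussian nuclei of prescribed integrated
  intensity (default anisotropic PSF sigma (1.6, 2.2, 2.2) px — z
  coarser than xy, as in confocal stacks) on a constant background of
  100 counts, with Poisson shot noise by default (Gaussian read noise
  and combinations available). Ground-truth masks are 3-SD-per-axis
  boxes holding ~99.2% of the blob mass, so mask truncation biases
  recovered totals by < 1%; the background mask sits beyond 4 SD.
  Values are clipped to 16 bits and >0.1% saturation is an error.
* Pair tables: negative-binomial counts. Query genes default to a mean
  of 2,000 counts with dispersion theta = 500 (CV ~ 5%), the regime of
  deeply sequenced plate-based libraries in which the abundant H3.3
  transcripts are measured precisely; background genes are lognormal
  around ~50 counts. Truly asymmetric pairs (a seeded random subset of
  the requested fraction) get a 2-3-fold split of the query genes in a
  common direction, mean preserved; the rest get splits of at most
  1.2-fold. Per-cell capture efficiencies (lognormal, CV 0.2) scale
  genes and ERCC spike-ins identically; ERCC totals average 5e4 counts,
  so size factors recover capture efficiencies to well under 2%. QC
  metadata emulate ~13,000 detected genes and ~2% mitochondrial reads.

What passing tests show — and do not. The generators reproduce the
*statistical* structure the analyses assume (binomial scoring noise,
Gaussian intensity mixture, Poisson imaging noise, NB counts with a
shared capture factor), with ground truth known. They deliberately do
not emulate real-data pathologies: segmentation error and uneven
illumination in images, transcriptome-wide cluster structure, dropout
bursts, or batch effects. Recovery on these fixtures validates the
estimators' correctness under their own model, not robustness to
model violation.

## Problem sizes

Default analyses run at the study's own scales: 5,000 in-silico cells
per mixture simulation and per moment-matching candidate, 48 cell
pairs, 300 scored cells per day over 8 days, 12 x 64 x 64 z-stacks.
Bootstrap and replicate counts in the test suite (1,000 bootstrap
resamples, 200 coverage replicates, 20 fit replicates) match the
contracts stated in the module documentation.
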