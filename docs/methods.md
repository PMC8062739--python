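# Methods

`sifinet` re-creates, on synthetic data with known ground truth, the
analysis chain of a multisensory-aging MEG study of the sound-induced
flash illusion (SiFi): behavioral scoring and stratification, factorial
cluster-permutation statistics on oscillatory power, transfer-entropy
(TE) network inference, and hierarchical Bayesian comparison of
effective-connectivity models. This note describes the models, the
estimators, the defaults and why they were chosen, and what the
synthetic validation does and does not establish about real data.

## Synthetic data

### Coupled source dynamics

Source activity is a linear vector-autoregressive network with per-link
transmission delays:

    x_i[t] = a_i x_i[t-1] + sum_{j->i} c_ji f(x_j[t - d_ji]) + sigma eps_i[t]

with `f` the identity by default, or the centred square `x^2 - 1` when
`nonlinearity='quadratic'` is requested (to exercise the TE estimator's
sensitivity to non-linear coupling). Stationarity is checked through the
spectral radius of the companion matrix; unstable systems are rejected
with the radius in the message. The analytic stationary covariance
(discrete Lyapunov equation on the companion form) serves as an oracle
for the simulator's output statistics.

The default 8-source ground truth places ten feed-forward links
(strength 0.4, delays 2–8 samples, self-coefficients 0.5, unit noise)
over bilateral auditory (BA22) and visual (BA18) cortex, bilateral
fusiform gyrus (FFG), right middle temporal (MTG) and right middle
frontal gyrus (MFG) — the node set of the illusion network. The graph
is acyclic (spectral radius = 0.5) and deliberately contains two-step
chains and shared drivers, so that a bivariate analysis produces the
cascade and common-drive artifacts the pruning stage is designed to
remove. Trials are independent realizations (burn-in from zero initial
conditions), matching the exchangeability assumption of the
trial-ensemble TE estimator. Defaults: 300 Hz sampling, epochs from
−1.0 to 0.62 s relative to stimulus onset.

Condition-dependent coupling (the generative counterpart of a
modulation/B-matrix) scales selected link strengths on trials labelled
`illusion`.

### Time-frequency experiment

The 2×2 (Age × Propensity) power design adds a band-limited oscillation
(centre frequency of the effect band, random phase per trial) of
cell-specific amplitude in a declared sensor subset and time window, on
top of broadband white noise in all sensors. Sensors sit on a jittered
planar grid so a distance-based adjacency can be built. Power scales
with amplitude squared, giving the ANOVA a known effect location and
size.

### Behavior

Per-trial flash-count responses: on 2 beeps / 1 flash trials the
response is "2" (an illusion) with the group- and SOA-specific
probability; audiovisual control conditions err with a small fixed
probability (default 0.05). Defaults mirror the study design: SOAs
50–500 ms for the behavioral-only task, and in-scanner illusion rates
of 61.8% (young) and 64.7% (older) at the 100-ms SOA. A
between-subject spread (`between_subject_sd`, default 0 for exact
group probabilities; 0.18 in the demo pipeline) produces the
individual propensity differences the median split needs.

## Behavioral scoring and stratification

The illusion rate is the fraction of 2 beeps / 1 flash trials answered
"2"; cells without trials yield NaN with a warning, never a silent
zero. Within each age group, subjects strictly above the group median
rate are labelled PPI (propensity to perceive the illusion), subjects
at or below it PPNI; the tie-at-median policy is conservative toward
"no illusion" (the analysis this mirrors reports no tie rule). Trial-count
equalization between two sets subsamples the larger uniformly without
replacement under an explicit seed.

## Time-frequency statistics

Morlet wavelets with 5 cycles (temporal SD = cycles / (2πf)) truncated
at 3 Gaussian SDs per side, unit-energy normalized; the default grid is
2–60 Hz in 2-Hz steps, and per-trial power is averaged per condition.
Baseline handling: the named baseline interval (−1.0 to −0.5 s) is
applied as relative change (power / baseline mean − 1) before
statistics, switchable off — the original description names the
interval but not a correction formula.

The factorial cluster test computes per-bin F values for the two main
effects and the interaction from an effect-coded Type-III regression,
thresholds at the nominal critical F(1, N−4) at `cluster_alpha`,
clusters suprathreshold bins through the sensor adjacency graph (an
optional lattice extension handles sensor × time × frequency bins), and
sums F within clusters. Null distributions of the maximum cluster mass
come from label permutations: a main effect permutes its own factor's
labels within the levels of the other factor; the interaction uses the
approximate whole-subject permutation scheme (exactness is not claimed
— no exact permutation test for a factorial interaction exists). When
an effect's distinct permutation count is below the requested
Monte-Carlo count, all distinct assignments are enumerated instead.
Cluster p-values use (1 + exceedances) / (1 + permutations). The ANOVA
is run on 12–25 Hz beta power by default; 12–30 Hz is available as
configuration since both bounds appear in the literature the design
follows.

## Transfer entropy

TE from source X to target Y at lag u is the conditional mutual
information I(Y_t ; X_{t−u} | Y_{t−1}), with states reconstructed by
time-delay embedding. Embedding dimension and delay follow the Ragwitz
criterion: minimal mean-squared error of a locally constant
nearest-neighbor one-step predictor. An optional parsimony tolerance
accepts the smallest dimension within `tol` of the best error; the
pipeline uses `tol = 0.25`, preferring minimal states because the
nearest-neighbor CMI estimator loses accuracy quickly with dimension
(and the linear generator's targets need only their previous sample
once a bivariate analysis cannot condition on other parents anyway).

Estimation is the Kraskov–Stögbauer–Grassberger / Frenzel–Pompe
nearest-neighbor form with the maximum norm, k = 4 by default, pooling
state vectors across trials; each series is z-scored first so all
state coordinates share a scale. Estimates are reported as-is — small
negative values are within estimator bias and meaningful only relative
to surrogates. Two neighbor-counting backends produce bit-identical
counts: a kd-tree reference (scipy) and a numba kernel that sorts
points along the conditioning coordinate and sweeps outward (with a
batched variant that shares the sweep across several candidate lags);
the test suite cross-checks them.

The interaction delay δ is the lag maximizing TE over a scanned range
(ties toward the smaller lag; default range 1–15, the pipeline scans
1–8 to cover the generator's 2–8-sample delays with margin below).
Significance against the null of no coupling uses surrogates that
permute the trial assignment of the source series — each trial's
autocorrelation survives, the cross-coupling does not — with
p = (1 + exceedances) / (1 + surrogates).

### Why the network stage splits trials

Testing TE *at the scanned argmax lag* against surrogates evaluated at
that same fixed lag is anticonservative: the observed statistic is a
maximum over lags, the surrogate is not, and on the default generator
this inflates the per-link false-positive rate to roughly 0.35–0.4 at a
nominal 0.05. `subject_network` therefore reconstructs the delay on one
half of the trials and runs the surrogate test at that now-fixed lag on
the held-out half; the selection is independent of the test data and
the permutation test is exact. Measured on the default network (12
subjects' worth of seeds): per-link sensitivity ≈ 0.95–0.98 and a
non-artifact false-positive rate ≈ 0.05 at α = 0.05. The surrogate loop
stops as soon as the p-value can no longer fall below α; p-values on
retained links are exact.

Known limitation: bivariate TE with finite target embeddings produces
systematic non-generative links — cascades (X→Y→Z yields X→Z),
common-drive effects (X→{Y,Z} yields Y→Z or Z→Y), and weaker
reverse-direction links from under-embedded conditioning. These are
expected, retained, and handed to the model-comparison stage.

### Group networks

A link enters a group network when significant in at least
⌈support_fraction × n_subjects⌉ subjects (50% default; at n = 19 the
threshold is 10). Each kept link carries its support count and the
exact one-sided binomial tail P(K ≥ support) under K ~ B(n, 0.5); no
fixed alpha is hard-coded for this tail. PPI and PPNI group networks
are combined by link-set union with provenance flags.

## Model space

For n sources, the unconstrained space holds 2^(n(n−1)/2) structural
models per coupling-sign family — 2^28 = 268,435,456 at n = 8 — which
motivates TE-guided construction. Step 1 emits the full union model,
every single-link deletion, and the PPI-only / PPNI-only variants
(links + 3 models). Step 2 targets the bivariate artifacts: in every
transitive triangle X→Y, Y→Z, X→Z, either X→Z is a cascade artifact or
Y→Z a common-drive artifact — never both, the two explanations being
mutually exclusive — so the model set enumerates all subsets of
candidate links that remove at most one candidate per triangle
(depth-first with early constraint pruning; verified against brute
force). Triangles are catalogued on the union network, and links
removed by step 1 keep counting against each triangle's one-candidate
budget: pruning them first would otherwise dissolve exactly the
triangle that licenses removing a second spurious link. Step 3 fixes
the winning structure and varies which links are percept-modulated
(all-modulated plus one variant per link).

Each structure can be instantiated per coupling-sign family
(excitatory / inhibitory / mixed), implemented as sign constraints on
the fitted couplings. Two details make the family comparison
meaningful rather than vacuous. First, a sign constraint is a
truncated-and-renormalized symmetric prior, worth +log 2 of evidence
per constrained coupling: without this, the mixed family can tie but
never lose to a constrained family, since the hard bound costs
likelihood only when violated. Second, families are compared through
the log marginal evidence of the whole step-1 model set (uniform
within-family model prior, log-mean-exp over models), not through any
single structure: structures still carrying spurious links can
genuinely prefer sign-violating couplings, but the family marginal is
dominated by the well-fitting pruned structures. The pipeline selects
the family first and runs every subsequent BMS within it; on the
default (all-excitatory) generator the excitatory family wins, and an
all-negative generator flips the choice to inhibitory (tested).

In the pipeline, the step-1 single-deletion scan is iterated: while the
winning model is a deletion, the scan restarts from it. A single round
can remove only one artifact, but group TE networks routinely carry
several simultaneously — including reverse-direction links, which form
2-cycles that no acyclic-triangle constraint covers.

## Evidence and model selection

The study design this package mirrors scored models with a
neural-mass dynamic causal model for cross-spectral density; that
machinery is deliberately replaced by a
linear-Gaussian spectral surrogate that preserves the inferential
logic (evidence-based comparison of graph-constrained spectral models)
at desk scale. Per subject and model, the data in the analysis window
(−250 to 75 ms, mean removed per trial) are Fourier-transformed and
restricted to the band (12–25 Hz default); each node's coefficients
are regressed on its own lag-1 phase-shifted coefficients plus one
phase-shifted regressor per incoming link at that link's transmission
delay, with coupling signs bounded by the family. This is an
innovations-form Whittle likelihood in which the band-restricted
log-determinant correction (exactly zero on the full frequency grid)
is dropped, which decouples the fit into tiny per-node least-squares
problems. Two consequences are documented rather than hidden: (i)
band-limited coupling estimates are filtered projections, biased
toward zero relative to the generative coefficients (full-band fits
recover them exactly, and the test suite checks both); (ii) evidence
differences, which all models share the objective for, remain a valid
basis for comparison. Link delays are refined within ±2 samples of the
TE-reconstructed value by greedy residual minimization, because
bivariate delay estimates between embedded network nodes are biased
toward indirect paths. Log evidence is the maximized log likelihood
minus 0.5·k·log(N_eff) (k = free parameters, N_eff = trials × band
frequencies), an information-criterion approximation.

Random-effects BMS fits the standard variational multinomial-Dirichlet
scheme from a uniform prior, returning expected model probabilities,
Monte-Carlo exceedance probabilities (seeded), and the variational
free energy. Group comparison contrasts one shared population
distribution (pooled fit) against independent per-group distributions:
log BF = F_pooled − (F_1 + F_2), positive favoring a shared
distribution. Modulation strengths — illusion minus no-illusion
coupling from per-condition fits on trial-count-equalized halves — are
contrasted between age groups with Welch t-tests, uncorrected across
links by default (a correction option exists but per-link p-values are
reported individually, matching standard practice for these
connection-wise contrasts).

## Pipeline hygiene

TE estimation uses the odd-numbered trials (1-based), model selection
the even-numbered ones, so the exploratory and confirmatory stages
never share data. Every stochastic stage derives its seed from the run
seed via `numpy.random.SeedSequence`; re-running a configuration
reproduces all outputs bit-identically (checksums in the manifest).

## Problem sizes and numerical choices

The validation scale is 12 subjects × 60 trials (8 sources, 487
samples per epoch at 300 Hz), with the TE stage on a −250 to +75 ms
window; the estimator pools every sample of that window (stride
configurable), uses 20 surrogates at α = 0.05 in the network stage
(retention then requires zero exceedances; p = 1/21), and scans lags
1–8. Calibration suites use 100-surrogate tests on 200 white-noise
pairs and 500 null 2×2 experiments at 500 permutations on a 20-sensor
chain. Degenerate inputs fail loudly: unstable generators, all-equal
illusion rates, frequencies at Nyquist, windows outside the epoch,
non-finite evidences, and surrogate counts that cannot resolve the
requested alpha all raise with diagnostics.

## What passing tests do and do not show

The generator is linear-Gaussian with independent trials, white
sensor noise, stationary couplings, and a known acyclic truth. Passing
validation here shows the estimators are correct and calibrated under
these assumptions, and that the pruning-plus-evidence hierarchy can
undo the specific artifacts bivariate TE introduces on such systems.
It does not establish performance under real MEG conditions — volume
conduction and field spread, non-stationarity, 1/f noise,
head-movement artifacts, source-leakage correlations — nor can participant-level
numbers from real cohorts be reproduced here: they depend on raw
recordings that are not publicly deposited and on a different
(neural-mass) generative model.
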