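# Methods

`somnidyn` analyses sleep-stage-resolved thalamo-cortical functional
connectivity in ROI-level fMRI: sliding-window dynamic FC (DFC) inside
stage-pure sleep episodes, mixed-effects stage contrasts under family-wise
error control, and Gaussian hidden-Markov brain states with phasic/tonic
REM identification.  A synthetic whole-night generator with exported ground
truth makes every stage verifiable without access to real recordings.  This
note records the models, the parameters that matter, the numerical choices,
and the design decisions that were genuinely open.

## Data model

A night is one or more runs of T×R BOLD (TR = 3 s by default), a hypnogram
scored on 30-s epochs (Wake, N1, N2, N3, REM, plus Unscored, which is
excluded from every analysis), and a per-TR boolean censor mask (True =
usable frame) produced upstream by motion scrubbing.  The atlas table maps
each ROI to one of 19 networks: 14 cortical networks and 5 thalamic
subnetworks (THAL_DMN, THAL_VIS, THAL_CON, THAL_lSMN, THAL_dSMN, partitioned
2/2/4/2/2 over the 12 thalamic ROIs).  The bundled default atlas is a
60-ROI synthetic reduction with that full network structure; no volumetric
geometry is handled.  ROI indices are 0-based and all TR intervals are
half-open.  Subcortical/cerebellar ROIs can alternatively be (re)assigned to
the cortical network with which they share the strongest mean Fisher-z FC
(ties broken lexicographically, with a warning); by default the atlas's own
assignments are used.

## Episodes and windows

An episode is a maximal run of ≥ `min_epochs` (default 3, i.e. 90 s)
consecutive same-stage epochs.  Sliding windows (30 TR long, step 1 TR —
three scoring epochs, so every window is stage-pure) are placed only inside
episodes and never span run boundaries.  Under the default `drop_any`
censoring policy a window containing any censored frame is discarded; the
`max_frac` alternative keeps windows whose censored fraction is below a
threshold.  `drop_any` is the strictest reading and biases estimates least;
whether the original analysis dropped or repaired such windows is not
determinable, so the choice is exposed as configuration.

## DFC

Each window yields the full ROI×ROI Pearson correlation matrix,
Fisher-transformed (z = atanh r; |r| = 1 is clamped to ±0.999999 with a
warning).  Network-level FC is the mean z over contributing ROI pairs —
between-network entries over all cross pairs, within-network entries over
unordered distinct pairs (undefined for single-ROI networks).  Fisher-z is
applied at the ROI-pair level *before* averaging.  An ROI with zero
variance in a window contributes missing pairs; a window with ≥ 5 % missing
entries is dropped with a log entry.  The intra-thalamic connection is the
mean of the 10 distinct thalamic-subnetwork pair entries (a
diagonal-inclusive variant exists behind a flag).  Stage-average matrices
are computed per participant first and then averaged across participants.
Global-signal regression (per-run OLS of each ROI on the across-ROI mean,
with intercept, estimated on usable frames) is available as a sensitivity
option.

## Synthetic nights

The generator emulates the statistical structure the analysis assumes.

*Hypnogram.*  A semi-Markov chain at epoch resolution: geometric dwell with
stage-specific mean, then a transition with self-transitions forbidden.
REM is disallowed during the first `rem_latency_epochs` (default 30).  The
default chain and dwells (Wake 8, N1 3, N2 16, N3 12, REM 16 epochs) give a
stationary occupancy of roughly 10 % Wake, 6 % N1, 48 % N2, 17 % N3 and
20 % REM with about four REM periods per 320-epoch night, matching the
composition of typical adult nocturnal sleep (REM near a fifth to a quarter
of the night, more frequent later).  `scaled_config()` compresses dwell
means and REM latency proportionally when a shorter night is requested, so
a compressed night keeps the full night's composition and cycle count
rather than its bout durations.

*REM sub-states.*  Within REM, a phasic/tonic chain runs at TR resolution
with sticky defaults (mean phasic segment ≈ 2.5 min), so sub-states form
contiguous segments, as brain states at fMRI timescale do — these are
HMM-style sub-states, not eye-movement bursts.  Two default-on mechanisms
create the identification signatures: the tonic→phasic entry rate follows
a cubic ramp in normalized night time (phasic segments concentrate in the
final third of the night, mean entry rate preserved), and REM episodes that
end while tonic exit to Wake with probability `rem_exit_wake_bias` (0.8)
while phasic-ending episodes never exit directly to Wake (tonic borders
arousal; phasic does not).

*Covariance.*  Per condition (four non-REM stages + phasic + tonic), a
block correlation matrix from four parameters: `r_within` (0.5) for
same-network pairs, `r_between` (0.1) otherwise, overridden by `r_thal`
for cross-subnetwork thalamic pairs and `r_thal_sens` for thalamic ×
sensory-cortical pairs (sensory = VIS, AUD, lSMN, dSMN, CON).  Defaults
rise monotonically: Wake 0.10/0.10, N1 0.15/0.15, N2 0.20/0.20, N3
0.20/0.15, tonic 0.35/0.30, phasic 0.50/0.35.  The phasic thalamo-sensory
value is 0.35 rather than a rounder 0.40 because 0.40 is infeasible for
this block pattern — positive definiteness would require distorting
entries by > 0.05.  PD is enforced by an eigenvalue floor (1e-6) followed
by rescaling to unit diagonal; if that projection moves any entry by more
than 0.05 the coupling is rejected as infeasible.  A non-monotone
phasic/tonic/Wake ordering triggers a warning.

*Signal.*  x_t = a·x_{t−1} + √(1−a²)·e_t with e_t ~ N(0, Σ_cond(t)), so the
stationary covariance inside a same-condition segment equals Σ_cond;
AR(1) (a = 0.5) stands in for hemodynamic smoothing — no HRF convolution,
which windowed correlation and dwell behaviour do not require.  Unit
variances and zero means everywhere: FC analysis is correlation-based and
scale-free, and mean shifts would make state discovery artificially easy.
Measurement noise is iid N(0, 0.2²), which attenuates observable
correlations by 1/(1 + 0.04); the exported ground truth therefore contains
both the latent Σ and the observation covariance Σ + σ²I, and recovery
checks compare against the latter.  Censoring is Bernoulli per TR with
stage-specific rates (Wake 4 % down to N3 1 % — motion is higher awake),
chosen so that a realistic share of 30-TR windows survives `drop_any`.

What the generator does **not** emulate: hemodynamic response shape,
physiological (cardiac/respiratory) structure, spatial autocorrelation,
scanner drift, inter-participant covariance differences, EEG.  Passing
tests therefore show the *pipeline machinery* is correct under the assumed
statistical structure, not that real nights would yield these effect sizes.

## Gaussian HMM

Brain states are a K-state HMM with full-covariance Gaussian emissions
fitted by maximum-likelihood Baum-Welch (scaled forward-backward; exact
log-space Viterbi for decoding).  This is deliberately simpler than the
variational-Bayesian observation model of the HMM-MAR family: only state
decompositions and transition structure are consumed downstream, and those
the ML fit provides equally.  Runs are split at censoring gaps; each
segment re-enters through the initial distribution and no transition spans
a gap.  The covariance M-step adds `reg`·I (default 1e-4).  Convergence is
declared when the per-frame log-likelihood gain drops below `tol` (default
1e-5 nats/frame); the trace must be non-decreasing (relative tolerance
1e-8) or the fit aborts — this is an invariant, not a warning.  K = 21 is
the default for full-scale nights; tests use small K.

*Initialisation.*  Default (`init="windows"`): each usable segment is cut
into 50-frame blocks, each block is described by the Fisher-z upper
triangle of its correlation matrix, the block features are projected onto
their leading 10 principal components and k-means-clustered (seeded);
frames inherit their block's cluster, and means/covariances/transitions are
estimated from that labelling (small clusters are shrunk toward the pooled
covariance).  Restarts perturb by randomly reassigning 20 % of blocks; the
best restart by final log-likelihood is returned.  Plain k-means on frames
(`init="frames"`) is kept for mean-separated problems, but cannot see
covariance-only state differences — with zero-mean conditions it collapses
EM into near-identical states, which is why the window variant is the
default here.

*Preprocessing.*  Two standard options, both exposed in the pipeline
config: temporal prewhitening (per-run removal of the pooled lag-1 AR
component; default on) and PCA reduction before fitting (default 16
dimensions in the pipeline; off at the `fit_hmm` level).  Prewhitening
matters because the emission model assumes conditional independence over
time: with autocorrelated input the likelihood rewards states that absorb
slow fluctuations by splitting the majority stages, and stage structure is
lost.  On AR(1) data the prewhitened innovations are iid within condition,
after which stage-aligned states emerge reliably.  PCA shrinks each state's
covariance from R(R+1)/2 to d(d+1)/2 free parameters, curbing the tendency
of full-covariance ML to spend states on sampling noise.  Because
covariances fitted in whitened/reduced space are not ROI-space FC, the
pipeline computes per-state network FC *empirically* from the decoded
frames in ROI space; `state_network_fc` (from model covariances) remains
for ROI-space fits.

*Labelling and REM sub-states.*  Winner-take-all: each state takes the
stage most frequent among its Viterbi frames (Unscored excluded; ties break
by Wake < N1 < N2 < N3 < REM with a warning).  Among REM-labelled states
(the two with highest occupancy if more than two), tonic is the state with
the largest total transition probability into Wake-labelled states, and
phasic is the remaining state with the latest mean normalized time of
night (per-TR mean; a per-visit median would be an alternative, not
implemented).  If the wake-mass difference is below 1e-4 — less than the
footprint of a single observed transition at these data sizes, i.e. no
evidence — the timing criterion decides alone and the report says so.  If
both criteria point at the same single state, no assignment is made and a
conflict report is returned.

*A structural limit worth knowing.*  At desk scale (≈ 7×10³ frames, 60
ROIs, ~10–15 % REM, K near the number of conditions) the fully unsupervised
fit reliably produces *one* REM-labelled state — the one with the highest
intra-thalamic FC — but essentially never two.  The likelihood genuinely
prefers spending extra states on the N2/Wake bulk: fits initialised at the
ground-truth condition partition retain separate phasic/tonic states and
decode them almost perfectly, yet score thousands of nats below the
EM solutions, so this is a global-optimum property, not a search failure.
Splitting REM sub-states by unsupervised HMM needs the full-scale regime
(many hours of data and K large enough that the majority stages are
saturated, e.g. K = 21).  The sub-state identification rule itself is
validated against ground-truth-constructed models on full-length synthetic
nights, where it is correct in ≥ 90 % of nights.

## Statistics

Stage contrasts: `fc_z ~ stage + (1 | participant)` fitted by REML
(statsmodels MixedLM) on window-level values, Wald z-tests against the Wake
reference.  Window-level observations are serially dependent (step 1 TR);
this follows the source design, and a thinned mode (step = window length)
is available to gauge the impact.  Under the null the Wald test's type-I
error at the default reduced scale is within the 95 % binomial interval of
0.05 (measured 0.043 over 1000 replicates).  A single participant degrades
the random intercept; the model then falls back to OLS with a warning.

Family-wise error: Bonferroni by default over the 190 unique network-pair
tests (19 networks, self-pairs included: 19·20/2), per-test threshold
0.05/190 ≈ 2.63e-4; Holm is available.  When only a subset of pairs is
fitted, the Bonferroni divisor can still be set to the full family size.

Phasic outlier: z = (v_phasic − mean v) / sd(v) over all K states'
intra-thalamic values (K−1 normalization; all-K rather than leave-one-out,
matching the "relative to the average over all states" framing), two-sided
normal p.  Phasic-vs-tonic: Welch two-sample t on per-visit FC estimates
(one Fisher-z value per contiguous Viterbi visit of ≥ 10 TRs); Welch rather
than Student because visit counts are unequal by construction.  Per-visit
rather than per-window or per-participant units keeps the observations
approximately independent while retaining power; per-participant
aggregation is possible from the same outputs.

## Pipeline, sizes, determinism

`run_pipeline` chains generate → segment → DFC → LME/FWE → HMM → sub-state
tests, caches intermediates as TSV/JSON, and is deterministic given the
seed (all randomness flows from numpy `SeedSequence`s derived from it).
The config hash covers exactly the analysis-relevant fields.  Reported
problem sizes in the test-suite and the reproduction script use a
compressed night (6 participants × 1200 TRs, 60 ROIs, K = 6) so a full run
completes in about a minute; the statistical-calibration checks use 1000
reduced-scale replicates.  Degenerate inputs are handled explicitly: nights
without REM complete with REM-dependent outputs absent; stages without
surviving windows are skipped; single-ROI networks yield missing
within-network FC.

## Known limitations

Maximum-likelihood HMM without complexity control (see the structural note
above); no HRF modelling; no autocorrelation-robust standard errors beyond
thinning; Bonferroni is conservative for correlated FC tests; the
generator's ground truth is block-structured and cannot probe
misspecification of the network partition itself.
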