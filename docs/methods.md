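# Methods

## The model

Each channel `j` (an individual bird, or an (individual, call-type) pair)
is modelled as an inhomogeneous Poisson process whose conditional
intensity is driven by the group's recent calling history:

    lambda_j(t) = sigma( b_j + sum_i (K_ij * y_i)(t) )

- `y_i(t)` is channel i's event train (call onsets only; call duration is
  not modelled — self-kernels simply absorb the ~0.1 s a call occupies).
- `K_ij` is the influence kernel from i to j, including the reflexive
  `i = j` entry; a positive lobe means i's calls transiently raise j's
  calling rate, a negative lobe suppresses it.
- `b_j` is a constant base drive; `sigma(b_j)` is j's resting rate.
- `sigma` is monotonic and non-negative. Two link modes are supported:
  **additive** (softplus `sigma(x) = s·log(1+exp(x/s))`; influences add on
  the rate scale and the softplus acts as a soft threshold at zero) and
  **multiplicative** (`sigma(x) = exp(x)`; influences add on the log-rate
  scale). The pairing of link mode and nonlinearity is enforced.

Time is discretised into bins of width `Δ` and per-bin counts are
modelled as Poisson(`lambda_j(t)·Δ`). Convolutions are strictly causal
with a minimum lag of one bin, so an event can never influence its own
bin. Kernels are parameterised as weighted sums of raised-cosine bumps
whose peaks are spaced on a log-warped lag axis (denser at short lags,
where interactions are fastest).

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| bin width Δ | 10 ms | calls last ~100 ms and kernel peaks sit at 150–250 ms, so ≥15 bins resolve the first peak |
| kernel support | 2.0 s | observed structure (self-suppression ~0.8 s, cross-excitation decaying by 0.7 s) fits well inside |
| n_basis | 8 raised-cosine bumps | enough freedom for mixed excitation/suppression shapes without overfitting hour-long sessions |
| first bump peak | support/40 (50 ms) | about the earliest a vocal response can begin; anchoring the first peak here (rather than at one bin) keeps the earliest bump wide enough to be estimable — a 10 ms peak is shorter than a call itself and its near-zero data exposure produced spurious short-lag peaks on no-connection kernels |
| softplus scale s | 0.1 | puts typical base drives (~0.15–0.2 for 12 calls/min) on the near-linear part of the softplus, so additive kernels read directly as excess calling rate in events/s and the threshold only engages for strong suppression |
| ridge penalty α | 1.0 on kernel weights | MAP under a Gaussian prior; fixed rather than cross-validated for determinism. Base drives are unpenalised |
| optimiser | L-BFGS-B, gtol 1e-6, ≤500 iter | the likelihood factorises over receivers, so each receiver's 1+C·B parameters are fitted independently with exact gradients; design columns are RMS-normalised for conditioning |

Initialisation is deterministic (weights zero, base drive at the inverse
link of the empirical rate), so identical data and configuration give
identical fits.

Link selection fits both modes with the same basis and penalty and
compares unpenalised log-likelihoods. The two models have identical
parameter counts, so the odds ratio reduces to a likelihood ratio with
threshold 1; ties go to additive.

## Simulation

The generic sampler iterates the likelihood's own time grid: per bin it
computes the intensity from strictly earlier events, draws a Poisson
count per channel, and places events at bin centres. Simulation and
inference therefore share one discretisation, which makes parameter
recovery exact in the large-data limit. An Ogata-style thinning sampler
is available (`method="thinning"`) to cross-validate the discretisation.

### Chain scenario

Three individuals A → B → C: A is homogeneous Poisson (0.5 events/s);
each A call triggers at most one B call with probability 0.9 at a 0.25 s
delay plus 0.05 s Gaussian jitter (truncated to at least one bin), and
each B call likewise triggers at most one C call. There is no direct
A → C mechanism. The generator is deliberately *not* a member of the GLM
family (at-most-one response, rather than a rate modulation), so the
analysis models compete on even terms. Cross-correlation shows an
indirect A → C artefact near twice the delay; a first-order Markov fit
adds a C → A transition standing in for A's base rate; the fitted GLM
keeps the direct A → C influence small and adds the self-inhibition on B
and C that encodes "at most one response".

### Group scenario

Emulates the captive-group regime the model was designed for: four birds
at 12 calls/bird/min (2880 calls per hour-long session), strong
self-suppression for ~0.8 s after each own call, and excitation by
others peaking at 0.25 s and decaying to zero by 0.7 s; an optional
partner map gives pair-bonded partners their own (typically stronger)
kernel. Config amplitudes are on the rate scale for both link modes; for
the multiplicative link each curve is converted so that a *single*
active kernel produces the same rate profile (with a floor at 5% of the
target rate, since full additive suppression has no finite log-rate
analogue) — the two link modes then differ only in how simultaneous
influences combine, which is exactly what link selection must detect.

Base drives are calibrated so the realised rate hits the target: a
mean-field fixed point (exact if every channel sat at the target rate
and sigma were linear) is refined by up to six damped pilot-simulation
rounds (1200 s pilots, damping 0.6, stop within 4%, keeping the
best-seen drives). The mean-field start alone overshoots because sigma
clips strong self-suppression.

What the generator does *not* emulate: call durations and overlaps,
slow drifts in motivation (time-varying base rates), bout structure
beyond what kernels express, heterogeneous per-bird kernel shapes, and
measurement artefacts (missed or misattributed calls). Passing
recovery tests on this data shows the estimator works when the model
family matches reality; it does not certify robustness to those
unmodelled features.

## Kernel summaries

Fitted kernels are evaluated on a shared 10 ms lag grid and summarised
two ways. Aggregate bands show the pointwise median and 5–95 percentile
range per relation category (self-self / self-partner / self-other).
Dimensionality reduction uses **uncentered** PCA (SVD of the
rows-by-grid matrix without mean subtraction, 2 components kept): the
origin of the projected space then still means "zero influence", so a
kernel's distance from the origin is a scalar influence magnitude, and
a signed magnitude takes the sign of the kernel's globally largest
|value| (excitatory vs inhibitory). Components are sign-fixed so the
largest-|loading| entry is positive, making projections reproducible.
The PCA is fitted pooled across all rows passed in (sessions included);
per-analysis fitting is possible by passing subsets.

## Statistics

- **MRPP** on the 2-D projections: observed statistic is the
  group-size-weighted (n_g/N) mean within-group pairwise Euclidean
  distance; the null permutes labels within strata (we stratify by
  receiver identity so listener effects cancel). p uses the add-one
  estimator (≥ 1/(n_perm+1)); chance-corrected agreement
  A = 1 − δ_obs/mean(δ_perm). An exact mode enumerates all distinct
  within-stratum arrangements on small instances. The implementation is
  cross-checked against `vegan::mrpp` (weight.type 1) in the test suite.
- **Latin-square day matchings**: identity, same-location, and two null
  bijections (cyclic rows of a Latin square distinct from the first
  two); per-matching Pearson correlations of signed magnitudes, with
  self-self and self-other pairs analysed separately since their kernels
  differ in kind. p-values from the t distribution with n−2 df.
- **Segment predictability**: sequential (segment k, k+1) magnitude
  pairs pooled across directed pairs and sessions; a 60 min session cut
  into 15 min segments contributes three sequential pairs.
- **PSTH correlation index**: rate of the receiver's calls inside the
  union of [50 ms, 500 ms] windows after each sender call, divided by
  the receiver's overall rate, minus 1 — so 0 means independence.
  Overlapping windows are merged before measuring occupancy.
- **Markov baseline**: first-order transition MLE on the pooled,
  time-ordered call sequence.

## Numerical choices and degenerate inputs

- Likelihood evaluation is log-sum-exp safe; strongly negative drives
  give tiny positive rates, never zero or NaN. Non-finite objective
  values are replaced by a large constant so line searches back off.
- Half-open binning [kΔ, (k+1)Δ); an event exactly at the session end is
  kept in the final bin. Bins may hold counts above 1.
- Trailing partial segments are dropped by default (balanced segment
  analyses); a flag keeps them.
- Zero-variance inputs: constant magnitudes give a flagged correlation
  with no p; all-identical MRPP points give A = 0 with a warning; a
  receiver with no calls has an undefined (NaN) PSTH index.
- Sparse per-type channels (< 10 events) are fitted but flagged
  low-data, mirroring the high variance expected of such kernels.

## Problem sizes used in validation

The test-suite studies run at the scale the analyses were designed for:
hour-long (3600 s) sessions for recovery and calibration checks, 1800 s
sessions for the 20-replicate link-selection study, 500 replicates for
MRPP calibration. The acceptance script uses 8 replicates per link mode
for selection and 300 replicates for MRPP calibration.

## Known limitations

- The likelihood is the discretised (10 ms) approximation, not the exact
  continuous-time point-process likelihood; simulator and fitter share
  the approximation by construction.
- No hidden states, semi-Markov durations, or time-varying base rates;
  strict sequence lengths ("exactly three calls in a row") cannot be
  expressed.
- The ridge strength is fixed, not tuned; per-dataset cross-validation
  would give better-calibrated shrinkage at the cost of determinism.
- Per-call-type analyses multiply the kernel count by the square of the
  number of types and hit data sparsity quickly.
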