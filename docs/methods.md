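# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `eegconn`, and what the synthetic-cohort tests do and
do not establish about real clinical EEG.

## Signal model and preprocessing

Recordings are treated as channels × samples matrices in microvolts with a
common sampling rate (256 Hz in the canonical setting; configurable).
Analysis operates on contiguous fixed-length epochs (default 20 s), guarded
by a configurable amplitude limit (default 150 µV peak) that stands in for
expert visual artifact screening: an epoch exceeding the limit raises an
explicit, inspectable rejection rather than being dropped silently. No ICA,
regression-based artifact removal or re-referencing is performed.

Band filtering uses a third-order Butterworth band-pass per canonical band
(delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz). "Third order" refers to
the prototype; the default application is zero-phase (forward–backward,
`sosfiltfilt`), which squares the magnitude response and doubles the
effective order. Zero-phase is the default because the phase lag index is
meaningless if the filter itself introduces frequency-dependent phase
shifts; a single-pass mode (`zero_phase=False`) is available when strict
causal-filter fidelity matters. EDF input is decoded with MNE after a raw
header scan that rejects duplicate labels and mixed per-channel rates; EDF
output (synthetic cohorts, fixtures) uses a minimal 16-bit writer with a
symmetric physical range per channel, so round-trip error is bounded by one
quantization step of that range.

## Epoch-based entropy (EpEn)

The EEG trace (or a stacked channel pair, D = 2) is modeled as a
piecewise-stationary process by a continuous left-to-right HMM: state i may
transition only to itself or to state i+1, and each state emits through an
M-component Gaussian mixture. Baum–Welch preserves the structural zeros of
the left-to-right transition matrix, so the fitted model keeps the
topology; the entry state is pinned at state 0. The Viterbi path is
therefore non-decreasing and cuts the series into at most N contiguous
quasi-stationary epochs.

Per-epoch entropy supports two estimators:

* `literal` (default): `H* = -Σ_z p(z) log2 p(z)` summed over the epoch's
  samples with p the state's emission density. This follows the printed
  definition exactly; note that p here is a *density*, so the quantity is
  not a normalized Shannon entropy — it can be negative for sharply peaked
  states and grows with epoch length.
* `rate`: the mean of `-log2 p(z)` per sample, a consistent estimate of the
  epoch's differential entropy rate (for a Gaussian state it converges to
  `0.5 log2(2πeσ²)`, verified at n = 10⁵ within 2%). This is the
  statistically interpretable choice and the one used in monotonicity
  tests.

Densities are floored at 1e-300 before the logarithm. The signal-level
EpEn is the arithmetic mean over visited epochs. For channel coupling one
joint HMM is fitted on 2-D observations with full covariance (the
inter-channel correlation is exactly the signal of interest), giving a
single joint Viterbi path; the two channels' epochs are therefore shared
and have identical boundaries by construction — a model statement, not an
empirical claim about matched-but-unequal epoch durations.

N and M are exposed (`HMMConfig`, defaults N = 10, M = 3) because no
principled universal value exists; all outputs record the values used.
Initialization is deterministic and ordering-aware: states are seeded from
a uniform time partition of the series and each state's M components from
M contiguous sub-blocks of its partition (block means and covariances,
equal weights). This respects the temporal structure the left-to-right
topology encodes, makes fits reproducible without seed juggling, and is
equivariant under exchanging the two coordinates of a coupling pair, which
yields the exact `epen_coupling(x, y) == epen_coupling(y, x)` symmetry.
Covariances are regularized by 1e-6 of the data variance. Degenerate
(zero-variance) inputs are rejected; EM that hits the iteration cap warns
and returns the best iterate. The EM log-likelihood trace is retained and
asserted non-decreasing in tests.

## Classical connectivity measures

**PLI** uses analytic-signal phases with 5% of samples discarded at each
edge (edge transients bias the phase estimate). The statistic is
`|mean(sign(sin Δφ))|`; zero-lag or π-lag coupling gives 0 by construction.

**MSC** is the standard Welch magnitude squared coherence
(`|⟨XY*⟩|² / (⟨|X|²⟩⟨|Y|²⟩)`). A published variant of the formula with
`|⟨X⟩||⟨Y⟩|` in the denominator is dimensionally inconsistent with a
[0, 1]-bounded coherence and is treated as a typo. Defaults: 1-s segments,
50% overlap, Hann window; the band value is the mean over in-band bins.
With a single segment MSC is identically 1 — this degeneracy is preserved
but warned about.

**Spectrogram MI** normalizes the two spectrograms and the magnitude cross
time–frequency distribution to unit mass and evaluates
`Σ Cxy log2(Cxy/(CxCy))` with `0·log(·) := 0`. The grid is restricted to
in-band bins *before* normalization (switchable to broadband). Because
`Cxy` uses `|XY*|`, it does not factorize exactly for independent signals;
the zero-MI property is exact at the distribution level and approximate at
the estimator level. All logarithms are base 2 (bits).

## Graph analysis

Proportional thresholding keeps `round(pt·n(n−1)/2)` strongest
upper-triangle weights (round half away from zero) and binarizes. Ties at
the cut are broken by ascending (row, col) index — deterministic and
recorded; an all-equal matrix triggers a warning since selection is then
purely order-determined. Thresholded graphs are nested in PT by
construction.

The five node-level parameters follow the conventions: clustering and
local efficiency sum over unordered neighbour pairs with the
`2/(k(k−1))` normalization and are 0 for k < 2; local-efficiency distances
are computed in the subgraph induced by the node's neighbours (the node
itself removed); path length averages BFS distances over *reachable* nodes
only (an ∞-propagation mode is selectable), with +∞ flagged for isolated
nodes; betweenness uses the `1/(n(n−1))` ordered-pair normalization, so
the middle node of a 3-path scores 1/3. Shortest-path machinery is
delegated to networkx; normalizations are applied on top and everything is
verified against independent brute-force enumeration in the tests.

## Feature selection

OFR ranks candidate features by squared cosine between the centered
feature and the centered residual output, then projects the output onto
the selected feature's null space and Gram–Schmidt-orthogonalizes the
remaining candidates. Features whose residual norm falls below 1e-10 of
their original norm are collinear with the selection and skipped.

The random-probe stop draws `n_probes` (default 1000) iid standard-normal
probe features; each is ranked alongside the real candidates and the
empirical cdf of the probe's rank is formed (ties count as the probe
winning). A real feature at step k is accepted while `P(probe rank ≤ k) <
risk` (default 0.1). Selection runs per band first, then again on the
pooled survivors, so the final set can mix bands while cross-band
duplicates die by orthogonalization.

A calibration subtlety worth knowing: with a *single* pure-noise candidate
the acceptance probability equals the risk exactly (probability integral
transform of the candidate's correlation). With p exchangeable noise
candidates, however, the first-ranked candidate is the best of p, which a
single probe rarely beats — its rank-1 cdf is 1/(p+1) — so the rule
typically admits a bounded number (≈ `risk·(p+1) − 1`) of noise features
rather than rejecting everything. The tests assert both regimes against
derived expectations; users should read "risk" as a per-step rank
criterion, not a family-wise error rate.

## Classification and evaluation

Two-class problems use a linear SVM (C = 1.0 by default; the value is a
convention, not a fit) with leave-one-out cross-validation by default
(appropriate for cohorts of 50–78 subjects); stratified k-fold is
selectable. Specificity and sensitivity are the recalls of the first and
second class of the comparison respectively. Two evaluation modes are
shipped and labelled in every report: `faithful` selects features on all
data and cross-validates only the SVM — matching protocols that report one
selected feature set, and knowingly susceptible to selection leakage — and
`nested` re-runs the whole two-stage selection inside every training fold.
On pure-noise features, faithful mode exceeds chance while nested mode
stays at it; both behaviours are asserted in the tests. Neither mode
claims to reproduce accuracies published for any unavailable clinical
cohort.

The protocol grid evaluates 9 PT values × feature counts 3–10. The grid
uses the fused ranking (extended, where the probe stop admits fewer than
the requested count, by the plain OFR order of the remaining features) so
every cell is well-defined; the best cell maximizes accuracy with ties
broken by smaller feature count, then smaller PT. Three-class decisions
train one SVM per class pair (each with its own selected features),
calibrate decision values to probabilities by a logistic (Platt) fit, and
couple pairwise posteriors via `Pr(Ci|x) = 1/(Σ_{j≠i} 1/Pr_ij − (K−2))`,
which is an exact inverse on consistent pairwise probabilities and reduces
to the identity for K = 2. Pairwise probabilities at 0 or 1 are clipped to
[1e-6, 1−1e-6] with a warning.

Worked-example reference tables (a 78-subject, 22/28/28 three-group
cohort) are included only where the printed total accuracy is
arithmetically consistent with the printed counts; inconsistent rows are
excluded rather than "corrected".

## Synthetic cohorts

The generator produces band-limited (1–30 Hz) unit-variance Gaussian noise
per channel, scaled to a plausible 20 µV RMS, and injects coupling on
designated pairs. Each mechanism is a positive control for one measure:
`phase_lag` (shared oscillator, fixed offset, default 10 Hz and π/4) for
PLI; `linear_mix` (shared source, variance-preserving mixing) for MSC;
`regime_shared` (common alternating quiet/burst variance schedule,
multiplier 4 at full strength) for joint EpEn. Strength 0 reduces every
mechanism to independent channels; strength 1 is the maximal-coupling
limit (e.g. a pure lagged oscillator pair with PLI → 1). Subjects are
bit-reproducible given (seed, group, index) via seed sequences. The default
three-group layout mirrors realistic memory-clinic sizes (22/28/28) with
coupling strength decreasing across groups.

What this emulates — and what it does not: the cohorts have controllable
coupling, realistic band-limited spectra and class imbalance, but no 1/f
background, volume conduction, eye-blink or muscle artifacts, non-Gaussian
bursts, or electrode-position correlation structure. Passing tests
therefore establish the *correctness and sensitivity* of the estimators
and the pipeline's ability to recover planted structure; they do not
establish clinical effect sizes or diagnostic accuracy on real EEG.

## Problem sizes and numerics

Desk-scale defaults used by the test-suite and the acceptance script: the
end-to-end study runs a 10/12/12 three-group cohort, 8 channels at 128 Hz,
20-s epochs, phase-lag coupling on three disjoint pairs (strengths
0.9/0.5/0.1 by group), PLI + degree features, the full 9 × 8 grid with
nested leave-one-out CV and 50 probe realizations per selection; it
completes in well under a minute on one CPU. Monte Carlo checks use
seed-averaged replicates sized so that 2σ bands are decisive. Other
numerical conventions: density floor 1e-300; collinearity tolerance 1e-10;
covariance regularization 1e-6 of data variance; symmetric matrices
asserted to 1e-9; probe and EM randomness fully seeded.
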