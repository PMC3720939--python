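# Methods

`sigaging` studies *template aging* in on-line (dynamic) signature
verification: the gradual loss of verification performance caused by
long-term changes in a person's signing behavior, as opposed to the
short-term scatter between consecutive samples.  The package provides the
full experimental chain — data model and SVC file I/O, a synthetic
multi-session signature generator with controllable aging drift, three
verification systems, the aging and template-update score protocols,
DET/EER evaluation, and the longitudinal drift statistics (Aging
Coefficient, Variation Coefficient, trend curves, AC-based monitoring).

## Data model

A dynamic signature is the tablet record of one signing act: pen
coordinates `x(t)`, `y(t)` and pressure `p(t)` sampled at a nominal
100 Hz, pressure quantized to 1024 levels; `p = 0` marks pen-up samples.
Files use the SVC plain-text layout (point-count header, one integer row
per sample); a seven-column dialect (`x y t button azimuth altitude
pressure`) and a compact three-column dialect are supported.
Pen-inclination columns are ignored: only coordinates and pressure carry
the modeled information.

The long-term grid mirrors a six-session campaign over 15 months: four
early sessions of 4 signatures (`BID1..BID4`, nominal months 0/2/4/6) and
two later sessions of 15 signatures (`Bure1` month 12, `Bure2` month 15),
each captured as three groups of five (`Bure11/12/13`, `Bure21/22/23`).
That is 46 genuine samples per user; 29 users give 1,334 signatures.
Session months are manifest fields, so other spacings can be declared.

## Synthetic signer model

Each signer is a prototype: 2–4 pen strokes, each a cubic spline through
`complexity + 2` random control points in a unit box, a base duration
drawn from U[2, 4] s, interior pen-ups (zero-pressure gaps of 50–200 ms),
and a smooth positive pressure profile peaking near level 900.  A sample
render adds per-sample jitter (control-point noise, fractional duration
noise, pressure-peak noise).  Prototypes and every render are
deterministic functions of `(user_id, seed)` — seeds fan out through
`numpy.random.SeedSequence`, so adding users or samples never reshuffles
existing ones.

**Aging drift** transforms the prototype *before* jitter — aging is a
systematic trend, not extra noise.  Five mechanisms, each a per-month
rate multiplied by a per-user log-normal scale (`sigma = 0.75`, clipped
to [0.2, 2.5]) that makes aging strongly signer-dependent:

| rate | default | effect |
| --- | --- | --- |
| `alpha_duration` | 0.012 /mo | fractional shrink of total duration |
| `alpha_smooth` | 0.05 /mo | growth of the trajectory smoothing kernel |
| `alpha_detail` | 0.03 /mo | fraction of low-salience stroke control points removed |
| `alpha_penup` | 0.02 /mo | marginal probability that an interior pen-up has merged |
| `alpha_jitter` | 0.12 /mo | growth of all intra-sample jitter scales |

Detail removal ranks a stroke's interior control points by their distance
to the chord of their neighbors and deletes the least salient first; each
point carries a fixed per-signer random threshold, so a given signer's
signature simplifies along one reproducible path.  Pen-up merging works
the same way: each gap has a fixed threshold and disappears for good once
`scale * alpha_penup * month` exceeds it, while marginally over signers
the merge probability is `min(1, scale * alpha_penup * month)` — the
binomial expectation holds across signers, not across renders.  The
jitter growth reproduces the documented property of aged scores being
*more disperse*, not just lower.

Together these produce the canonical simplification trend — signatures
become shorter, smoother (fewer coordinate maxima), with fewer pen-ups,
and faster (path length falls more slowly than duration) — with rates
chosen so the pooled genuine-score mean drops and the EER growth over 15
months land in the few-percent-to-tens-of-percent band reported for real
long-term signature data.  Absolute drift magnitudes are otherwise free
parameters of the emulation.

What the generator does **not** model: biomechanical handwriting
synthesis (delta-lognormal strokes), forgeries, device noise or
quantization artifacts beyond pressure levels, session-level acquisition
effects, or learning/"warm-up" effects inside a session.  Passing tests
on this data therefore demonstrate that the *pipeline* recovers planted
longitudinal structure, not that real signatures behave this way.

## Preprocessing and features

Preprocessing translates the pen-down centroid to the origin, rotates the
principal axis of the pen-down cloud horizontal, and rebases time.  The
180° ambiguity is resolved by the writing direction (start-to-end
displacement along the principal axis made non-negative); the skewness
sign is only used when that projection is below 5% of the width.  The
projection is a width-sized quantity, so jitter cannot flip the
orientation between renditions — a skewness-only rule did exactly that
for near-symmetric signatures and produced catastrophic single-session
mismatches.

Time functions (per-sample signals): `x, y, p, dx, dy, dp, speed,
path_angle, d_angle, log_curv_radius, accel, d_speed`; derivatives are
central differences on the timestamp axis, and every column is z-scored
per signature so Euclidean local distances are comparable.  The HMM uses
a fixed 10-function subset, DTW a 9-function subset; the subsets are
configuration, not re-derived by feature selection.

Global features: 47 scalars with explicit formulas, each labeled
`static` or `dynamic` by a mechanical rule — *dynamic iff the formula
references timestamps or time derivatives*.  Operationally every static
feature is invariant under uniform time rescaling (the same trajectory
replayed faster), which is property-tested.  A few dynamic-labeled ratios
(e.g. the pen-down duration fraction) are also rescaling-invariant; the
label still follows the mechanical rule.  The five interpretable trend
features are always present: duration, pen-up count, maxima counts of
`x` and `y`, average speed.

Tanh normalization maps each feature through
`0.5*(tanh(0.01*(v - mu)/sigma) + 1)` with `mu`, `sigma` estimated from
training data (`sigma` floored at 1e-8).  The verification protocols fit
one normalizer on the *background population* (all users' first-session
signatures); a per-client fallback exists but four samples give an
unusable scale estimate.

## The three verification systems

All matchers expose `train(enrollment) -> model` and
`score(model, test) -> similarity` (higher = more genuine).

**DTW** — symmetric dynamic time warping on the 9-function rows: steps
(1,0) and (0,1) with weight 1, (1,1) with weight 2, Euclidean local cost,
first cell weighted 2, total normalized by `n_a + n_b`.  Joint Euclidean
distance over the function vector is used (not per-function DTW).  The
similarity is `exp(-d_min/d_ref)` with `d_min` the distance to the
closest enrollment reference and `d_ref` the mean pairwise distance among
references — per-user normalization that makes scores poolable across
users; `d_ref` is floored at 1e-6 and set to 1 for single-reference
models.  The dynamic program is verified against exhaustive warping-path
enumeration on small instances.

**GF** — diagonal-covariance Mahalanobis on tanh-normalized global
features: the client model is the enrollment mean and per-feature
variance (floored at 1e-6); the score is the negative Mahalanobis
distance.  Four-to-eight enrollment samples cannot support a full
covariance, hence the diagonal restriction.

**HMM** — a left-to-right GMM-HMM (12 states, 4 diagonal-covariance
mixtures per state; the state count drops to `min_len // 3` for very
short sequences).  Initialization is deterministic given the seed:
uniform segmentation of each training sequence over the states, then
k-means per state.  Baum–Welch (implemented in `sigaging/_ghmm.py`,
forward/backward in log space with numba) runs until the log-likelihood
gain falls below 1e-3 or 15 iterations — with the segmental
initialization the fit is within a fraction of a nat of converged by
then, and a full study trains 145 client models.  Variances are floored
at 1e-3 (on z-scored features).  The score is the per-frame forward
log-likelihood.  The forward pass is cross-checked in the tests against
both brute-force path enumeration and an independent HMM library on
identical parameters.

## Protocols and evaluation

*Aging (A–E):* per user, the model is trained on the 4 first-session
samples; genuine scores come from each later session (BID2, BID3, BID4,
Bure1 = 15 samples, Bure2 = 15 samples).  One impostor set is shared by
A–E: for each target, the designated first sample of each of the six
sessions of every other user (6 × 28 = 168 scores per target at 29
users).  *Template update (F–I):* the test set is always the five Bure13
samples; enrollment is BID1 (F, baseline), Bure11 (G, complete update, 4
samples), BID1+Bure11 (H, mixed, 8), Bure11+Bure12 (I, complete, 8; the
Bure groups hold five samples, the first four enter the template).
Impostors are re-scored against each experiment's model.

DET curves are empirical FAR/FRR step functions over the pooled threshold
sweep (accept iff `score >= threshold`); the EER is read at the first
threshold where FRR ≥ FAR, linearly interpolated between the bracketing
operating points, ties toward the lower threshold.  With 29 users the
genuine sets hold 116–435 scores, so EER differences below one empirical
step (~1/145 for the update experiments) are ties.

## Aging statistics

**Aging Coefficient.**  For one user with an early genuine score set
(experiment A) and a late one (experiment E):

    delta_mu    = (mu_E  - mu_A ) / |mu_A|
    delta_sigma = (s2_E  - s2_A ) / s2_A          (unbiased variances)
    AC          = delta_sigma - delta_mu

so a mean drop and a variance rise both raise the AC; `AC(x, x) = 0`;
denominators are floored at 1e-9; a flag switches the spread term to the
standard deviation.  This reconstruction satisfies the verbal definition
(both degradation modes in one metric, higher = more aged); the exact
published formula is not recoverable, so the definition is exposed as a
swappable hook.  Rankings report the top/bottom-k users by AC, by
`delta_mu` (most affected = largest mean drop) and by `delta_sigma`,
ties broken by user id.

A statistical caveat documented here because it shapes what the package
can demonstrate: with only 4 genuine scores in experiment A, `s2_A` has
3 degrees of freedom and `delta_sigma` is distributed like F(14, 3) - 1
under stationarity — infinite variance, null IQR of roughly [-0.5, +1.9],
95th percentile ≈ 7.7.  Per-user AC values are therefore dominated by
variance-estimation noise unless the true within-user variance changes by
an order of magnitude.  On synthetic data the planted per-user drift
scale is recovered far more faithfully by the mean-drop component alone
than by the full AC; the package reports both.

**Variation Coefficient.**  Per global feature, on tanh-normalized
values: feature values are first averaged across users sample by sample;
`delta_mu_gf` and `delta_sigma_gf` are the relative changes of the mean
and variance of those per-sample cross-user means between the first
(BID1) and last (Bure2) sessions, and `VC = |delta_mu_gf| +
|delta_sigma_gf|` — for feature *stability*, change in either direction
is instability.  Summaries list the ten most/least variable features by
VC and by each component, with static/dynamic counts.

**Trend curves.**  For each feature, a 46-element curve whose j-th entry
is the cross-user mean of the feature on every user's j-th sample in
chronological order; trends are summarized by the least-squares slope
over the sample index.

**AC monitor.**  Over an ordered stream of genuine scores, after every
attempt beyond `2N` the AC between the first `N` scores and the most
recent `N` is computed; an alert fires when it exceeds the threshold and
carries the update strategy recommended for the system (mixed for the
HMM, which needs training data; complete replacement for DTW and GF,
which need recent data).  Defaults: `N = 15`; threshold 1.5, the ~95th
percentile of the AC statistic on simulated stationary Gaussian streams,
giving a ~5% per-evaluation false-alarm rate.

## Numerical and design choices

- DTW step weights (1, 1, 2) with `n_a + n_b` normalization are the
  standard symmetric form consistent with "three correspondences with
  symmetrical weighting".
- Impostor designation "one signature from each session" uses the first
  sample of each session (first group for the split Bure sessions);
  configurable in principle, fixed in the protocols.
- Scores are recomputed per system; nothing is shared across matchers
  except the signatures themselves.
- Maxima are counted on the raw preprocessed series (no smoothing);
  plateaus count once, at the plateau start; series shorter than 3
  return 0 with a warning.
- Degenerate inputs: all-identical point clouds refuse to preprocess;
  zero-variance features normalize to 0.5; constant time-function columns
  stay zero after standardization; generated durations at or below 0.2 s
  are a generation error.
- Problem sizes: the shipped study uses 29 users × 46 samples (~300
  samples per signature at 100 Hz); a full three-system run of both
  protocols takes a few minutes on one core, dominated by the 145
  Baum–Welch fits and ~150k DTW alignments (numba-compiled kernel,
  ~1 ms per pair).

## Known limitations

- The synthetic signer is a spline-and-noise model; its inter-user
  geometry is far better separated than real signatures, so absolute
  EERs are optimistic.  Only qualitative longitudinal structure is
  claimed.
- Per-user AC estimates inherit the 3-df variance noise described above;
  AC-based *rankings* on 4-sample early sessions are intrinsically noisy
  no matter the matcher.
- The global-feature catalog is this package's own (documented formulas,
  same static/dynamic semantics as the classical 100-feature set); it is
  not numerically compatible with any published catalog.
- Real-data ingest is supported through the SVC reader and the manifest,
  but no shipped test depends on external data.
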