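# sigaging

Longitudinal **aging analysis for on-line (dynamic) signature
verification**.  A person's signature is not a fixed trait: over months
it becomes shorter, smoother, faster, with fewer pen lifts — and the
enrollment template a verification system stored at month 0 slowly stops
matching the person who made it.  `sigaging` is a tested pipeline for
studying that drift: it generates (or ingests) multi-session signature
databases, runs three classical verification systems over fixed-template
*aging* protocols and *template-update* protocols, and computes the
longitudinal statistics that quantify who and what is drifting.

Intended users: biometrics researchers and engineers who need a
reproducible testbed for template-aging questions — how fast do error
rates grow, which update strategy helps which matcher, which features
are stable — without access to scarce multi-year signature corpora.

## What is inside

- **Data model + SVC I/O** — 100 Hz `x/y/pressure` series (pressure in
  [0, 1023], zero = pen-up), plain-text SVC files, and a six-session
  manifest spanning 15 months with 46 genuine samples per user
  (4+4+4+4+15+15; 29 users = 1,334 signatures).
- **Synthetic signer generator** — spline-stroke prototypes with
  reproducible per-sample jitter and a controllable, signer-dependent
  aging drift (duration shrink, detail/pen-up loss, smoothing, growing
  motor variability).  The drift is systematic per signer, so aging is a
  trend, not noise.
- **Three verification systems**, all `train(enrollment)` /
  `score(model, test)` with higher = more genuine:
  - *DTW*: symmetric dynamic time warping on 9 time functions, score
    `exp(-d_min/d_ref)`;
  - *GF*: 47 global features, tanh-normalized, diagonal Mahalanobis
    client model;
  - *HMM*: left-to-right GMM-HMM (12 states × 4 mixtures) on 10 time
    functions, per-frame forward log-likelihood.
- **Protocols + evaluation** — aging experiments A–E (enroll on session
  1, test on each later session, shared impostor set) and template-update
  experiments F–I (fixed late test set, varying enrollment); empirical
  DET curves and interpolated EER.
- **Aging statistics** — per-user Aging Coefficient
  `AC = Δσ² − Δμ` (relative variance rise minus relative mean change of
  the genuine scores) with most/least-affected rankings; per-feature
  Variation Coefficient `VC = |Δμ_gf| + |Δσ²_gf|` with static/dynamic
  summaries; 46-point sample-by-sample trend curves; an AC-threshold
  monitoring protocol that recommends an update strategy.

See `docs/methods.md` for the model details, parameter defaults and
known limitations.

## Worked example

```python
import sigaging as sg

# 8 simulated signers, 46 samples each over 15 months, default aging drift
ds, scales = sg.generate_longterm_db(8, sg.default_manifest(8), master_seed=7)
matcher = sg.DTWMatcher()
aging = sg.run_aging_protocol(ds, matcher)    # experiments A..E
for ss in aging:
    mu, var = sg.score_stats(ss)
    eer = 100 * sg.eer_of_scores(ss.genuine_scores(), ss.impostor_scores())
    print(ss.experiment_id, mu, var, eer)
```

prints (seed 7):

```
exp  months  genuine_mean  genuine_var   EER%
  A       2        0.347       0.0025    0.00
  B       4        0.295       0.0077    0.00
  C       6        0.271       0.0087    0.30
  D      12        0.183       0.0134    9.23
  E      15        0.157       0.0101    9.23
```

The fixed month-0 template degrades as the test session moves away in
time: the genuine similarity mean falls monotonically (0.347 → 0.157)
and the equal error rate climbs from 0% to ~9% over 15 months, while the
impostor scores — unaffected by aging — stay put.  Per-user Aging
Coefficients between the earliest and latest score sets then rank
signers by how strongly they drift:

```python
acs = sg.aging_coefficients_from_scoresets(aging[0], aging[-1])
print(sg.rank_users(acs, k=3)["AC"]["most"])    # most affected signers
```

The same study runs from the shell:

```bash
sigaging run --users 29 --seed 1 --out study/     # full A-I x 3 systems
sigaging generate --users 10 --seed 3 --out db/   # SVC files on disk
sigaging evaluate --protocol aging --system dtw --in db/ --report rep/
```

`study/report/` then holds the EER summary, per-user AC tables and
rankings, per-feature VC tables, and the 46-point trend curves.

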