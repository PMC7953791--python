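# Methods

## Model

The ranker is a naive-Bayes classifier over binary IHC results. For a
disease *D* with curated positivities `p_{D,m}` and a panel
`B = {(m_i, b_i)}`, the likelihood is the product of per-marker factors
`f_i = p'_{D,i}` for a positive result and `1 − p'_{D,i}` for a negative
one, where `p' = clip(p, ε, 1−ε)`. Markers are assumed conditionally
independent given the disease; the knowledge base is authored, not fitted.
Posteriors follow `P(D|B) = P(D) L(D) / Σ_j P(D_j) L(D_j)`, computed in
log space with max-subtraction before exponentiation so the normalization
is stable however small the products get. The prior defaults to uniform —
incidence varies so much with population and setting that the method
treats it as uninformative — and an explicit `disease_id → probability`
map is accepted for users who do want incidence weighting.

### Why the clip floor ε

The curation vocabulary includes "never" (0%). Under a literal product a
single positive result on a "never" marker would hard-exclude the disease,
yet atypical profiles are the dominant failure mode of marker-based
diagnosis in practice. Clipping to `[ε, 1−ε]` (default ε = 0.01,
configurable via `RankerConfig.floor`, constrained to (0, 0.5)) turns an
atypical result into a large but finite penalty (log-factor `ln ε ≈ −4.6`)
and keeps every log-likelihood finite.

### Missing profile entries

Most disease/marker pairs are uncurated. The default policy imputes 0.5 —
an uninformative factor — so that diseases with sparse profiles remain
comparable to densely profiled ones on the same number of factors. The
alternative `skip` policy drops untested pairs from the product; it is
available but biased when profile coverage differs between candidates
(a disease with one well-matched curated marker would beat one with nine
good matches and one miss). `n_profiled` reports how many factors were
backed by actual curation, and the tie-break prefers better-evidenced
diseases.

### Two scores

The posterior is relative: it sums to 1 across the differential and
collapses when two profiles are near-identical. The concordance —
`100 · (∏ f_i)^{1/n}`, the geometric mean of the factors on the percent
scale — is absolute: two diseases fitting the panel equally well both show
high concordance. Ranking uses the posterior by default
(`score_mode="concordance"` switches); output reports both.

### Ordering and ties

Descending score, then descending `n_profiled`, then ascending
`disease_id`. The last key makes ranking deterministic; a consequence is
that among exact ties (e.g. duplicated profiles) the lexicographically
first id always takes rank 1.

## Knowledge-base conventions

- Six-term encoding: always 95%, often 75%, in-about-half 50%, seldom
  30%, rarely/occasionally 10%, never 0%; numeric percentage cells are
  accepted directly. Conflicting sources merge by unweighted arithmetic
  mean, with the inputs retained for provenance.
- Display grades bin the percent scale half-open with the top bin closed:
  [75, 100] `++`, [50, 75) `+`, [30, 50) `+/-`, [10, 30) `-/+`, [0, 10)
  `--`. Half-open bins make the mapping total on fractional values (an
  integer-range reading leaves e.g. 74.5% undefined). Files use the ASCII
  labels; pretty output may use the typographic forms (`+/−`, `−/+`, `–`).
  Grade cells decode back to the vocabulary value inside each bin
  (`++`→95%, `+`→50%, `+/-`→30%, `-/+`→10%, `--`→0%); the conversion is
  lossy by construction and only the numeric rendering round-trips (to
  1e-9).
- Antibody names resolve case-insensitively with hyphen/space/slash
  treated as equivalent (and removable) separators, so `TTF1`, `TTF-1`
  and `TTF 1` are one key; canonical names take precedence over synonyms.
  Hyphenation variance is the dominant real-world alias pattern; a
  curated synonym table refines the rest.
- Disease identifiers are opaque curator-supplied keys; no ontology
  binding. `equivalence_group` marks entries that differ only by
  anatomical site.

## Validation protocol

Cases are filtered the way an archive would be curated: prognostic-only
markers (flagged in the registry, e.g. EGFR, p53) are stripped because
they inform outcome rather than origin; a case is excluded if any result
token is inconclusive (fails to parse as positive/negative), if no
diagnostic marker remains, or if fewer than three markers remain. A case
is a *hit* when its ground-truth disease, or any disease in its
equivalence group, appears in the top-k (k = 10) differential. Reports
tally accurate/error counts per disease category and overall; rendered
rates use one decimal place, counts stay exact.

Two datasets are compared with the uncorrected Pearson chi-square on the
2×2 accurate/error table (df = 1, p from the chi-square survival
function). No Yates continuity correction is applied: on the reference
training-vs-validation table (441/121 vs 298/84) the uncorrected test
gives p = 0.8666, matching the value reported for those data, while the
corrected test (p = 0.93) does not. Degenerate tables (a zero margin)
are rejected rather than patched.

`split_dataset` is a seeded uniform shuffle followed by a cut at
`round(n · ratio)`; whether the original 6:4 split was random or
chronological is not documented, so seeded-random is the default and the
seed is part of the call signature.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
any real disease. A `SyntheticSpec` fixes:

- `n_diseases=30`, `n_antibodies=80`, `markers_per_disease=(10, 18)`,
  `specific_markers_per_disease=2` by default — the smallest scale at
  which profiles are simultaneously sparse, overlapping, and coverable by
  realistic panels;
- `panel_size_mean=6.8`, `panel_size_range=(1, 13)` — the reported panel
  statistics of real TUO workups. Panel sizes are drawn as
  `1 + Binomial(12, (mean−1)/12)` clipped to the range: bounded,
  integer-valued, mean-matched, and simple to record in a manifest. No
  dispersion for real panel sizes is documented; the binomial is a stated
  stand-in.
- `atypicality_rate=0.1` — the probability that a sampled result
  contradicts its profile, the tunable analogue of the atypical-profile
  error source that dominates real misdiagnoses. 0.1 is a realistic
  default; the evaluation sweeps 0–0.3.

Profile construction: each disease owns `specific_markers_per_disease`
lineage markers profiled "always" (95%) for it and "never" (0%) in every
other disease — disease-specific means the marker does not stain other
entities, and lineage markers are universally recorded in real curation.
The `markers_per_disease` range governs how many additional markers each
disease profiles from the shared (non-lineage) pool, with values drawn
uniformly from the six-term vocabulary. Any antibody left uncovered is
assigned to one disease so QC sees no dead columns.

Case sampling mirrors how a pathologist composes a workup: the suspected
entity's lineage markers enter first (when panel size permits), then its
graded shared markers, then other entities' lineage markers, finally
unprofiled antibodies (sampled at chance). Results are Bernoulli draws at
the *unclipped* profile value — the generator emulates biology, the clip
floor is an inference device — then flipped with probability
`atypicality_rate`. All generation is deterministic given the spec and
seed (numpy `default_rng` over a `SeedSequence`).

What passing synthetic tests shows — and does not. The simulations verify
the machinery: near-perfect recovery when profiles are distinctive and
noise-free, graceful monotone degradation as results become atypical, and
sensitivity to overlapping profiles (a duplicated profile splits rank 1
and recovers at rank 2). They do not certify performance on real cases:
real marker correlations, the real case mix over organs, and real curation
error are all outside the generator.

## Problem sizes and numerics

The test suite and the acceptance script run simulations at 500 cases per
condition, 20 diseases × 60 antibodies, 3–5 seeds per noise level —
enough for ~1-point Monte-Carlo error on a hit rate, which is the
tolerance the degradation check allows for inversions. Equivalence with
the direct-product oracle is asserted to 1e-9 on knowledge bases up to
6×6; round-trips to 1e-9; mean-merge identities to 1e-12.

## Known limitations

- Conditional independence is assumed, not tested; correlated marker
  programs (e.g. co-regulated cytokeratins) will over- or under-weight
  evidence.
- The knowledge base is authored; nothing here learns positivities from
  labelled cases.
- The concordance score is this package's defined statistic for absolute
  fit; other systems display percentages computed by undocumented rules,
  and no equivalence is claimed.
- Uniform priors ignore incidence; an explicit prior map is supported but
  no incidence table ships.
- The synthetic generator models no marker-marker correlation and no
  realistic organ mix; it is a test harness, not an epidemiological
  simulator.
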