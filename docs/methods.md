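# Methods

## Data model

The unit of analysis is the provider-by-drug claim-count matrix
α ∈ ℕ^{n×m}: α_{i,j} is the number of reimbursed outpatient prescription
claims for drug j attributed to provider i in one year.  Drugs are keyed by
the (brand name, generic name) pair, which is unique in PUF-style releases;
a bare brand name is not a valid key and is rejected.  Identifiers (NPI,
county FIPS, CBSA) are zero-padded text throughout.

**Censoring.**  Public releases suppress small cells: α_{i,j} < t ⇒ 0, with
t = 11 for the 2013 release.  We use the strict rule — a cell exactly equal
to the threshold survives — because summary counts in such releases are
phrased as "≥ t claims".  Censoring is idempotent, monotone (raising t never
increases a cell) and composes (censor at t₁ then t₂ ≥ t₁ ≡ censor at t₂);
all three are property-tested.  Because only censored data are released, all
compositions are computed *after* censoring.  This biases low-volume
providers: their small cells vanish, so their surviving compositions
over-weight their few large cells.  The ≥ 1000-claims filter used before
embedding largely removes this regime.

## Statistics

**Compositions.**  Provider i's profile is Ω_i/Σ_j α_{i,j} (row sums 1).
Class-level profiles sum member-drug counts per provider *before*
normalization, so class totals equal drug totals exactly (conservation is
asserted in tests).  Zero-total rows stay zero rather than NaN.

**Gini index.**  G = Σᵢ (2i − n − 1) xᵢ / (n²μ) with x sorted ascending.
The denominator is n²μ exactly — no (n−1) small-sample correction — because
that is the estimator this analysis tradition reports.  G equals half the
mean absolute pairwise difference over μ; the test suite checks this
identity to 1e-12 on random samples, plus scale invariance.  The CI is a
percentile bootstrap (default 1000 resamples of observations); the interval
is widened to contain the point estimate in the rare tiny-sample corner
where the percentile method excludes it.  All-zero input is an error (μ = 0).

**Cohort split.**  Providers are partitioned at a claims threshold (default
25,000/year, the conventional "high-volume" cut).  The specialty composition
of the two cohorts is compared with a chi-square test on the contingency
table — the source analyses report only "p < 0.001" without naming a test,
and chi-square is the standard choice for composition tables.

**State shares.**  Percent of providers vs percent of enrollees per state,
with an OLS fit and R².  A single-state universe is flagged degenerate
rather than fit.

## Embedding

Compositions (no further variance scaling — the only normalization is by
provider totals) are reduced to 50 principal components, then embedded with
t-SNE: perplexity 40, 300–1500 gradient iterations, Barnes-Hut angle
θ = 0.5.  Exact gradients are used below 2,000 points, where the
tree approximation costs more than it saves and θ is irrelevant.  Because
the objective is non-convex, `n_restarts` (default 5) runs are made with
distinct seeds derived from one master seed, and the run with the minimum
final KL divergence is returned; determinism under a fixed config is
regression-tested.  Perplexity must satisfy p < (n−1)/3 or the call fails
with the feasible bound.  Euclidean distance on the PCA scores is the
affinity metric.

Annotation layers: 2-D histograms whose bin edges come from the full
embedding (so subset panels are comparable and additive), and per-provider
claim-fraction overlays clipped at 15% — single-drug fractions above that
are all "saturated red" in the conventional display.

## Clustering

Ward's minimum-variance criterion on Euclidean distances over the same
composition matrix used for embedding (clustering validates the embedding's
groupings, so both see identical features).  Centroid linkage is available
behind a flag but non-default.  The cluster count is a required input — no
automatic selection is claimed.  Dominance analysis: per cluster, the modal
specialty and its fraction; ties break lexicographically and are flagged;
the summary is the share of clusters with dominance ≥ 0.30.  The
implementation is scipy's linkage; an independent naive Lance-Williams
agglomeration written in the test suite must agree with every flat cut for
n ≤ 12, and the k = 2 cut on a two-pairs fixture must match exhaustive
minimum-variance partition enumeration.

## Regional comparison

Region profiles are claims-per-enrollee vectors: features restricted to
drugs with national claims strictly above a threshold (the national analysis
used "over 100,000 claims", read as strictly greater), region claim sums
divided by Part D enrollee counts.  Distances are d_ij = 1 − r_ij (Pearson
between region rows; values in [0, 2]); zero-variance rows are an error
naming the region.  Classical (Torgerson) MDS — double-center the squared
distances, eigendecompose, keep the top-k coordinates — is hand-implemented
because scikit-learn's MDS is SMACOF, not classical.  Negative eigenvalues
(1 − r is generally non-Euclidean) are truncated with a warning; distance
recovery on genuinely Euclidean inputs is tested to 1e-9.

**Permutation null.**  Provider-region labels are permuted (exactly
preserving per-region provider counts), the full profile → distance → MDS
pipeline is recomputed, and each permuted configuration is aligned to the
real one by orthogonal Procrustes (MDS is defined only up to rotation/
reflection; no scaling is applied, since the null's smaller spread is the
signal).  The dispersion summary is the mean distance of region points from
their centroid.  The default is 100 permutations — enough to place a 95th
percentile, cheap enough for a laptop.  Calibration is tested both ways: a
generator with planted regional effects puts the real dispersion above the
null's 95th percentile, and an effect-free generator puts it inside the
central 95%.

**Fold comparison.**  For two regions, features whose rate ratio exceeds a
fold (default 5) are flagged.  Features with a zero rate in either region
are excluded by default — they cannot be drawn on the log-log panel — with a
pseudocount option to retain them.

**Distance correlation.**  State-level mean prescribing vectors and mean
disease-prevalence vectors (13 chronic conditions in the motivating data)
each yield a Euclidean distance matrix; R² is the squared Pearson
correlation over the upper-triangle pairs — the standard Mantel-style
statistic.  The motivating analysis attributes its R² to "analysis of
variance" without details; squared Pearson over unique pairs is the
defensible reading and is what is implemented.  No permutation p-value is
attached (the source reports none).

**Mann-Whitney U.**  Exact null when the combined sample is ≤ 20 and
tie-free; tie-corrected normal approximation otherwise.  The exact branch is
verified against full enumeration of label assignments, and the asymptotic
branch against a type-I-error simulation.

## Synthetic generator

The generator emulates the release's salient structure with known ground
truth:

| parameter | default | rationale |
|---|---|---|
| volume model | log-normal(μ=6.2, σ=1.2) | median ≈ 500 claims/yr, heavy right tail past 25,000 — the shape of real annual provider volumes |
| specialty profile | Dirichlet, concentration 2.0 on a preferred drug block, 0.02 elsewhere | draws resemble the specialty's mean profile with realistic provider-level variability; specialties are recognizable, which is the phenomenon under study |
| regional effect | multiplicative per-drug, log-normal sd 0.3 | simplest mechanism producing region-level profile divergence |
| mixed practices | 10% of providers, 50/50 mixture of two specialty draws | mixed scopes of practice exist but no quantitative model is available |
| censor threshold | 11 | the released rule |
| disease linkage | optional linear map (log scale) from region prevalence to drug effects | gives the distance-correlation analysis a tunable ground truth |

Per provider: specialty ~ categorical(weights), region ~ categorical(shares),
θ ~ Dirichlet(α_specialty) (mixed: average of two draws), θ ∝ θ × region
effect, total ~ log-normal, counts ~ Multinomial(total, θ), then censoring.
Identical seeds give bit-identical output (SeedSequence-derived streams).

What the generator does **not** emulate: drug costs and day-supply,
beneficiary demographics and case mix, provider networks, within-region
spatial structure, real per-specialty profile parameters (no public
calibration exists — presets are illustrative), and the empirical
correlation between volume and diversity beyond what the volume model
induces.  A green recovery test therefore establishes that the pipeline
detects the planted mechanism at realistic noise, not that real data carry
that mechanism.

## Numerical choices and degenerate inputs

- Distance matrices are symmetrized ((d + dᵀ)/2) and clipped to [0, 2]
  to absorb floating-point asymmetry before validation at 1e-12.
- Composition rows are validated to sum to 1 within 1e-9.
- `drop_empty` on an all-zero matrix returns an empty matrix with a warning
  rather than an error; an empty cohort in the HV/SV split skips the test
  with a warning.
- In the permutation null, a region that loses all providers under a
  permutation (possible only in tiny populations) re-enters the aligned
  cloud at the origin.
- PCA requests beyond min(n, d) retain what exists, with a warning.
- All stochastic stages accept explicit seeds; the pipeline derives stage
  seeds from one global seed via `numpy.random.SeedSequence`.

## Known limitations

- Post-censoring compositions are biased for low-volume providers (above).
- The 1 − r distance treats regions with proportional profiles as identical
  even when absolute per-enrollee rates differ; the fold comparison is the
  complementary absolute view.
- Classical MDS coordinates are reported in the top-2 plane even when the
  distance matrix supports fewer positive eigenvalues (zero-padded, with a
  warning) — with very few regions the second axis can be vacuous.
- t-SNE hyperparameter sensitivity is exposed (any perplexity/PCA-dims list
  can be swept by the caller) but no canonical grid is asserted.
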