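# rxscape

Prescribing-pattern landscape analysis for privacy-censored provider-by-drug
claims matrices.

## The problem

National outpatient prescription claims releases (Medicare Part D public use
files and their counterparts) record, for every provider and every drug, the
annual number of reimbursed claims — a provider-by-drug matrix with on the
order of 10⁶ providers and 10³ drugs.  Small cells are censored for privacy
(counts under 11 are zeroed), volumes are heavy-tailed over several orders
of magnitude, and the matrix is sparse.  Researchers in pharmacoepidemiology
and health-services research use these data to ask: do providers cluster by
prescribing pattern, does that clustering recover the specialty taxonomy,
and how much does prescribing vary between regions once enrollment is
accounted for?

`rxscape` implements that analysis as a tested, reusable library:

- **Ingest** — read/write the three PUF-shaped tables (provider, drug,
  provider-drug long format), apply the censoring rule (cells `< t` → 0,
  default `t = 11`; a cell equal to `t` survives), trim empty rows/columns,
  and link providers to metropolitan regions (CBSAs) via a county-FIPS
  crosswalk.
- **Profiles** — per-provider feature vectors Ω_i = {α_{i,1}, …, α_{i,m}}
  at drug or drug-class level, normalized to compositions (row sums 1);
  diversity/volume distributions; Gini concentration index

  G = Σᵢ (2i − n − 1) xᵢ / (n² μ),  x₁ ≤ … ≤ xₙ,

  with a percentile-bootstrap CI; high-volume cohort splits; state
  provider-share vs enrollee-share regressions.
- **Embedding** — PCA pre-processing (50 dims) then t-SNE (perplexity 40,
  Barnes-Hut θ = 0.5 above 2,000 points, exact gradients below), several
  restarts with derived seeds, minimum-KL-cost run selected; density maps
  and per-drug claim-fraction overlays (color capped at 15%).
- **Clustering** — agglomerative clustering with Ward's minimum-variance
  criterion on Euclidean distances; per-cluster dominant-specialty analysis
  and cluster × region composition tables.
- **Regional** — region × drug claims-per-enrollee profiles (features
  filtered by national claim volume), correlation distances
  d_ij = 1 − r_ij, classical MDS, a permutation null that shuffles
  provider-region memberships while preserving per-region provider counts,
  pairwise region fold-difference comparison, and the Mantel-style R²
  between state prescribing-pattern distances and disease-prevalence
  distances.
- **Synthetic populations** — a generator with planted ground truth
  (Dirichlet specialty profiles, log-normal volumes, multiplicative regional
  effects, mixed practices, censoring, optional disease-prevalence linkage)
  so every stage is testable without the CMS download.

## Worked example

`examples/04_clustering.py` generates 800 providers over 5 planted
specialties, clusters their censored compositions, and prints:

```
Cut the Ward tree into 20 clusters.
95% of clusters have one specialty accounting for >= 30% of their providers.

Largest clusters:
            size dominant_specialty  dominant_fraction
cluster_id
3            143        Specialty_A           0.986014
11           138        Specialty_C           0.992754
7            125        Specialty_D           1.000000
```

Reading: unsupervised clustering of prescribing compositions recovers the
planted specialty structure — 19 of 20 clusters are dominated (≥ 30% of
members) by a single specialty, most of them almost pure.  The analogous
statistic on the real national release is the headline of this kind of
analysis.  `examples/02_profiles_and_gini.py` prints the Gini indexes of
per-drug vs per-class claim totals (0.159 vs 0.067 on its fixture):
aggregating drugs into classes always evens out the distribution.  The other
examples cover ingest round-trips, t-SNE embedding quality, regional MDS
with its permutation null, and the full pipeline with figures.

## Acceptance script

`scripts/acceptance.py` exercises the complete pipeline end-to-end on a
seeded synthetic population — generation with censoring, ingest, profile
statistics (diversity, Gini), PCA + t-SNE embedding with restart selection,
Ward clustering with dominance analysis, and the regional MDS permutation
null — and writes its JSON result:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope

The package analyzes data shaped like the 2013 Medicare Part D prescriber
release but ships no CMS data; dataset-level figures from the national
analysis (e.g. 808,020 active providers) require the public download and are
out of scope for the test suite, which instead verifies every statistic
against independent oracles and planted-structure recovery (see
`docs/methods.md`).
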