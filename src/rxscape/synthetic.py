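"""Synthetic claims populations with planted, recoverable structure.

Real Part D prescriber files cannot ship with a package, so every downstream
stage is exercised on generated populations whose ground truth is known.
The generative model mirrors the salient features of the real release:

* **Specialty profiles.**  Each specialty has a Dirichlet concentration
  vector over drugs; a provider's expected composition is a draw from their
  specialty's Dirichlet.  Low concentration (default 0.1 on a specialty's
  preferred drug block) produces the sparse, spiky per-provider profiles
  seen in claims data.
* **Volume skew.**  Per-provider total claims are log-normal; empirical
  claim-volume distributions are heavy-tailed over several orders of
  magnitude.
* **Regional effects.**  Each region carries a multiplicative per-drug
  effect applied to the provider's profile before renormalization, so
  providers of the same specialty prescribe systematically differently
  across regions.
* **Mixed practices.**  A configurable fraction of providers draw a 50/50
  mixture of two specialty profiles.
* **Censoring.**  Cells below the privacy threshold (default 11) are zeroed,
  exactly as in the released files.
* **Disease linkage.**  Optionally, per-region disease-prevalence vectors
  perturb the drug profile through a linear map (log-scale), so the
  prescribing-distance vs prevalence-distance correlation has a tunable
  ground truth.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ClaimsMatrix, make_drug_index
from .errors import ValidationError
from .io import apply_censoring, write_puf_tables  # noqa: F401  (re-export)

_STATE_POOL = [
    "MA", "NY", "PA", "FL", "IL", "TX", "MO", "CO", "CA", "WA",
    "GA", "OH", "MN", "OK", "NC", "AZ", "VA", "TN", "WI", "OR",
]


@dataclass
class SpecialtySpec:
    """One specialty: its name, population weight, and Dirichlet profile."""

    name: str
    weight: float
    concentration: np.ndarray  # length n_drugs, all > 0

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if (self.concentration <= 0).any():
            raise ValidationError(
                f"specialty {self.name!r}: Dirichlet concentration must be > 0"
            )
        if self.weight < 0:
            raise ValidationError(f"specialty {self.name!r}: weight must be >= 0")


@dataclass
class RegionSpec:
    """One region (CBSA-like): share of providers and per-drug effect."""

    name: str
    share: float
    effect: np.ndarray  # length n_drugs, multiplicative, all > 0
    state: str = "XX"
    county_fips: str = "00000"

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=float)
        if (self.effect <= 0).any():
            raise ValidationError(f"region {self.name!r}: effects must be > 0")
        if self.share < 0:
            raise ValidationError(f"region {self.name!r}: share must be >= 0")


@dataclass
class SimulationConfig:
    """Full description of a synthetic claims population.

    ``volume_model`` is the (mu, sigma) of the log-normal over per-provider
    total claims.  Defaults (6.2, 1.2) put the median near 500 claims/year
    with a heavy right tail reaching past 25,000 — the shape of real annual
    Part D provider volumes.
    """

    n_providers: int
    n_drugs: int
    n_classes: int
    specialties: list[SpecialtySpec]
    volume_model: tuple[float, float] = (6.2, 1.2)
    regions: list[RegionSpec] = field(default_factory=list)
    mixed_practice_fraction: float = 0.0
    censor_threshold: int = 11
    enrollees_per_region: dict[str, int] = field(default_factory=dict)
    disease_link: np.ndarray | None = None  # (n_drugs, n_diseases)
    n_diseases: int = 13
    disease_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_providers", "n_drugs", "n_classes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.censor_threshold < 0:
            raise ValidationError("censor_threshold must be >= 0")
        if not 0.0 <= self.mixed_practice_fraction <= 1.0:
            raise ValidationError("mixed_practice_fraction must be in [0, 1]")
        if not self.specialties:
            raise ValidationError("specialties must be non-empty")
        w = sum(s.weight for s in self.specialties)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"specialty weights sum to {w}, expected 1")
        if self.regions:
            s = sum(r.share for r in self.regions)
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"region shares sum to {s}, expected 1")
        for spec in self.specialties:
            if len(spec.concentration) != self.n_drugs:
                raise ValidationError(
                    f"specialty {spec.name!r}: concentration length "
                    f"{len(spec.concentration)} != n_drugs {self.n_drugs}"
                )
        for reg in self.regions:
            if len(reg.effect) != self.n_drugs:
                raise ValidationError(
                    f"region {reg.name!r}: effect length != n_drugs"
                )
        if self.disease_link is not None:
            self.disease_link = np.asarray(self.disease_link, dtype=float)
            if self.disease_link.shape != (self.n_drugs, self.n_diseases):
                raise ValidationError(
                    "disease_link must have shape (n_drugs, n_diseases)"
                )


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    specialty: pd.Series  # npi -> specialty label
    region: pd.Series  # npi -> region label
    uncensored: ClaimsMatrix
    region_effects: pd.DataFrame  # region x drug multiplicative effects
    region_prevalence: pd.DataFrame  # region x disease prevalence (percent)
    mixed_with: pd.Series  # npi -> second specialty, or None


def default_config(
    n_providers: int = 1000,
    n_drugs: int = 60,
    n_classes: int = 12,
    n_specialties: int = 4,
    n_regions: int = 3,
    *,
    specialty_concentration: float = 2.0,
    baseline_concentration: float = 0.02,
    region_effect_sd: float = 0.3,
    mixed_practice_fraction: float = 0.1,
    censor_threshold: int = 11,
    volume_model: tuple[float, float] = (6.2, 1.2),
    disease_linked: bool = False,
    disease_effect_scale: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """Build a reasonable planted-structure configuration.

    Each specialty prefers a contiguous block of drugs (concentration
    ``specialty_concentration`` there, ``baseline_concentration`` elsewhere).
    The default of 2.0 per preferred drug gives a total concentration of
    ~2 x block size, so provider draws resemble their specialty's mean
    profile with realistic provider-to-provider variability — specialties
    have characteristic, recognizable patterns.  Setting it well below 1
    instead yields spiky, near-single-drug profiles where providers of the
    same specialty barely resemble each other.  Region effects are i.i.d.
    log-normal per drug with log-sd ``region_effect_sd``.  When
    ``disease_linked`` is True a random linear map ties each region's
    disease-prevalence vector to a log-scale drug-profile perturbation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1CE]))
    block = max(1, n_drugs // n_specialties)
    specialties = []
    for s in range(n_specialties):
        conc = np.full(n_drugs, baseline_concentration)
        lo = (s * block) % n_drugs
        conc[lo : lo + block] = specialty_concentration
        specialties.append(
            SpecialtySpec(name=f"Specialty_{chr(65 + s)}", weight=1.0 / n_specialties,
                          concentration=conc)
        )
    regions = []
    enrollees: dict[str, int] = {}
    for r in range(n_regions):
        effect = np.exp(rng.normal(0.0, region_effect_sd, size=n_drugs))
        name = f"R{r + 1:02d}"
        regions.append(
            RegionSpec(
                name=name,
                share=1.0 / n_regions,
                effect=effect,
                state=_STATE_POOL[r % len(_STATE_POOL)],
                county_fips=f"{10000 + 10 * r:05d}",
            )
        )
        enrollees[name] = int(rng.integers(50_000, 200_000))
    disease_link = None
    if disease_linked:
        disease_link = rng.normal(0.0, disease_effect_scale, size=(n_drugs, 13))
    return SimulationConfig(
        n_providers=n_providers,
        n_drugs=n_drugs,
        n_classes=n_classes,
        specialties=specialties,
        volume_model=volume_model,
        regions=regions,
        mixed_practice_fraction=mixed_practice_fraction,
        censor_threshold=censor_threshold,
        enrollees_per_region=enrollees,
        disease_link=disease_link,
        seed=seed,
    )


def _drug_index(n_drugs: int) -> pd.MultiIndex:
    brands = [f"BRAND_{j:04d}" for j in range(n_drugs)]
    generics = [f"generic_{j:04d}" for j in range(n_drugs)]
    return make_drug_index(brands, generics)


def _class_map(drugs: pd.MultiIndex, n_classes: int) -> pd.Series:
    # contiguous blocks of drugs share a class; every drug maps exactly once
    labels = [f"CLASS_{j % n_classes:03d}" for j in range(len(drugs))]
    return pd.Series(labels, index=drugs, name="drug_class")


def generate_population(
    config: SimulationConfig,
) -> tuple[ClaimsMatrix, pd.DataFrame, pd.Series, GroundTruth]:
    """Generate a censored claims population and its ground truth.

    Per provider: draw a specialty (and, for mixed practices, a second one),
    a region, and a profile ``theta ~ Dirichlet(alpha_specialty)`` (mixed:
    the 50/50 average of two draws); multiply by the region's per-drug
    effect and renormalize; draw total claims from the log-normal volume
    model; allocate them with one multinomial draw; finally censor cells
    below ``config.censor_threshold``.

    Returns
    -------
    (censored ClaimsMatrix, annotations DataFrame, ClassMap Series, GroundTruth)
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1A1]))
    n, m = config.n_providers, config.n_drugs
    drugs = _drug_index(m)
    npis = pd.Index([f"1{i:09d}" for i in range(n)], name="npi")

    spec_w = np.array([s.weight for s in config.specialties])
    spec_idx = rng.choice(len(config.specialties), size=n, p=spec_w)
    mixed = rng.random(n) < config.mixed_practice_fraction
    second_idx = np.full(n, -1)
    if len(config.specialties) > 1:
        for i in np.flatnonzero(mixed):
            choices = [k for k in range(len(config.specialties)) if k != spec_idx[i]]
            second_idx[i] = rng.choice(choices)
    else:
        mixed[:] = False

    if config.regions:
        reg_w = np.array([r.share for r in config.regions])
        reg_idx = rng.choice(len(config.regions), size=n, p=reg_w)
        region_names = [r.name for r in config.regions]
        effects = np.vstack([r.effect for r in config.regions])
    else:
        reg_idx = np.zeros(n, dtype=int)
        region_names = ["R01"]
        effects = np.ones((1, m))

    # disease prevalence per region (percent scale) and its drug-profile effect
    n_reg = len(region_names)
    prevalence = rng.uniform(2.0, 30.0, size=(n_reg, config.n_diseases))
    if config.disease_link is not None:
        delta = (prevalence - prevalence.mean(axis=0)) / 100.0
        disease_effect = np.exp(delta @ config.disease_link.T)  # (n_reg, m)
        effects = effects * disease_effect

    mu, sigma = config.volume_model
    totals = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(np.int64)

    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        alpha = config.specialties[spec_idx[i]].concentration
        theta = rng.dirichlet(alpha)
        if mixed[i]:
            theta = 0.5 * (theta + rng.dirichlet(
                config.specialties[second_idx[i]].concentration))
        theta = theta * effects[reg_idx[i]]
        theta = theta / theta.sum()
        counts[i] = rng.multinomial(totals[i], theta)

    uncensored = ClaimsMatrix(sp.csr_matrix(counts), npis, drugs, censor_threshold=0)
    censored = apply_censoring(uncensored, config.censor_threshold)

    spec_labels = pd.Series(
        [config.specialties[k].name for k in spec_idx], index=npis, name="specialty"
    )
    reg_labels = pd.Series(
        [region_names[k] for k in reg_idx], index=npis, name="region"
    )
    states = [config.regions[k].state if config.regions else "XX" for k in reg_idx]
    fips = [config.regions[k].county_fips if config.regions else "00000" for k in reg_idx]

    annotations = pd.DataFrame(
        {
            "specialty": spec_labels.to_numpy(),
            "state": states,
            "county_fips": fips,
            "cbsa": reg_labels.to_numpy(),
            "total_claims": censored.row_totals(),
        },
        index=npis,
    )

    truth = GroundTruth(
        specialty=spec_labels,
        region=reg_labels,
        uncensored=uncensored,
        region_effects=pd.DataFrame(effects, index=region_names, columns=drugs),
        region_prevalence=pd.DataFrame(
            prevalence,
            index=region_names,
            columns=[f"disease_{d:02d}" for d in range(config.n_diseases)],
        ),
        mixed_with=pd.Series(
            [config.specialties[k].name if k >= 0 else None for k in second_idx],
            index=npis,
            name="mixed_with",
        ),
    )
    class_map = _class_map(drugs, config.n_classes)
    return censored, annotations, class_map, truth


def make_crosswalk(config: SimulationConfig) -> pd.DataFrame:
    """County-FIPS -> CBSA crosswalk implied by the region specs."""
    return pd.DataFrame(
        {
            "county_fips": [r.county_fips for r in config.regions],
            "cbsa": [r.name for r in config.regions],
        }
    )


def make_enrollee_table(config: SimulationConfig) -> pd.DataFrame:
    """Per-region Part D enrollee counts as a two-column table."""
    return pd.DataFrame(
        {
            "region": list(config.enrollees_per_region),
            "enrollees": list(config.enrollees_per_region.values()),
        }
    )
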