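"""Synthetic cohorts for metaGRS development and validation.

Emulates the data structure of a multi-trait polygenic-score study of
intracranial aneurysm (IA): LD-blocked genotypes, a set of genetically
correlated traits with configurable SNP heritabilities, liability-threshold
case/control status with a proportional-hazards age at aneurysmal
subarachnoid hemorrhage (ASAH), and an IA-patient clinical-characteristics
table with injected score effects.

Genotypes are drawn from a latent-Gaussian copula: each LD block carries an
AR(1) latent process, two independent haplotype draws are thresholded at the
allele-frequency quantile, and the adjacent latent correlations are
calibrated (bivariate-normal bisection) so that the realized *dosage*
correlation matches the requested within-block level, compensating for
tetrachoric attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .sumstats import Variant

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class GenotypeMatrix:
    """Sample-by-variant dosages with an LD-block index.

    ``dosages`` holds values in {0, 1, 2} with NaN marking missing entries;
    ``block_index`` is non-decreasing along the variant axis.
    """

    sample_ids: list
    variants: list
    dosages: np.ndarray
    block_index: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.block_index = np.asarray(self.block_index)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError("dosage shape does not match ids/variants")
        if np.any(np.diff(self.block_index) < 0):
            raise ValidationError("block_index must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0) / 2.0

    def standardized(self, impute_missing: bool = True) -> np.ndarray:
        """Dosages centred and scaled to unit variance; missing -> 0 (mean)."""
        mu = np.nanmean(self.dosages, axis=0)
        sd = np.nanstd(self.dosages, axis=0)
        sd[sd == 0] = 1.0
        X = (self.dosages - mu) / sd
        if impute_missing:
            X = np.nan_to_num(X, nan=0.0)
        return X

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return GenotypeMatrix(ids, self.variants, self.dosages[mask],
                              self.block_index)


@dataclass
class CohortPhenotypes:
    """Outcome table aligned with a genotype cohort."""

    df: pd.DataFrame  # sample_id, sex, is_case, subtype, age_event_or_censor,
                      # sbp, smoking_packs_per_day, stratum
    liabilities: np.ndarray | None = None
    genetic_liabilities: np.ndarray | None = None
    traits: np.ndarray | None = None       # n x T quantitative traits
    genetic_values: np.ndarray | None = None

    def __post_init__(self):
        d = self.df
        bad = ((d["subtype"].isin(["ASAH", "UIA"]) & ~d["is_case"])
               | ((d["subtype"] == "control") & d["is_case"]))
        if bad.any():
            raise ValidationError("subtype inconsistent with is_case")


@dataclass
class ArchitectureConfig:
    """Multi-trait genetic architecture shared between traits and disease.

    ``rg`` is the trait-by-trait genetic correlation matrix (symmetric, unit
    diagonal, PSD); trait ``disease_trait_index`` is the disease liability.
    ``onset_log_hazard_per_sd`` scales the ASAH onset hazard with the
    standardized genetic liability.
    """

    n_traits: int
    h2: np.ndarray                       # per-trait SNP heritability
    rg: np.ndarray                       # genetic-correlation matrix
    causal_fraction: float = 1.0
    disease_trait_index: int = 0
    prevalence: float = 0.05
    onset_log_hazard_per_sd: float = 0.3
    asah_fraction: float = 0.6           # ASAH : UIA split among cases
    sbp_liability_corr: float = 0.2
    smoking_liability_corr: float = 0.15
    uia_detection_prob: float = 1.0      # optional under-detection of UIA
    seed: int = 0

    def __post_init__(self):
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if len(self.h2) == 1:
            self.h2 = np.repeat(self.h2, self.n_traits)
        self.rg = np.asarray(self.rg, dtype=float)
        if self.rg.shape != (self.n_traits, self.n_traits):
            raise ValidationError("rg shape must be n_traits x n_traits")
        if not np.allclose(self.rg, self.rg.T, atol=1e-8):
            raise ValidationError("rg must be symmetric")
        if not np.allclose(np.diag(self.rg), 1.0, atol=1e-8):
            raise ValidationError("rg must have unit diagonal")
        if np.linalg.eigvalsh(self.rg).min() < -1e-8:
            raise ValidationError("rg must be positive semi-definite")
        if np.any(self.h2 <= 0) or np.any(self.h2 > 1):
            raise ValidationError("h2 must lie in (0, 1]")
        if not 0 < self.causal_fraction <= 1:
            raise ValidationError("causal_fraction must lie in (0, 1]")
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

from functools import lru_cache


def _calibrate_latent_r(target: float, maf_a: float, maf_b: float) -> float:
    # memoized on rounded arguments: the bivariate-normal CDF bisection is
    # the cost center and nearby frequencies give near-identical solutions
    return _calibrate_cached(round(float(target), 3), round(float(maf_a), 2),
                             round(float(maf_b), 2))


@lru_cache(maxsize=100_000)
def _calibrate_cached(target: float, maf_a: float, maf_b: float) -> float:
    """Latent Gaussian correlation giving allele-indicator correlation ≈ target.

    Solves P(Z1<τa, Z2<τb; ρ) = maf_a·maf_b + target·sqrt(maf_a(1−maf_a)·
    maf_b(1−maf_b)) for ρ by bisection; clipped to [0, 0.999].
    """
    if target <= 0:
        return 0.0
    ta, tb = stats.norm.ppf(maf_a), stats.norm.ppf(maf_b)
    want = maf_a * maf_b + target * np.sqrt(
        maf_a * (1 - maf_a) * maf_b * (1 - maf_b))

    def joint(rho):
        return stats.multivariate_normal.cdf(
            [ta, tb], mean=[0, 0], cov=[[1, rho], [rho, 1]])

    lo, hi = 0.0, 0.999
    if joint(hi) <= want:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if joint(mid) < want:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class Population:
    """A fixed variant panel: alleles, frequencies, and latent LD structure.

    Drawing several cohorts from one :class:`Population` keeps variant
    identities, allele labels and population frequencies consistent, which
    any train/validation split requires.
    """

    variants: list
    block_index: np.ndarray
    mafs: np.ndarray
    sizes: np.ndarray
    latent: list  # per block: adjacent latent correlations


def simulate_genotypes(n_samples: int, n_variants: int, n_blocks: int,
                       maf_range: tuple = (0.05, 0.5),
                       within_block_r: float = 0.0,
                       missing_rate: float = 0.0,
                       seed: int = 0,
                       chrom: str = "1",
                       population: Population | None = None) -> GenotypeMatrix:
    """Simulate LD-blocked hard-call genotypes.

    Variants are partitioned into ``n_blocks`` contiguous blocks; within a
    block adjacent dosage correlations target ``within_block_r`` (scalar, or
    one value per block; AR(1)-like decay with distance); blocks are
    independent.  Monomorphic draws are
    rejected and redrawn.  Deterministic for fixed seed.
    """
    if n_blocks > n_variants:
        raise ValidationError("n_blocks must not exceed n_variants")
    within_block_r = np.broadcast_to(
        np.asarray(within_block_r, float), (n_blocks,)).copy()
    if np.any((within_block_r < 0) | (within_block_r >= 1)):
        raise ValidationError("within_block_r must lie in [0, 1)")
    if not (0 < maf_range[0] < maf_range[1] <= 0.5):
        raise ValidationError("maf_range must satisfy 0 < lo < hi <= 0.5")
    if missing_rate >= 1 or missing_rate < 0:
        raise ValidationError("missing_rate must lie in [0, 1)")

    if population is None:
        pop_rng = np.random.default_rng([seed, 0x5eed])
        sizes = np.full(n_blocks, n_variants // n_blocks)
        sizes[: n_variants % n_blocks] += 1
        block_index = np.repeat(np.arange(n_blocks), sizes)
        # block-level base frequency with small per-variant jitter: variants
        # in tight LD share ancestry, and near-equal thresholds keep high
        # dosage correlations attainable under the latent-Gaussian copula
        block_maf = pop_rng.uniform(maf_range[0], maf_range[1], size=n_blocks)
        mafs = np.clip(
            np.repeat(block_maf, sizes)
            + pop_rng.uniform(-0.02, 0.02, n_variants),
            maf_range[0], maf_range[1])
        latent = []
        start = 0
        for b, size in enumerate(sizes):
            block_mafs = mafs[start:start + size]
            r_b = within_block_r[b]
            latent.append(np.array([
                _calibrate_latent_r(r_b, block_mafs[j], block_mafs[j + 1])
                for j in range(size - 1)
            ]) if r_b > 0 else np.zeros(max(size - 1, 0)))
            start += size
        variants = []
        pos = 0
        for j in range(n_variants):
            pos += int(pop_rng.integers(500, 5000))
            ea, oa = _ALLELE_PAIRS[int(pop_rng.integers(len(_ALLELE_PAIRS)))]
            variants.append(Variant(f"rs{j + 1}", chrom, pos, ea, oa))
        population = Population(variants, block_index, mafs, sizes, latent)
    else:
        sizes = population.sizes
        block_index = population.block_index
        mafs = population.mafs
        variants = population.variants

    rng = np.random.default_rng([seed, 0xd05a6e])
    n_var = len(variants)
    dosages = np.empty((n_samples, n_var))
    start = 0
    for b, size in enumerate(sizes):
        cols = slice(start, start + size)
        for attempt in range(50):
            dos = _draw_block(rng, n_samples, mafs[cols], population.latent[b])
            freq = dos.mean(axis=0) / 2
            if np.all((freq > 0) & (freq < 1)):
                break
        else:
            raise ValidationError(
                f"block {b}: could not draw polymorphic genotypes")
        dosages[:, cols] = dos
        start += size

    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        # never blank out a whole variant
        full = mask.all(axis=0)
        mask[:, full] = False
        dosages = np.where(mask, np.nan, dosages)

    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    out = GenotypeMatrix(sample_ids, variants, dosages, block_index)
    out.population = population
    return out


def _draw_block(rng, n, mafs, latent_adjacent):
    """Two haplotype draws of an inhomogeneous AR(1) latent chain, thresholded."""
    size = len(mafs)
    taus = stats.norm.ppf(mafs)
    dos = np.zeros((n, size))
    for _hap in range(2):
        z = rng.standard_normal((n, size))
        for j in range(1, size):
            r = latent_adjacent[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r**2) * z[:, j]
        dos += (z < taus)
    return dos


# ---------------------------------------------------------------------------
# Effects and phenotypes
# ---------------------------------------------------------------------------

def simulate_effect_matrix(variants: list, config: ArchitectureConfig
                           ) -> np.ndarray:
    """True per-variant, per-trait effects on the standardized-genotype scale.

    A shared ``causal_fraction`` subset of variants is causal for all traits;
    causal effects are drawn jointly multivariate-normal so the cross-trait
    effect correlation equals ``rg``; each trait's column is then rescaled so
    its sum of squared effects equals that trait's h2 exactly.
    """
    m = len(variants)
    rng = np.random.default_rng(config.seed)
    n_causal = max(1, round(config.causal_fraction * m))
    causal = rng.choice(m, size=n_causal, replace=False)
    scale = np.sqrt(config.h2 / n_causal)
    cov = config.rg * np.outer(scale, scale)
    # PSD guard for numerically borderline rg
    w, V = np.linalg.eigh(cov)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    raw = rng.standard_normal((n_causal, config.n_traits)) @ L.T
    effects = np.zeros((m, config.n_traits))
    effects[causal] = raw
    ss = (effects**2).sum(axis=0)
    ss[ss == 0] = 1.0
    effects *= np.sqrt(config.h2 / ss)
    return effects


def simulate_phenotypes(genotypes: GenotypeMatrix, effects: np.ndarray,
                        config: ArchitectureConfig,
                        stratum: str = "cohort",
                        seed: int | None = None) -> CohortPhenotypes:
    """Liability-threshold disease with proportional-hazards onset ages.

    Quantitative traits are standardized-genotype x effect plus normal noise
    to unit total variance; the disease trait's column is the liability; a
    sample is a case iff liability exceeds Φ⁻¹(1−K).  Cases draw age at ASAH
    from an exponential onset model with log-hazard proportional to the
    standardized genetic liability, truncated to (18, 100); controls and UIA
    cases get a censoring/assessment age ~ Uniform(40, 80).
    """
    if effects.shape[0] != genotypes.n_variants:
        raise ValidationError("effects do not conform to genotype variants")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1_000_003)
    X = genotypes.standardized()
    G = X @ effects                                    # n x T genetic values
    n = genotypes.n_samples
    noise_sd = np.sqrt(np.clip(1.0 - config.h2, 0.0, None))
    traits = G + rng.standard_normal(G.shape) * noise_sd

    liab = traits[:, config.disease_trait_index]
    g_liab = G[:, config.disease_trait_index]
    g_sd = g_liab.std()
    g_std = (g_liab - g_liab.mean()) / (g_sd if g_sd > 0 else 1.0)
    tau = stats.norm.ppf(1 - config.prevalence)
    is_case = liab > tau

    sex = np.where(rng.random(n) < 0.55, "female", "male")  # IA skews female
    subtype = np.full(n, "control", dtype=object)
    case_idx = np.where(is_case)[0]
    asah = rng.random(len(case_idx)) < config.asah_fraction
    subtype[case_idx[asah]] = "ASAH"
    subtype[case_idx[~asah]] = "UIA"
    if config.uia_detection_prob < 1.0:
        uia_idx = np.where(subtype == "UIA")[0]
        undetected = rng.random(len(uia_idx)) >= config.uia_detection_prob
        subtype[uia_idx[undetected]] = "control"
        is_case = subtype != "control"

    age = rng.uniform(40, 80, size=n)                  # censoring / assessment
    asah_idx = np.where(subtype == "ASAH")[0]
    base_rate = 1.0 / 45.0                             # mean onset ~63y untruncated
    rate = base_rate * np.exp(config.onset_log_hazard_per_sd * g_std[asah_idx])
    onset = 18.0 + rng.exponential(1.0 / rate)
    onset = np.minimum(onset, 99.5)
    age[asah_idx] = onset

    def corr_noise(r):
        return r * g_std + np.sqrt(1 - r**2) * rng.standard_normal(n)

    sbp = np.clip(125 + 15 * corr_noise(config.sbp_liability_corr), 71, 249)
    smoking = np.maximum(
        0.0, 0.35 + 0.45 * corr_noise(config.smoking_liability_corr))

    df = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "sex": sex,
        "is_case": is_case,
        "subtype": subtype,
        "age_event_or_censor": age,
        "sbp": sbp,
        "smoking_packs_per_day": smoking,
        "stratum": stratum,
    })
    return CohortPhenotypes(df, liabilities=liab, genetic_liabilities=g_liab,
                            traits=traits, genetic_values=G)


def simulate_cohort(n_samples, n_variants, n_blocks, config: ArchitectureConfig,
                    maf_range=(0.05, 0.5), within_block_r=0.3,
                    missing_rate=0.0, effects: np.ndarray | None = None,
                    stratum: str = "cohort", seed: int | None = None,
                    population: Population | None = None):
    """Convenience wrapper: genotypes + (shared) effects + phenotypes.

    Pass the training cohort's ``genotypes.population`` (and its effect
    matrix) to draw a validation cohort from the same population.
    """
    seed = config.seed if seed is None else seed
    geno = simulate_genotypes(n_samples, n_variants, n_blocks, maf_range,
                              within_block_r, missing_rate, seed=seed,
                              population=population)
    if effects is None:
        effects = simulate_effect_matrix(geno.variants, config)
    phen = simulate_phenotypes(geno, effects, config, stratum=stratum,
                               seed=seed)
    return geno, effects, phen


# ---------------------------------------------------------------------------
# Patient-characteristics cohort (ISGC-like)
# ---------------------------------------------------------------------------

@dataclass
class PatientEffectConfig:
    """True effects of the standardized score on IA patient characteristics.

    Linear effects are in the characteristic's units per SD of score
    (``age_at_asah_years_per_sd``); binary/location effects are log-odds per
    SD.  ``cohort_offsets`` shift each characteristic per cohort, and
    ``cohort_score_assortment`` makes cohort membership depend on the score
    (creating confounding that cohort covariates must absorb).
    """

    age_at_asah_years_per_sd: float = 0.0
    location_log_or_per_sd: dict = field(default_factory=dict)  # group -> log-OR
    multiplicity_log_or_per_sd: float = 0.0
    rupture_log_or_per_sd: float = 0.0
    family_history_log_or_per_sd: float = 0.0
    smoking_log_or_per_sd: float = 0.0
    hypertension_log_or_per_sd: float = 0.0
    sex_log_or_per_sd: float = 0.0
    size_mm_per_sd: float = 0.0
    cohorts: tuple = ("coh1", "coh2", "coh3")
    cohort_offsets: dict = field(default_factory=dict)  # cohort -> shift
    cohort_score_assortment: float = 0.0
    asah_base_fraction: float = 0.7
    age_at_asah_mean: float = 52.0
    age_at_asah_sd: float = 12.0
    smoking_mediates: float = 0.0  # extra age shift per smoking (mediation tests)


_LOCATION_BASE = {"ICA": 0.20, "PCOM": 0.15, "ACA": 0.25, "MCA": 0.25,
                  "PC": 0.10, "other": 0.05}


def simulate_patient_characteristics(n_patients: int, score_per_sample,
                                     effect_config: PatientEffectConfig,
                                     seed: int = 0) -> pd.DataFrame:
    """ISGC-like clinical table for IA patients with injected score effects.

    The score is standardized internally; every injected effect is expressed
    per SD of that standardized score, so the heterogeneity module's
    association models can recover them directly.
    """
    if n_patients < 2:
        raise ValidationError("need at least two patients")
    s = np.asarray(score_per_sample, dtype=float)
    if len(s) != n_patients:
        raise ValidationError("score length must equal n_patients")
    s = (s - s.mean()) / (s.std() if s.std() > 0 else 1.0)
    rng = np.random.default_rng(seed)
    ec = effect_config

    # cohort assignment, optionally score-assorted
    k = len(ec.cohorts)
    logits = np.zeros((n_patients, k))
    logits += rng.standard_normal((n_patients, k)) * 0.1
    if ec.cohort_score_assortment:
        logits += np.outer(s, np.linspace(-1, 1, k)) * ec.cohort_score_assortment
    cohort = np.array(ec.cohorts)[np.argmax(logits, axis=1)]
    off = np.array([ec.cohort_offsets.get(c, 0.0) for c in cohort])

    def bern(base_logit, log_or):
        p = 1 / (1 + np.exp(-(base_logit + log_or * s + off)))
        return rng.random(n_patients) < p

    sex_female = bern(0.6, ec.sex_log_or_per_sd)       # ~65% female baseline
    smoking_ever = bern(0.2, ec.smoking_log_or_per_sd)
    hypertension = bern(-0.4, ec.hypertension_log_or_per_sd)
    family_history = bern(-1.8, ec.family_history_log_or_per_sd)
    multiple = bern(np.log(0.25 / 0.75), ec.multiplicity_log_or_per_sd)
    n_aneurysms = np.where(multiple, 2 + rng.poisson(0.5, n_patients), 1)
    ruptured = bern(np.log(ec.asah_base_fraction / (1 - ec.asah_base_fraction)),
                    ec.rupture_log_or_per_sd)

    # grouped location via multinomial logit with per-group score effects
    base = np.log(np.array([_LOCATION_BASE[g] for g in _LOCATION_BASE]))
    loc_logits = np.tile(base, (n_patients, 1))
    for gi, g in enumerate(_LOCATION_BASE):
        eta = ec.location_log_or_per_sd.get(g, 0.0)
        loc_logits[:, gi] += eta * s + off
    gumbel = rng.gumbel(size=loc_logits.shape)
    location = np.array(list(_LOCATION_BASE))[
        np.argmax(loc_logits + gumbel, axis=1)]

    age = (ec.age_at_asah_mean + ec.age_at_asah_years_per_sd * s + off
           + ec.smoking_mediates * smoking_ever
           + rng.standard_normal(n_patients) * ec.age_at_asah_sd)
    age = np.clip(age, 18.5, 99.5)
    age_at_asah = np.where(ruptured, age, np.nan)
    size_base = np.exp(np.log(6.0) + rng.standard_normal(n_patients) * 0.4)
    size = np.where(ruptured,
                    np.maximum(1.0, size_base + ec.size_mm_per_sd * s),
                    np.nan)

    return pd.DataFrame({
        "id": [f"P{i + 1}" for i in range(n_patients)],
        "cohort": cohort,
        "sex": np.where(sex_female, "female", "male"),
        "smoking_ever": smoking_ever,
        "hypertension": hypertension,
        "rupture_status": np.where(ruptured, "ASAH", "UIA"),
        "age_at_asah": age_at_asah,
        "family_history": family_history,
        "n_aneurysms": n_aneurysms,
        "location_grouped": location,
        "size_at_rupture": size,
        "score": s,
        "metagrs_version": "all",
    })
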