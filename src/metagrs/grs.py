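"""Trait-level polygenic score construction from summary statistics.

Three weighting methods, matching standard practice for the score family
this package implements:

* LD clumping + p-value thresholding — greedy index-variant selection,
  weights = raw marginal betas;
* SBLUP — per-LD-block ridge solution (n·R + λI)·b = n·β̂ on the
  standardized scale, λ = M·(1/h² − 1);
* SBayesR — Gibbs sampling under a point-mass-plus-scaled-normals mixture
  prior on standardized effects; weights are posterior means.

Plus cohort scoring with explicit missing-dosage policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (ConvergenceError, OverlapError, ValidationError)
from .sumstats import SumStatsTable, Variant


@dataclass
class LDBlockMatrix:
    """Block-diagonal LD (correlation) structure over a variant panel.

    ``blocks`` is a list of ``(indices, R)`` pairs where ``indices`` are
    positions into ``variants`` and ``R`` is the correlation matrix of the
    standardized dosages; blocks partition the variant set.
    """

    variants: list
    blocks: list
    n: int

    def __post_init__(self):
        seen = np.concatenate([np.asarray(ix) for ix, _ in self.blocks])
        if sorted(seen.tolist()) != list(range(len(self.variants))):
            raise ValidationError("blocks must partition the variant set")
        for ix, R in self.blocks:
            R = np.asarray(R)
            if not np.allclose(R, R.T, atol=1e-8):
                raise ValidationError("block R must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-6):
                raise ValidationError("block R must have unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValidationError("block R must be PSD within tolerance")


def ld_block_matrix(genotypes) -> LDBlockMatrix:
    """Empirical within-block correlation matrices from a genotype cohort."""
    X = genotypes.standardized()
    blocks = []
    for b in np.unique(genotypes.block_index):
        ix = np.where(genotypes.block_index == b)[0]
        Xb = X[:, ix]
        R = np.corrcoef(Xb, rowvar=False)
        R = np.atleast_2d(R)
        # shrink tiny negative eigenvalues from sampling noise
        w, V = np.linalg.eigh(R)
        if w.min() < 0:
            R = (V * np.clip(w, 1e-10, None)) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        blocks.append((ix, R))
    return LDBlockMatrix(genotypes.variants, blocks, genotypes.n_samples)


@dataclass
class WeightVector:
    """Per-SNP effect-allele weights for one score."""

    df: pd.DataFrame  # variant_id, chromosome, base_pair_location,
                      # effect_allele, other_allele, weight
    trait: str = "trait"
    method: str = "clump"
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.df["variant_id"].duplicated().any():
            raise ValidationError("weight vector has duplicate variants")
        if not np.isfinite(self.df["weight"].to_numpy()).all():
            raise ValidationError("weights must be finite")

    def __len__(self):
        return len(self.df)


def _weights_frame(table: SumStatsTable, weights: np.ndarray, keep=None
                   ) -> pd.DataFrame:
    df = table.df
    out = pd.DataFrame({
        "variant_id": df["variant_id"],
        "chromosome": df["chromosome"],
        "base_pair_location": df["base_pair_location"],
        "effect_allele": df["effect_allele"],
        "other_allele": df["other_allele"],
        "weight": weights,
    })
    if keep is not None:
        out = out.loc[keep].reset_index(drop=True)
    return out


def _block_r2(ld: LDBlockMatrix):
    """variant position -> (block order index, r² row lookup)."""
    lookup = {}
    for bi, (ix, R) in enumerate(ld.blocks):
        for local, j in enumerate(ix):
            lookup[int(j)] = (bi, local)
    return lookup


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def clump(table: SumStatsTable, ld: LDBlockMatrix, r2_threshold: float,
          p_threshold: float = 1.0) -> WeightVector:
    """Greedy LD clumping with p-value thresholding.

    Repeatedly takes the remaining variant with the smallest p ≤ p_threshold
    as an index variant and removes remaining variants with r² ≥ r2_threshold
    to it within its LD block.  Ties break on smaller p then lexicographic
    id.  Index variants keep their raw marginal beta as weight.
    """
    if not 0 < r2_threshold <= 1:
        raise ValidationError("r2_threshold must lie in (0, 1]")
    if not 0 < p_threshold <= 1:
        raise ValidationError("p_threshold must lie in (0, 1]")
    _check_aligned(table, ld)
    df = table.df
    p = df["p_value"].to_numpy()
    ids = df["variant_id"].to_numpy()
    lookup = _block_r2(ld)
    order = sorted(range(len(df)), key=lambda j: (p[j], ids[j]))
    alive = np.ones(len(df), bool)
    kept = []
    for j in order:
        if not alive[j] or p[j] > p_threshold:
            continue
        kept.append(j)
        alive[j] = False
        bi, local = lookup[j]
        ix, R = ld.blocks[bi]
        r2row = R[local] ** 2
        for other_local, k in enumerate(ix):
            if alive[k] and r2row[other_local] >= r2_threshold:
                alive[k] = False
    kept = sorted(kept)
    wv = _weights_frame(table, df["beta"].to_numpy(), keep=np.array(kept, int))
    return WeightVector(wv, trait=table.trait, method="clump",
                        hyperparameters={"r2_threshold": r2_threshold,
                                         "p_threshold": p_threshold})


def _check_aligned(table: SumStatsTable, ld: LDBlockMatrix):
    ids = table.df["variant_id"].tolist()
    ref = [v.id for v in ld.variants]
    if ids != ref:
        raise ValidationError(
            "table must be harmonized/ordered to the LD reference variants")


def _to_standardized(table: SumStatsTable) -> np.ndarray:
    beta = table.df["beta"].to_numpy().astype(float)
    if table.effect_scale == "standardized":
        return beta, None
    table.require_eaf("dosage-to-standardized conversion")
    f = table.df["effect_allele_frequency"].to_numpy()
    sd = np.sqrt(2 * f * (1 - f))
    return beta * sd, sd


# ---------------------------------------------------------------------------
# SBLUP
# ---------------------------------------------------------------------------

def sblup(table: SumStatsTable, ld: LDBlockMatrix, h2: float,
          m_total: int | None = None) -> WeightVector:
    """Summary-statistic BLUP: blockwise ridge solution of the joint model.

    On the standardized scale solves (n·R_b + λI)·b = n·β̂_b per LD block with
    λ = M·(1/h² − 1); weights are converted back to the dosage scale when the
    input effects are per-dosage.
    """
    if not 0 < h2 < 1:
        raise ValidationError("h2 must lie in (0, 1)")
    _check_aligned(table, ld)
    m_total = len(table) if m_total is None else m_total
    lam = m_total * (1.0 / h2 - 1.0)
    beta_std, sd = _to_standardized(table)
    n = table.df["n"].to_numpy().astype(float)
    b = np.zeros(len(table))
    for ix, R in ld.blocks:
        nb = n[ix]
        n_eff = float(np.median(nb))
        A = n_eff * R + lam * np.eye(len(ix))
        try:
            b[ix] = np.linalg.solve(A, n_eff * beta_std[ix])
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"SBLUP solve failed in block at {ix[0]}: {exc}")
    w = b if sd is None else b / sd
    return WeightVector(_weights_frame(table, w), trait=table.trait,
                        method="sblup",
                        hyperparameters={"h2": h2, "lambda": lam,
                                         "m_total": m_total})


# ---------------------------------------------------------------------------
# SBayesR
# ---------------------------------------------------------------------------

@dataclass
class SBayesRConfig:
    """Mixture prior and sampler settings for SBayesR.

    ``gamma`` are ascending variance multipliers with γ₁ = 0 (the null
    component); ``pi`` the initial mixture proportions; the effect-variance
    scale σ²_β and π are resampled each sweep unless frozen (useful for
    oracle comparisons on fixed hyperparameters).
    """

    gamma: tuple = (0.0, 0.01, 0.1, 1.0)
    pi: tuple = (0.95, 0.02, 0.02, 0.01)
    iterations: int = 600
    burn_in: int = 150
    dirichlet_alpha: float = 1.0
    sigma_beta2: float = 0.01
    update_pi: bool = True
    update_sigma_beta: bool = True
    nu0: float = 4.0
    s02: float = 0.01
    seed: int = 0

    def __post_init__(self):
        g = np.asarray(self.gamma, float)
        if g[0] != 0.0:
            raise ValidationError("gamma[0] must be 0 (null component)")
        if np.any(np.diff(g) <= 0):
            raise ValidationError("gamma must be strictly ascending")
        p = np.asarray(self.pi, float)
        if len(p) != len(g):
            raise ValidationError("pi and gamma must have equal length")
        if abs(p.sum() - 1) > 1e-8 or np.any(p < 0):
            raise ValidationError("pi must be a probability vector")
        if not 0 <= self.burn_in < self.iterations:
            raise ValidationError("burn_in must be < iterations")


def sbayesr(table: SumStatsTable, ld: LDBlockMatrix,
            config: SBayesRConfig | None = None) -> WeightVector:
    """SBayesR: Gibbs sampling of standardized joint effects.

    Per sweep and variant j the marginal effect is residualized against the
    current effects of LD partners (r_j = β̂_j − Σ_{k≠j} R_jk·b_k); a mixture
    component is sampled with probability ∝ π_k·exp(½·log(ṽ_k/ψ_k) +
    μ_k²/(2ṽ_k)) where ψ_k = γ_k·σ²_β, ṽ_k = σ²_e/(n + σ²_e/ψ_k),
    μ_k = ṽ_k·n·r_j/σ²_e, the null component being a point mass at zero;
    b_j is drawn from the selected normal.  After each sweep π is redrawn
    from a Dirichlet over component counts and σ²_β from its scaled
    inverse-chi-square conditional.  The returned weight is the post-burn-in
    posterior mean.  σ²_e is fixed at 1 on the standardized scale.
    """
    config = config or SBayesRConfig()
    _check_aligned(table, ld)
    rng = np.random.default_rng(config.seed)
    beta_std, sd = _to_standardized(table)
    n = float(np.median(table.df["n"].to_numpy()))
    m = len(table)
    K = len(config.gamma)
    gamma = np.asarray(config.gamma, float)
    pi = np.asarray(config.pi, float).copy()
    sigma_b2 = float(config.sigma_beta2)
    sigma_e2 = 1.0

    b = np.zeros(m)
    comp = np.zeros(m, int)
    post_sum = np.zeros(m)
    n_post = 0
    # per-block caches: R and running R @ b
    block_data = []
    for ix, R in ld.blocks:
        block_data.append((np.asarray(ix, int), np.asarray(R, float),
                           np.zeros(len(ix))))

    for sweep in range(config.iterations):
        counts = np.zeros(K)
        # per-sweep constants (only depend on sigma_b2 / pi)
        psi = gamma[1:] * sigma_b2
        v = sigma_e2 / (n + sigma_e2 / psi)
        sqrt_v = np.sqrt(v)
        mu_coef = v * n / sigma_e2
        half_log_vpsi = 0.5 * np.log(v / psi)
        inv_2v = 1.0 / (2 * v)
        with np.errstate(divide="ignore"):  # pi entries may be exactly 0
            log_pi = np.log(pi)
        # pre-draw uniforms and normals for the sweep
        unif = rng.random(m)
        norm = rng.standard_normal(m)
        for ix, R, Rb in block_data:
            for local in range(len(ix)):
                j = ix[local]
                bj_old = b[j]
                r_j = beta_std[j] - (Rb[local] - bj_old)
                mu = mu_coef * r_j
                logk = half_log_vpsi + mu * mu * inv_2v
                lw = np.empty(K)
                lw[0] = log_pi[0]
                lw[1:] = log_pi[1:] + logk
                lw -= lw.max()
                w_ = np.exp(lw)
                cdf = np.cumsum(w_)
                k = int(np.searchsorted(cdf, unif[j] * cdf[-1], side="right"))
                counts[k] += 1
                comp[j] = k
                bj_new = 0.0 if k == 0 else mu[k - 1] + sqrt_v[k - 1] * norm[j]
                if abs(bj_new) > 10:
                    raise ConvergenceError(
                        f"SBayesR diverged at variant "
                        f"{table.df['variant_id'].iloc[j]} (sweep {sweep}, "
                        f"|b|={abs(bj_new):.2f}, sigma_beta2={sigma_b2:.3g})")
                if bj_new != bj_old:
                    Rb += R[:, local] * (bj_new - bj_old)
                    b[j] = bj_new
        if config.update_pi:
            pi = rng.dirichlet(counts + config.dirichlet_alpha)
            pi = np.maximum(pi, 1e-8)
            pi /= pi.sum()
        if config.update_sigma_beta:
            nz = comp > 0
            q = int(nz.sum())
            if q:
                # scaled inverse-chi-square conditional with Σ b_j²/γ_{k(j)}
                comp_ss = float((b[nz] ** 2 / gamma[comp[nz]]).sum())
                df_post = config.nu0 + q
                scale = comp_ss + config.nu0 * config.s02
                sigma_b2 = scale / rng.chisquare(df_post)
                sigma_b2 = float(np.clip(sigma_b2, 1e-8, 10.0))
        if sweep >= config.burn_in:
            post_sum += b
            n_post += 1
    post_mean = post_sum / max(n_post, 1)
    w = post_mean if sd is None else post_mean / sd
    return WeightVector(_weights_frame(table, w), trait=table.trait,
                        method="sbayesr",
                        hyperparameters={"gamma": tuple(gamma),
                                         "iterations": config.iterations,
                                         "burn_in": config.burn_in},
                        seed=config.seed)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_cohort(genotypes, weights: WeightVector,
                 missing_policy: str = "mean_impute") -> np.ndarray:
    """Apply per-SNP weights to a genotype cohort.

    Variants are matched by id; when the weight file's effect allele equals
    the cohort's *other* allele the dosage is flipped (d -> 2−d).  Missing
    dosages are mean-imputed with 2·EAF (cohort empirical frequency) under
    ``mean_impute`` (default), or the observed-weight sum is rescaled by
    total/observed weight count under ``skip_renormalize``.
    """
    if missing_policy not in ("mean_impute", "skip_renormalize"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    geno_ix = {v.id: j for j, v in enumerate(genotypes.variants)}
    cols, w_list, flip = [], [], []
    mismatches = 0
    for row in weights.df.itertuples(index=False):
        j = geno_ix.get(row.variant_id)
        if j is None:
            continue
        v = genotypes.variants[j]
        if row.effect_allele == v.effect_allele and row.other_allele == v.other_allele:
            flip.append(False)
        elif row.effect_allele == v.other_allele and row.other_allele == v.effect_allele:
            flip.append(True)
        else:
            mismatches += 1
            continue
        cols.append(j)
        w_list.append(row.weight)
    if not cols:
        raise OverlapError(
            f"no overlapping variants between weights ({len(weights)}) and "
            f"genotypes ({genotypes.n_variants}); allele mismatches: {mismatches}")
    D = genotypes.dosages[:, cols].copy()
    w = np.asarray(w_list, float)
    flip = np.asarray(flip, bool)
    D[:, flip] = 2.0 - D[:, flip]
    obs = ~np.isnan(D)
    if missing_policy == "mean_impute":
        eaf = np.nanmean(D, axis=0) / 2.0
        D = np.where(obs, D, 2.0 * eaf)
        return D @ w
    contrib = np.where(obs, D, 0.0) @ w
    n_obs = obs.sum(axis=1).astype(float)
    n_obs[n_obs == 0] = np.nan
    scores = contrib * (len(w) / n_obs)
    return np.nan_to_num(scores, nan=0.0)
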