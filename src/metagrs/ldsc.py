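"""LD-score regression: SNP heritability, genetic correlation, and the
P<0.05 trait-inclusion filter used before building trait-level scores.

The regression follows the standard chi-square formulation
E[χ²_j] = N·h²·ℓ_j/M + intercept, with the bias-adjusted LD score
ℓ_j = Σ_k [r²_jk − (1−r²_jk)/(n−2)] over a positional window (k=j included).
Standard errors come from a delete-one block jackknife over contiguous
variant blocks; sample overlap between traits is absorbed by the free
intercept of the cross-trait regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MonomorphicVariantError, ValidationError


@dataclass
class LDScoreTable:
    """Per-variant adjusted LD scores plus the regression variant count."""

    variant_ids: list
    ld_score: np.ndarray
    m_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variant_id": self.variant_ids,
                             "ld_score": self.ld_score})


@dataclass
class RgEstimate:
    """A genetic-correlation estimate between one trait pair."""

    trait_a: str
    trait_b: str
    h2_a: float
    h2_b: float
    rg: float
    se_rg: float
    p_rg: float


def ld_scores(genotypes, window_variants: int = 50) -> LDScoreTable:
    """Adjusted LD scores from an in-sample genotype reference.

    ℓ_j sums r²_jk − (1−r²_jk)/(n−2) over variants within ±``window_variants``
    positions of j, including k=j (which contributes exactly 1).
    """
    n = genotypes.n_samples
    if n < 50:
        raise ValidationError("LD-score estimation needs at least 50 samples")
    sd = np.nanstd(genotypes.dosages, axis=0)
    if np.any(sd == 0):
        j = int(np.where(sd == 0)[0][0])
        raise MonomorphicVariantError(
            f"variant {genotypes.variants[j].id} is monomorphic")
    X = genotypes.standardized()
    m = X.shape[1]
    R = (X.T @ X) / n
    r2 = R**2
    adj = r2 - (1 - r2) / (n - 2)
    idx = np.arange(m)
    mask = np.abs(idx[:, None] - idx[None, :]) <= window_variants
    ell = np.where(mask, adj, 0.0).sum(axis=1)
    return LDScoreTable([v.id for v in genotypes.variants], ell, m)


def _align(table, ldscores: LDScoreTable):
    order = pd.Index(ldscores.variant_ids)
    df = table.df.set_index("variant_id").reindex(order)
    if df["beta"].isna().any():
        raise ValidationError("table is not harmonized to the LD-score variants")
    return df


def _jackknife(values: np.ndarray) -> float:
    k = len(values)
    return float(np.sqrt((k - 1) / k * ((values - values.mean())**2).sum()))


def _h2_fit(chi2, x, weights):
    """Weighted least squares of chi-square on N·ℓ/M with free intercept."""
    W = np.sqrt(weights)
    A = np.column_stack([np.ones_like(x), x]) * W[:, None]
    b = chi2 * W
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return coef  # [intercept, slope]


def ldsc_h2(table, ldscores: LDScoreTable, n_blocks: int = 20
            ) -> tuple[float, float, float]:
    """SNP heritability via LD-score regression.

    Returns ``(h2, se, intercept)``.  Weights default to the simple
    heteroskedasticity weights 1/ℓ_j; SE from a delete-one block jackknife.
    """
    df = _align(table, ldscores)
    m = ldscores.m_total
    if len(df) < 2 * n_blocks:
        raise ValidationError("fewer variants than 2x jackknife blocks")
    z = df["beta"].to_numpy() / df["standard_error"].to_numpy()
    chi2 = z**2
    x = df["n"].to_numpy() * ldscores.ld_score / m
    w = 1.0 / np.maximum(ldscores.ld_score, 1.0)
    intercept, slope = _h2_fit(chi2, x, w)
    blocks = np.array_split(np.arange(len(df)), n_blocks)
    pseudo = []
    for blk in blocks:
        keep = np.ones(len(df), bool)
        keep[blk] = False
        pseudo.append(_h2_fit(chi2[keep], x[keep], w[keep])[1])
    se = _jackknife(np.asarray(pseudo))
    return float(slope), se, float(intercept)


def ldsc_rg(table_a, table_b, ldscores: LDScoreTable,
            sample_overlap: float = 0.0, n_blocks: int = 20) -> RgEstimate:
    """Genetic correlation via cross-trait LD-score regression.

    The product z_a·z_b is regressed on sqrt(N_a·N_b)·ℓ_j/M with a free
    intercept (which absorbs any sample overlap); rg is the genetic
    covariance over sqrt(h2_a·h2_b).  SE and p come from jackknifing the
    whole rg statistic over contiguous blocks.
    """
    da, db = _align(table_a, ldscores), _align(table_b, ldscores)
    m = ldscores.m_total
    n_var = len(da)
    if n_var < 2 * n_blocks:
        raise ValidationError("fewer variants than 2x jackknife blocks")
    za = da["beta"].to_numpy() / da["standard_error"].to_numpy()
    zb = db["beta"].to_numpy() / db["standard_error"].to_numpy()
    na, nb = da["n"].to_numpy(), db["n"].to_numpy()
    ell = ldscores.ld_score
    w = 1.0 / np.maximum(ell, 1.0)
    xa, xb = na * ell / m, nb * ell / m
    xab = np.sqrt(na * nb) * ell / m

    def rg_on(keep):
        h2a = _h2_fit(za[keep]**2, xa[keep], w[keep])[1]
        h2b = _h2_fit(zb[keep]**2, xb[keep], w[keep])[1]
        if h2a <= 0 or h2b <= 0:
            return np.nan, h2a, h2b
        covg = _h2_fit((za * zb)[keep], xab[keep], w[keep])[1]
        return covg / np.sqrt(h2a * h2b), h2a, h2b

    all_keep = np.ones(n_var, bool)
    rg, h2a, h2b = rg_on(all_keep)
    if np.isnan(rg):
        raise ValidationError(
            f"h2 estimate non-positive ({h2a:.3g}, {h2b:.3g}); rg undefined")
    blocks = np.array_split(np.arange(n_var), n_blocks)
    pseudo = []
    for blk in blocks:
        keep = all_keep.copy()
        keep[blk] = False
        r, *_ = rg_on(keep)
        pseudo.append(r)
    pseudo = np.asarray(pseudo)
    if np.isnan(pseudo).any():
        pseudo = np.where(np.isnan(pseudo), rg, pseudo)
    se = max(_jackknife(pseudo), 1e-12)
    p = float(np.clip(2 * stats.norm.sf(abs(rg) / se), 1e-300, 1.0))
    return RgEstimate(table_a.trait, table_b.trait, float(h2a), float(h2b),
                      float(rg), se, p)


def filter_correlated_traits(estimates: list[RgEstimate], alpha: float = 0.05
                             ) -> list[str]:
    """Traits whose genetic correlation with the disease has p < alpha."""
    return [e.trait_a for e in estimates if e.p_rg < alpha]
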