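"""The metaGRS model: per-trait candidate selection by Nagelkerke pseudo-R²,
elastic-net combination of the selected trait-level scores, and the combined
per-SNP weight vector.

Exposed in the style of statsmodels: a :class:`MetaGRS` model object is built
from a training cohort plus per-trait summary statistics; :meth:`MetaGRS.fit`
runs the pipeline (genetic-correlation filter -> candidate grid ->
best-candidate selection -> elastic net -> weight combination) and returns a
:class:`MetaGRSResults` carrying the per-trait weights γ_t, the training
score standard deviations s_t, the combined weights, and a ``summary()``
table.  The combined per-SNP weight for variant j is Σ_t (γ_t/s_t)·w_{t,j}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConvergenceError, ValidationError
from .grs import (LDBlockMatrix, SBayesRConfig, WeightVector, clump,
                  ld_block_matrix, sblup, sbayesr, score_cohort)
from .ldsc import filter_correlated_traits, ld_scores, ldsc_h2, ldsc_rg

#: default clumping r² grid (9 thresholds)
CLUMP_R2_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8)
_METHOD_ORDER = {"clump": 0, "sblup": 1, "sbayesr": 2}


# ---------------------------------------------------------------------------
# Nagelkerke pseudo-R² and candidate selection
# ---------------------------------------------------------------------------

def _logit_llf(outcome, X) -> float:
    model = sm.Logit(outcome, X)
    try:
        fit = model.fit(disp=0, maxiter=200)
        if not np.isfinite(fit.llf):
            raise ValueError("non-finite log-likelihood")
        return float(fit.llf)
    except Exception:
        # separation guard: small ridge penalty
        fit = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0, maxiter=500)
        return float(model.loglike(fit.params))


def nagelkerke_r2(outcome, score, covariates=None) -> float:
    """Nagelkerke (max-rescaled Cox–Snell) pseudo-R² of a score for a binary
    outcome: R²_CS = 1 − exp((2/n)(ℓ₀ − ℓ₁)) divided by 1 − exp((2/n)·ℓ₀)."""
    y = np.asarray(outcome, float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("outcome must contain both classes")
    s = np.asarray(score, float)
    n = len(y)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)])
    ll0 = _logit_llf(y, base)
    ll1 = _logit_llf(y, np.column_stack([base, s]))
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


@dataclass
class TraitPanel:
    """Per-trait candidate weight vectors and their training-cohort scores."""

    candidates: dict  # trait -> list of (WeightVector, scores ndarray)

    def __post_init__(self):
        lengths = {len(s) for cands in self.candidates.values()
                   for _, s in cands}
        if len(lengths) > 1:
            raise ValidationError("candidates scored on unequal sample sets")


def select_best(panel: TraitPanel, outcome, covariates=None) -> dict:
    """Per trait, the candidate with the highest Nagelkerke pseudo-R² for
    disease status; ties break on fewer variants, then method order
    clump < sblup < sbayesr."""
    best = {}
    for trait, cands in panel.candidates.items():
        if not cands:
            raise ValidationError(f"trait {trait} has no candidates")
        scored = []
        for wv, s in cands:
            r2 = nagelkerke_r2(outcome, s, covariates) if np.std(s) > 0 else 0.0
            scored.append((-r2, len(wv), _METHOD_ORDER.get(wv.method, 9), wv, s))
        scored.sort(key=lambda t: t[:3])
        best[trait] = (scored[0][3], scored[0][4])
    return best


# ---------------------------------------------------------------------------
# Elastic net over trait scores
# ---------------------------------------------------------------------------

def fit_elastic_net(trait_scores: pd.DataFrame, outcome, l1_ratio: float = 0.5,
                    cv_folds: int = 5, seed: int = 0,
                    n_penalties: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Elastic-net logistic regression of disease status on trait scores.

    Scores are standardized internally; ``s_t`` records the raw training
    standard deviations.  The penalty strength is chosen on a log-spaced grid
    by cross-validated deviance with the one-standard-error rule (the
    strongest penalty within one SE of the minimum — the glmnet convention,
    which keeps the null model sparse); returns ``(gamma, s)`` with γ_t the
    coefficients on the standardized scale (exact zeros retained).
    """
    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    X_raw = np.asarray(trait_scores, float)
    s = X_raw.std(axis=0, ddof=0)
    if np.any(s == 0):
        raise ValidationError("a trait score is constant in training")
    X = (X_raw - X_raw.mean(axis=0)) / s
    n = len(y)
    Cs = np.logspace(-4, 2, n_penalties)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    dev = np.zeros((len(Cs), cv_folds))
    for ci, C in enumerate(Cs):
        for fi, (tr, te) in enumerate(folds):
            clf = _enet_logit(C, l1_ratio, seed)
            clf.fit(X[tr], y[tr])
            p = np.clip(clf.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
            dev[ci, fi] = -2 * np.mean(
                y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean_dev))
    # one-SE rule: strongest penalty (smallest C) within one SE of the best
    within = np.where(mean_dev <= mean_dev[best] + se_dev[best])[0]
    C_best = Cs[int(within.min())]
    clf = _enet_logit(C_best, l1_ratio, seed)
    clf.fit(X, y)
    gamma = clf.coef_.ravel().copy()
    return gamma, s


def _enet_logit(C, l1_ratio, seed):
    return LogisticRegression(solver="saga", C=C, l1_ratio=l1_ratio,
                              max_iter=5000, tol=1e-6, random_state=seed)


def combine_weights(weight_vectors: list[WeightVector], gamma, s,
                    trait_names=None) -> WeightVector:
    """Combined per-SNP weights: union over variants, weight_j =
    Σ_t (γ_t/s_t)·w_{t,j} with w_{t,j}=0 where trait t lacks variant j."""
    gamma = np.asarray(gamma, float)
    s = np.asarray(s, float)
    if len(weight_vectors) != len(gamma) or len(gamma) != len(s):
        raise ValidationError("weight vectors, gamma and s must align")
    if np.any(s <= 0):
        raise ValidationError("score standard deviations must be positive")
    pieces = []
    for wv, g, sd in zip(weight_vectors, gamma, s):
        d = wv.df.copy()
        d["weight"] = d["weight"] * (g / sd)
        pieces.append(d)
    cat = pd.concat(pieces, ignore_index=True)
    meta_cols = ["chromosome", "base_pair_location", "effect_allele",
                 "other_allele"]
    grp = cat.groupby("variant_id", sort=False)
    out = grp.agg(**{c: (c, "first") for c in meta_cols},
                  weight=("weight", "sum")).reset_index()
    out = out.sort_values(["chromosome", "base_pair_location"],
                          kind="mergesort").reset_index(drop=True)
    traits = (trait_names if trait_names is not None
              else [wv.trait for wv in weight_vectors])
    return WeightVector(out, trait="metaGRS", method="metaGRS",
                        hyperparameters={"traits": list(traits),
                                         "gamma": gamma.tolist(),
                                         "s": s.tolist()})


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class MetaGRSConfig:
    """Pipeline settings for :class:`MetaGRS`."""

    clump_r2_grid: tuple = CLUMP_R2_GRID
    clump_p_threshold: float = 1.0
    use_sblup: bool = True
    use_sbayesr: bool = True
    sbayesr: SBayesRConfig | None = None
    rg_alpha: float = 0.05
    ld_window: int = 50
    l1_ratio: float = 0.5
    cv_folds: int = 5
    jackknife_blocks: int = 20
    seed: int = 0


class MetaGRS:
    """metaGRS model: combine trait-level polygenic scores for one disease.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Training cohort genotypes (LD reference and scoring cohort).
    phenotypes : CohortPhenotypes or DataFrame
        Training outcomes; must carry ``is_case`` and ``sex``.
    disease_sumstats : SumStatsTable
        External GWAS of the disease (always included as a trait).
    trait_sumstats : dict[str, SumStatsTable]
        Candidate auxiliary traits, subjected to the genetic-correlation
        filter (p < ``rg_alpha``) before score construction.
    config : MetaGRSConfig
    """

    def __init__(self, genotypes, phenotypes, disease_sumstats,
                 trait_sumstats, config: MetaGRSConfig | None = None):
        self.genotypes = genotypes
        self.phenotypes = getattr(phenotypes, "df", phenotypes)
        self.disease_sumstats = disease_sumstats
        self.trait_sumstats = dict(trait_sumstats)
        self.config = config or MetaGRSConfig()

    # -- pipeline stages ---------------------------------------------------
    def _stage(self, name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise ConvergenceError(f"[stage {name}] {exc}") from exc

    def fit(self, stratum: str = "all", seed: int | None = None
            ) -> "MetaGRSResults":
        """Run the full construction pipeline; returns results for the
        requested stratum ('all', 'women' or 'men')."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        if stratum == "all":
            mask = np.ones(len(self.phenotypes), bool)
        elif stratum in ("women", "men"):
            want = "female" if stratum == "women" else "male"
            mask = (self.phenotypes["sex"] == want).to_numpy()
        else:
            raise ValidationError(f"unknown stratum {stratum!r}")
        geno = self.genotypes.subset_samples(mask)
        outcome = self.phenotypes.loc[mask, "is_case"].to_numpy().astype(float)
        if len(np.unique(outcome)) < 2:
            raise ValidationError(f"stratum {stratum}: single-class outcome")

        ld = self._stage("ld_reference", ld_block_matrix, geno)
        ells = self._stage("ld_scores", ld_scores, geno, cfg.ld_window)

        # genetic-correlation filter against the disease; a trait whose rg
        # is unestimable (non-positive h2 at this scale) is excluded, not fatal
        from .ldsc import RgEstimate

        rg_estimates = []
        for name, tab in self.trait_sumstats.items():
            try:
                est = ldsc_rg(tab, self.disease_sumstats, ells,
                              0.0, cfg.jackknife_blocks)
            except ValidationError:
                est = RgEstimate(tab.trait, self.disease_sumstats.trait,
                                 np.nan, np.nan, np.nan, np.nan, 1.0)
            rg_estimates.append(est)
        included = filter_correlated_traits(rg_estimates, cfg.rg_alpha)

        # candidate grid per trait (disease GWAS always included)
        tables = {self.disease_sumstats.trait: self.disease_sumstats}
        tables.update({t: self.trait_sumstats[t] for t in included})
        panel, h2_by_trait = {}, {}
        for name, tab in tables.items():
            cands = []
            for r2t in cfg.clump_r2_grid:
                wv = self._stage("clump", clump, tab, ld, r2t,
                                 cfg.clump_p_threshold)
                if len(wv):
                    cands.append((wv, score_cohort(geno, wv)))
            h2_hat, _, _ = self._stage("ldsc_h2", ldsc_h2, tab, ells,
                                       cfg.jackknife_blocks)
            h2_used = float(np.clip(h2_hat, 0.01, 0.9))
            h2_by_trait[name] = h2_used
            if cfg.use_sblup:
                wv = self._stage("sblup", sblup, tab, ld, h2_used)
                cands.append((wv, score_cohort(geno, wv)))
            if cfg.use_sbayesr:
                sb_cfg = cfg.sbayesr or SBayesRConfig(seed=seed)
                wv = self._stage("sbayesr", sbayesr, tab, ld, sb_cfg)
                if np.any(wv.df["weight"] != 0):
                    cands.append((wv, score_cohort(geno, wv)))
            panel[name] = cands
        panel = TraitPanel(panel)
        best = self._stage("select_best", select_best, panel, outcome)

        # a degenerate candidate (constant training score) cannot enter the
        # elastic net; the disease's own score always has variance here
        trait_names = [t for t in best if np.std(best[t][1]) > 0]
        score_mat = pd.DataFrame(
            {t: best[t][1] for t in trait_names})
        gamma, s = self._stage(
            "elastic_net", fit_elastic_net, score_mat, outcome,
            cfg.l1_ratio, cfg.cv_folds, seed)
        nonzero = gamma != 0
        if not nonzero.any():
            # degenerate all-null fit: fall back to the disease's own score
            nonzero = np.array([t == self.disease_sumstats.trait
                                for t in trait_names])
            gamma = nonzero.astype(float)
        sel_wvs = [best[t][0] for t, nz in zip(trait_names, nonzero) if nz]
        sel_names = [t for t, nz in zip(trait_names, nonzero) if nz]
        combined = combine_weights(sel_wvs, gamma[nonzero], s[nonzero],
                                   trait_names=sel_names)
        ia_only = best[self.disease_sumstats.trait][0]
        return MetaGRSResults(
            model=self, stratum=stratum, seed=seed,
            included_traits=sel_names,
            gamma=gamma[nonzero], s=s[nonzero],
            all_traits=trait_names, gamma_full=gamma, s_full=s,
            constituent_weights=sel_wvs, combined_weights=combined,
            ia_only_weights=ia_only, rg_estimates=rg_estimates,
            h2_by_trait=h2_by_trait,
            nagelkerke_best={t: nagelkerke_r2(outcome, best[t][1])
                             for t in trait_names},
        )


@dataclass
class MetaGRSResults:
    """Fitted metaGRS: per-trait elastic-net weights, score SDs, combined
    per-SNP weights, plus construction diagnostics."""

    model: MetaGRS
    stratum: str
    seed: int
    included_traits: list
    gamma: np.ndarray
    s: np.ndarray
    all_traits: list
    gamma_full: np.ndarray
    s_full: np.ndarray
    constituent_weights: list
    combined_weights: WeightVector
    ia_only_weights: WeightVector
    rg_estimates: list
    h2_by_trait: dict
    nagelkerke_best: dict = field(default_factory=dict)

    def score(self, genotypes, missing_policy: str = "mean_impute"):
        """metaGRS per sample in an arbitrary cohort."""
        return score_cohort(genotypes, self.combined_weights, missing_policy)

    def score_ia_only(self, genotypes, missing_policy: str = "mean_impute"):
        return score_cohort(genotypes, self.ia_only_weights, missing_policy)

    def summary(self) -> pd.DataFrame:
        """Per-trait construction summary (statsmodels-style results table)."""
        rows = []
        for t in self.all_traits:
            i = self.all_traits.index(t)
            rows.append({
                "trait": t,
                "included": t in self.included_traits,
                "elastic_net_gamma": self.gamma_full[i],
                "score_sd": self.s_full[i],
                "h2_ldsc": self.h2_by_trait.get(t, np.nan),
                "nagelkerke_r2": self.nagelkerke_best.get(t, np.nan),
            })
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        """Write the model bundle: per-trait scoring files, the combined
        scoring file, and a YAML manifest with γ_t, s_t and settings."""
        import os

        import yaml

        from .io import write_weights

        os.makedirs(directory, exist_ok=True)
        for wv in self.constituent_weights:
            write_weights(wv, os.path.join(directory, f"trait_{wv.trait}.txt"))
        write_weights(self.combined_weights,
                      os.path.join(directory, "metaGRS.txt"))
        write_weights(self.ia_only_weights,
                      os.path.join(directory, "ia_only.txt"))
        manifest = {
            "stratum": self.stratum,
            "seed": int(self.seed),
            "traits": list(self.included_traits),
            "gamma": np.asarray(self.gamma, float).tolist(),
            "s": np.asarray(self.s, float).tolist(),
            "l1_ratio": self.model.config.l1_ratio,
            "cv_folds": self.model.config.cv_folds,
            "clump_r2_grid": list(self.model.config.clump_r2_grid),
        }
        with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    def __str__(self):
        head = (f"MetaGRSResults(stratum={self.stratum!r}, "
                f"traits={len(self.included_traits)}, "
                f"variants={len(self.combined_weights)})")
        return head + "\n" + self.summary().to_string(index=False)


def build_metagrs(genotypes, phenotypes, disease_sumstats, trait_sumstats,
                  config: MetaGRSConfig | None = None, stratum: str = "all",
                  seed: int | None = None) -> MetaGRSResults:
    """Functional wrapper around :class:`MetaGRS` + :meth:`MetaGRS.fit`."""
    return MetaGRS(genotypes, phenotypes, disease_sumstats, trait_sumstats,
                   config).fit(stratum=stratum, seed=seed)
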