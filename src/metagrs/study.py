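"""Desk-scale study designs: the synthetic counterparts of the metaGRS
workflow's three stages (construction, validation, patient heterogeneity).

These functions bundle the generator settings that define the synthetic
study conditions — a disease with six genetically correlated auxiliary
traits (rg 0.2–0.6), liability-threshold case/control status at 5%
prevalence with proportional-hazards onset, an external GWAS cohort, a
UK-Biobank-like training cohort, a HUNT-like validation cohort, and an
ISGC-like patient cohort — so tests and reproduction scripts exercise one
shared configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import fit_cox, harrell_c
from .grs import SBayesRConfig
from .model import MetaGRS, MetaGRSConfig
from .simulate import (ArchitectureConfig, simulate_effect_matrix,
                       simulate_genotypes, simulate_phenotypes)
from .sumstats import run_gwas

#: genetic correlations of the six auxiliary traits with the disease
AUX_RG = (0.6, 0.5, 0.4, 0.3, 0.2, 0.2)
AUX_H2 = (0.5, 0.5, 0.4, 0.4, 0.3, 0.3)
DISEASE_H2 = 0.3


def shared_architecture_config(seed: int) -> ArchitectureConfig:
    """Disease + six auxiliary traits sharing a polygenic architecture."""
    T = 1 + len(AUX_RG)
    rg = np.eye(T)
    for t, r in enumerate(AUX_RG, start=1):
        rg[0, t] = rg[t, 0] = r
    # auxiliary traits correlate through the disease factor, keeping rg PSD
    for a in range(1, T):
        for b in range(a + 1, T):
            rg[a, b] = rg[b, a] = rg[0, a] * rg[0, b]
    return ArchitectureConfig(
        n_traits=T, h2=np.array((DISEASE_H2,) + AUX_H2), rg=rg,
        causal_fraction=0.5, prevalence=0.05, onset_log_hazard_per_sd=0.3,
        seed=seed)


def metagrs_validation_study(seed: int, n_variants: int = 400,
                             n_blocks: int = 40, n_gwas: int = 6000,
                             n_train: int = 5000, n_valid: int = 6000,
                             sbayesr_iterations: int = 200,
                             sbayesr_burn_in: int = 60) -> dict:
    """One end-to-end replicate: build a metaGRS and validate it.

    Simulates an external GWAS cohort (source of disease and trait summary
    statistics), a training cohort (candidate selection + elastic net), and
    an independent validation cohort; returns the validation hazard ratios
    per SD for the metaGRS and the IA-only comparator, and the C-indices of
    the reference model (sex only) with and without the metaGRS.
    """
    cfg = shared_architecture_config(seed)
    rng = np.random.default_rng(seed)
    block_r = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8], size=n_blocks)
    g_train = simulate_genotypes(n_train, n_variants, n_blocks, (0.1, 0.5),
                                 within_block_r=block_r, seed=seed)
    pop = g_train.population
    effects = simulate_effect_matrix(g_train.variants, cfg)
    ph_train = simulate_phenotypes(g_train, effects, cfg, seed=seed)

    g_gwas = simulate_genotypes(n_gwas, n_variants, n_blocks,
                                seed=seed + 10_000, population=pop)
    ph_gwas = simulate_phenotypes(g_gwas, effects, cfg, seed=seed + 10_000)
    disease_ss = run_gwas(g_gwas, ph_gwas.df["is_case"].to_numpy(float))
    disease_ss.trait = "IA"
    trait_ss = {}
    for t in range(1, cfg.n_traits):
        tab = run_gwas(g_gwas, ph_gwas.traits[:, t])
        tab.trait = f"trait{t}"
        trait_ss[tab.trait] = tab

    mcfg = MetaGRSConfig(
        clump_r2_grid=(0.01, 0.1, 0.4),
        sbayesr=SBayesRConfig(iterations=sbayesr_iterations,
                              burn_in=sbayesr_burn_in, seed=seed),
        seed=seed)
    results = MetaGRS(g_train, ph_train, disease_ss, trait_ss, mcfg).fit()

    g_val = simulate_genotypes(n_valid, n_variants, n_blocks,
                               seed=seed + 20_000, population=pop)
    ph_val = simulate_phenotypes(g_val, effects, cfg, seed=seed + 20_000)
    out = {"n_traits_included": len(results.included_traits), "seed": seed}
    time = ph_val.df["age_event_or_censor"].to_numpy()
    event = (ph_val.df["subtype"] == "ASAH").astype(int).to_numpy()
    sex_male = (ph_val.df["sex"] == "male").astype(float).to_numpy()
    for label, score in (("metagrs", results.score(g_val)),
                         ("ia_only", results.score_ia_only(g_val))):
        z = (score - score.mean()) / score.std()
        df = pd.DataFrame({"time": time, "event": event,
                           "sex_male": sex_male, "score": z})
        cox = fit_cox(df, ["sex_male", "score"])
        out[f"hr_{label}"] = float(cox.hr["score"])
        out[f"hr_{label}_p"] = float(cox.p["score"])
        lp = cox.linear_predictor(df[["sex_male", "score"]])
        out[f"c_{label}"], _ = harrell_c(lp, time, event, n_boot=0)
    ref = fit_cox(pd.DataFrame({"time": time, "event": event,
                                "sex_male": sex_male}), ["sex_male"])
    lp_ref = ref.linear_predictor(pd.DataFrame({"sex_male": sex_male}))
    out["c_reference"], _ = harrell_c(lp_ref, time, event, n_boot=0)
    out["results"] = results
    return out


def rg_recovery_study(seed: int, true_rg: float = 0.5, h2: float = 0.4,
                      n: int = 5000, m: int = 2000, n_blocks: int = 100
                      ) -> dict:
    """Simulate two correlated traits, run GWAS, and estimate rg by LD-score
    regression; returns the estimate, its jackknife SE, and the truth."""
    from .ldsc import ld_scores, ldsc_rg

    cfg = ArchitectureConfig(
        n_traits=2, h2=np.array([h2, h2]),
        rg=np.array([[1.0, true_rg], [true_rg, 1.0]]), seed=seed)
    rng = np.random.default_rng(seed)
    block_r = rng.choice([0.0, 0.3, 0.6, 0.9], size=n_blocks)
    g = simulate_genotypes(n, m, n_blocks, (0.1, 0.5),
                           within_block_r=block_r, seed=seed)
    effects = simulate_effect_matrix(g.variants, cfg)
    ph = simulate_phenotypes(g, effects, cfg, seed=seed)
    ta = run_gwas(g, ph.traits[:, 0])
    tb = run_gwas(g, ph.traits[:, 1])
    ta.trait, tb.trait = "a", "b"
    ells = ld_scores(g, 50)
    est = ldsc_rg(ta, tb, ells)
    return {"rg": est.rg, "se": est.se_rg, "true_rg": true_rg, "seed": seed}


def cox_recovery_study(seed: int, log_hr: float = 0.3, n: int = 4000,
                       baseline_rate: float = 0.02,
                       censor_rate: float = 0.25) -> dict:
    """Direct proportional-hazards simulation: exponential event times with
    log-hazard ``log_hr`` per SD of a standard-normal covariate, independent
    exponential censoring; returns the Cox estimate and Wald CI."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t_event = rng.exponential(1.0 / (baseline_rate * np.exp(log_hr * x)))
    t_cens = rng.exponential(1.0 / (baseline_rate * censor_rate), size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame({"time": time, "event": event, "x": x})
    cox = fit_cox(df, ["x"])
    return {"log_hr": float(np.log(cox.hr["x"])),
            "ci": (float(np.log(cox.ci_lower["x"])),
                   float(np.log(cox.ci_upper["x"]))),
            "n_events": int(event.sum()), "true_log_hr": log_hr,
            "seed": seed}


def age_effect_recovery_study(seed: int, years_per_sd: float = -1.7,
                              n: int = 4000) -> dict:
    """ISGC-like patient cohort with an injected age-at-ASAH effect;
    returns the recovered per-SD estimate and its CI."""
    from .heterogeneity import associate
    from .simulate import PatientEffectConfig, simulate_patient_characteristics

    rng = np.random.default_rng(seed)
    ec = PatientEffectConfig(age_at_asah_years_per_sd=years_per_sd)
    rec = simulate_patient_characteristics(n, rng.standard_normal(n), ec,
                                           seed=seed)
    res = associate(rec, rec["score"].to_numpy(), "age_at_asah")
    return {"effect": res.effect, "ci": (res.ci_lower, res.ci_upper),
            "true_effect": years_per_sd, "seed": seed}
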