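"""Association of the standardized metaGRS with IA patient characteristics.

Generalized linear models with sex and cohort as covariates, Bonferroni
control over the 11 primary phenotypes (rupture status, sex, family history,
IA multiplicity, the 5 grouped locations, age at ASAH, size at rupture),
optional multivariate adjustment for smoking and hypertension, and the
years-earlier quantile computation that converts a per-SD age-at-ASAH effect
into the expected onset shift for a score in the top q of the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError

#: raw location vocabulary -> grouped label
LOCATION_VOCABULARY = {
    # internal carotid artery group
    "ICA": "ICA", "internal carotid artery": "ICA",
    "ophthalmic artery": "ICA", "cavernous artery": "ICA",
    # posterior communicating artery
    "PCOM": "PCOM", "posterior communicating artery": "PCOM",
    # anterior cerebral arteries
    "ACA": "ACA", "anterior cerebral artery": "ACA",
    "A1 segment": "ACA", "A1 anterior segment": "ACA",
    "anterior communicating artery": "ACA", "A2 segment": "ACA",
    # middle cerebral artery
    "MCA": "MCA", "middle cerebral artery": "MCA",
    # posterior circulation (vertebrobasilar system)
    "PC": "PC", "posterior circulation": "PC", "vertebrobasilar": "PC",
    "basilar artery": "PC", "basilar tip": "PC", "vertebral artery": "PC",
    "posterior cerebral artery": "PC", "PICA": "PC",
    "posterior inferior cerebellar artery": "PC",
    # excluded from location analyses
    "other": "other",
}

LOCATION_GROUPS = ("ICA", "PCOM", "ACA", "MCA", "PC")

#: the 11 primary phenotypes behind the Bonferroni correction
PRIMARY_PHENOTYPES = ("rupture_status", "sex", "family_history",
                      "multiplicity") + tuple(
    f"location_{g}" for g in LOCATION_GROUPS) + ("age_at_asah",
                                                 "size_at_rupture")

BINARY_CHARACTERISTICS = {
    "sex", "smoking_ever", "hypertension", "family_history", "multiplicity",
    "rupture_status",
}
CONTINUOUS_CHARACTERISTICS = {"age_at_asah", "size_at_rupture"}


def group_locations(raw_location: str) -> str:
    """Map a raw IA location label onto the five analysis groups (or
    ``other``, which is excluded from location analyses downstream)."""
    if raw_location not in LOCATION_VOCABULARY:
        raise ValidationError(
            f"unknown location {raw_location!r}; known labels: "
            f"{sorted(LOCATION_VOCABULARY)}")
    return LOCATION_VOCABULARY[raw_location]


@dataclass
class AssociationResult:
    """A single score-characteristic association."""

    characteristic: str
    family: str              # "linear" or "logistic"
    effect: float            # per SD of score (years, mm, or log-OR)
    ci_lower: float
    ci_upper: float
    p: float
    covariates: tuple
    n_used: int

    @property
    def odds_ratio(self):
        if self.family != "logistic":
            raise ValidationError("odds ratio undefined for a linear model")
        return float(np.exp(self.effect))

    @property
    def or_ci(self):
        return (float(np.exp(self.ci_lower)), float(np.exp(self.ci_upper)))


def _characteristic_vector(records: pd.DataFrame, characteristic: str):
    if characteristic.startswith("location_"):
        group = characteristic.split("_", 1)[1]
        if group not in LOCATION_GROUPS:
            raise ValidationError(f"unknown location group {group!r}")
        loc = records["location_grouped"]
        y = (loc == group).astype(float)
        y[loc == "other"] = np.nan  # excluded from location analyses
        return y, "logistic"
    if characteristic == "multiplicity":
        return (records["n_aneurysms"] > 1).astype(float), "logistic"
    if characteristic == "rupture_status":
        return (records["rupture_status"] == "ASAH").astype(float), "logistic"
    if characteristic == "sex":
        return (records["sex"] == "female").astype(float), "logistic"
    if characteristic in ("smoking_ever", "hypertension", "family_history"):
        return records[characteristic].astype(float), "logistic"
    if characteristic in CONTINUOUS_CHARACTERISTICS:
        return records[characteristic].astype(float), "linear"
    raise ValidationError(f"unknown characteristic {characteristic!r}")


def _design(records, score_std, covariates, extra=()):
    cols = [score_std]
    names = ["score"]
    if "sex" in covariates:
        cols.append((records["sex"] == "female").astype(float).to_numpy())
        names.append("sex_female")
    if "cohort" in covariates:
        dummies = pd.get_dummies(records["cohort"], drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].astype(float).to_numpy())
            names.append(f"cohort_{c}")
    for name in extra:
        cols.append(records[name].astype(float).to_numpy())
        names.append(name)
    X = np.column_stack(cols)
    return sm.add_constant(X, has_constant="add"), names


def associate(records: pd.DataFrame, score, characteristic: str,
              covariates=("sex", "cohort"),
              single_ia_only_for_location: bool = True,
              min_n: int = 30, extra_covariates=()) -> AssociationResult:
    """GLM association of the standardized score with one characteristic.

    Continuous characteristics (age at ASAH, size at rupture) use a linear
    model of the characteristic on the score, so the effect reads in the
    characteristic's units per SD of score; binary characteristics use
    logistic regression (log-OR per SD).  Sex is dropped from the covariates
    when it is itself the characteristic; location analyses keep only
    single-IA patients and exclude ``other`` locations.  Samples missing the
    characteristic are excluded.
    """
    y, family = _characteristic_vector(records, characteristic)
    covariates = tuple(c for c in covariates
                      if not (characteristic == "sex" and c == "sex"))
    keep = y.notna().to_numpy()
    if characteristic.startswith("location_") and single_ia_only_for_location:
        keep &= (records["n_aneurysms"] == 1).to_numpy()
    s = np.asarray(score, float)
    keep &= np.isfinite(s)
    for name in extra_covariates:
        keep &= records[name].notna().to_numpy()
    n_used = int(keep.sum())
    if n_used < min_n:
        raise ValidationError(
            f"{characteristic}: only {n_used} usable records (< {min_n})")
    sub = records.loc[keep]
    yv = y.to_numpy()[keep]
    sv = s[keep]
    sv = (sv - sv.mean()) / sv.std()
    X, names = _design(sub, sv, covariates, extra=extra_covariates)

    if family == "logistic":
        if len(np.unique(yv)) < 2:
            raise ValidationError(f"{characteristic}: single-level outcome")
        fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
    else:
        fit = sm.OLS(yv, X).fit()
    j = 1  # score column (after the constant)
    eff, se = float(fit.params[j]), float(fit.bse[j])
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        characteristic=characteristic, family=family, effect=eff,
        ci_lower=eff - z * se, ci_upper=eff + z * se,
        p=float(fit.pvalues[j]),
        covariates=covariates + tuple(extra_covariates), n_used=n_used)


def multivariate_adjust(records: pd.DataFrame, score, characteristic: str,
                        extra_covariates=("smoking_ever", "hypertension"),
                        covariates=("sex", "cohort"), **kwargs
                        ) -> AssociationResult:
    """The :func:`associate` model with smoking and hypertension (or any
    other characteristics) added as covariates — the independence check for
    phenotypes that pass the Bonferroni filter."""
    usable = tuple(c for c in extra_covariates
                   if records[c].nunique(dropna=True) > 1)
    return associate(records, score, characteristic, covariates=covariates,
                     extra_covariates=usable, **kwargs)


def bonferroni_threshold(alpha: float = 0.05, k: int = 11) -> float:
    """Family-wise threshold alpha/k for the k primary phenotypes."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    return alpha / k


def classify(p: float, alpha: float = 0.05, k: int = 11) -> str:
    """Label a p-value: ``significant`` below alpha/k, ``nominal`` below
    alpha, ``null`` otherwise."""
    thr = bonferroni_threshold(alpha, k)
    if p < thr:
        return "significant"
    if p < alpha:
        return "nominal"
    return "null"


def years_earlier(beta_years_per_sd: float, upper_quantile: float) -> float:
    """Expected earlier onset (years) for a score at the q-th population
    quantile versus the population mean, assuming a linear per-SD effect:
    |β| × Φ⁻¹(q)."""
    if not 0 < upper_quantile < 1:
        raise ValidationError("quantile must lie in (0, 1)")
    return float(abs(beta_years_per_sd) * stats.norm.ppf(upper_quantile))


def association_table(records: pd.DataFrame, score,
                      characteristics=PRIMARY_PHENOTYPES,
                      covariates=("sex", "cohort"), alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Run :func:`associate` over the primary phenotypes and return a tidy
    table with Bonferroni classification (k = number of phenotypes)."""
    k = len(characteristics)
    rows = []
    for ch in characteristics:
        try:
            res = associate(records, score, ch, covariates=covariates)
        except ValidationError as exc:
            rows.append({"characteristic": ch, "error": str(exc)})
            continue
        rows.append({
            "characteristic": ch, "family": res.family, "effect": res.effect,
            "ci_lower": res.ci_lower, "ci_upper": res.ci_upper, "p": res.p,
            "n_used": res.n_used,
            "classification": classify(res.p, alpha=alpha, k=k),
        })
    return pd.DataFrame(rows)
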