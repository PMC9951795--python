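"""Validation of a risk score in an independent cohort.

Cox proportional hazards (Efron ties, via lifelines) for ASAH incidence with
age at ASAH as the time axis and age at last assessment as censoring time,
logistic regression for IA presence, Harrell's C with bootstrap CI, AUC with
DeLong CI, the DeLong paired-AUC test, continuous (category-free) NRI/IDI
for survival outcomes with inverse-probability-of-censoring weighting, and
the model ladder (reference / reference+score / clinical / full /
full-minus-one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats

from .exceptions import ValidationError


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x, n_knots: int = 3, knots=None) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear in the tails).

    Knots default to the 0.1/0.5/0.9 quantiles for 3 knots (evenly spaced
    inner quantiles otherwise); returns ``n_knots − 1`` columns: the linear
    term plus ``n_knots − 2`` restricted cubic terms, each normalized by
    (t_k − t_1)².
    """
    x = np.asarray(x, float)
    if knots is None:
        if len(np.unique(x)) < n_knots:
            raise ValidationError("x has fewer distinct values than knots")
        if n_knots == 3:
            qs = [0.1, 0.5, 0.9]
        else:
            qs = np.linspace(0.05, 0.95, n_knots)
        knots = np.quantile(x, qs)
    t = np.asarray(knots, float)
    k = len(t)
    if k < 3:
        raise ValidationError("need at least 3 knots")
    if len(np.unique(t)) != k:
        raise ValidationError("knots must be distinct (constant x?)")
    cols = [x]
    denom = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.clip(u, 0, None) ** 3

    for j in range(k - 2):
        cj = (pos3(x - t[j])
              - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
              + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(cj / denom)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratios with Wald CIs plus the partial log-likelihood."""

    params: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    se: pd.Series
    p: pd.Series
    log_likelihood: float
    fitter: CoxPHFitter

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        cols = list(self.params.index)
        return np.asarray(df[cols], float) @ self.params.to_numpy()


def fit_cox(df: pd.DataFrame, covariates: list, time_col: str = "time",
            event_col: str = "event", standardize: list | None = None
            ) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling.

    Columns named in ``standardize`` are scaled to unit SD first, so their
    hazard ratios read per SD.
    """
    data = df[covariates + [time_col, event_col]].copy()
    if data[event_col].sum() < 1:
        raise ValidationError("need at least one event")
    for c in covariates:
        if data[c].std() == 0:
            raise ValidationError(f"constant covariate {c!r}")
    for c in (standardize or []):
        data[c] = (data[c] - data[c].mean()) / data[c].std()
    cph = CoxPHFitter()
    cph.fit(data, duration_col=time_col, event_col=event_col)
    ci = np.exp(cph.confidence_intervals_)
    return CoxResult(
        params=cph.params_,
        hr=np.exp(cph.params_),
        ci_lower=ci.iloc[:, 0],
        ci_upper=ci.iloc[:, 1],
        se=cph.standard_errors_,
        p=cph.summary["p"],
        log_likelihood=float(cph.log_likelihood_),
        fitter=cph,
    )


def harrell_c(risk, time, event, n_boot: int = 200, seed: int = 0,
              alpha: float = 0.05) -> tuple[float, tuple]:
    """Harrell's concordance index with a seeded bootstrap CI.

    C = (concordant + 0.5·risk ties) / comparable, where pair (i, j) is
    comparable if time_i < time_j and subject i had the event.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    c = _c_index(risk, time, event)
    if n_boot == 0:
        return c, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    n = len(risk)
    reps = []
    for _ in range(n_boot):
        ix = rng.integers(0, n, n)
        try:
            reps.append(_c_index(risk[ix], time[ix], event[ix]))
        except ValidationError:
            continue
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return c, (float(lo), float(hi))


def _c_index(risk, time, event):
    if event.sum() == 0:
        raise ValidationError("no comparable pairs (no events)")
    # lifelines' concordance counts higher predicted *survival* as concordant
    # with longer observed time; pass -risk so higher risk ~ earlier event.
    return float(concordance_index(time, -risk, event))


# ---------------------------------------------------------------------------
# Logistic model, AUC, DeLong
# ---------------------------------------------------------------------------

@dataclass
class LogisticResult:
    params: pd.Series
    odds_ratio: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    auc: float
    auc_ci: tuple
    fitted_prob: np.ndarray
    penalized: bool = False


def _auc_mann_whitney(pred, outcome):
    pred = np.asarray(pred, float)
    y = np.asarray(outcome, int)
    pos, neg = pred[y == 1], pred[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes required for AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg))


def _delong_components(pred, outcome):
    """Structural components (V10, V01) of the AUC estimator."""
    pred = np.asarray(pred, float)
    y = np.asarray(outcome, int)
    pos, neg = pred[y == 1], pred[y == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1[x>y] + 0.5 1[x==y]
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    return v10, v01


def delong_auc_variance(pred, outcome) -> tuple[float, float]:
    v10, v01 = _delong_components(pred, outcome)
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + (
        np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    return float(auc), float(var)


def delong_test(pred_a, pred_b, outcome) -> tuple[float, float]:
    """DeLong test for the difference of two correlated AUCs on paired
    predictions; returns (ΔAUC = AUC_a − AUC_b, two-sided p)."""
    pred_a, pred_b = np.asarray(pred_a, float), np.asarray(pred_b, float)
    if len(pred_a) != len(pred_b):
        raise ValidationError("predictions must be paired on identical samples")
    if np.all(pred_a == pred_a[0]) and np.all(pred_b == pred_b[0]):
        raise ValidationError("degenerate (all-tied) predictions")
    va10, va01 = _delong_components(pred_a, outcome)
    vb10, vb01 = _delong_components(pred_b, outcome)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01])) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 1.0
    z = delta / np.sqrt(var)
    return delta, float(np.clip(2 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def fit_logistic_auc(outcome, covariates, alpha: float = 0.05
                     ) -> LogisticResult:
    """Maximum-likelihood logistic fit with ORs, Wald CIs, and AUC with a
    DeLong CI on the fitted probabilities.  Separation triggers a flagged
    small-ridge fallback."""
    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required")
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    Xc = sm.add_constant(X, has_constant="add")
    penalized = False
    model = sm.Logit(y, Xc)
    try:
        fit = model.fit(disp=0, maxiter=200)
        params, bse = fit.params, fit.bse
        if not np.all(np.isfinite(bse)) or np.any(bse > 1e3):
            raise ValueError("unstable SEs")
        prob = fit.predict(Xc)
    except Exception:
        penalized = True
        res = model.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
        params = np.asarray(res.params)
        cov = np.linalg.pinv(-model.hessian(params) + 2e-3 * np.eye(len(params)))
        bse = np.sqrt(np.diag(cov))
        prob = model.predict(params, Xc)
    z = stats.norm.ppf(1 - alpha / 2)
    names = [f"x{i}" for i in range(Xc.shape[1] - 1)]
    idx = pd.Index(["const"] + names)
    params = pd.Series(np.asarray(params), index=idx)
    bse = pd.Series(np.asarray(bse), index=idx)
    auc, var = delong_auc_variance(prob, y)
    half = z * np.sqrt(var)
    pvals = pd.Series(
        2 * stats.norm.sf(np.abs(params.to_numpy() / bse.to_numpy())), index=idx)
    return LogisticResult(
        params=params.iloc[1:],
        odds_ratio=np.exp(params.iloc[1:]),
        ci_lower=np.exp(params.iloc[1:] - z * bse.iloc[1:]),
        ci_upper=np.exp(params.iloc[1:] + z * bse.iloc[1:]),
        p=pvals.iloc[1:],
        auc=auc,
        auc_ci=(max(auc - half, 0.0), min(auc + half, 1.0)),
        fitted_prob=np.asarray(prob),
        penalized=penalized,
    )


# ---------------------------------------------------------------------------
# Survival NRI / IDI with IPCW
# ---------------------------------------------------------------------------

def _ipcw_weights(time, event, t0):
    """Inverse-probability-of-censoring weights at horizon t0.

    Events before t0 get 1/Ĝ(T−); subjects still at risk at t0 get 1/Ĝ(t0);
    subjects censored before t0 get weight 0.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    w = np.zeros(len(time))
    is_case = (time <= t0) & (event == 1)
    at_risk = time > t0
    if is_case.any():
        G_case = np.clip(
            kmf.predict(time[is_case]).to_numpy(), 1e-6, 1.0)
        w[is_case] = 1.0 / G_case
    Gt0 = float(np.clip(kmf.predict(t0), 1e-6, 1.0))
    w[at_risk] = 1.0 / Gt0
    return w, is_case, at_risk


def nri_idi(risk_old, risk_new, time, event, t0: float | None = None,
            n_perturb: int = 300, seed: int = 0) -> dict:
    """Continuous NRI and IDI for survival outcomes with IPCW at horizon t0.

    ``risk_*`` are predicted event probabilities by t0 in [0, 1].  Inference
    is by perturbation resampling with exponential weights (seeded); with no
    censoring and all follow-up beyond t0 the estimates reduce to the
    binary-outcome closed forms.
    """
    risk_old = np.asarray(risk_old, float)
    risk_new = np.asarray(risk_new, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if np.any((risk_old < 0) | (risk_old > 1) | (risk_new < 0) | (risk_new > 1)):
        raise ValidationError("risks must lie in [0, 1]")
    if t0 is None:
        t0 = float(np.quantile(time, 0.9))
    if t0 > time.max():
        raise ValidationError("t0 exceeds maximum follow-up")
    if not np.any((time <= t0) & (event == 1)):
        raise ValidationError("no events before t0")

    base_w, is_case, at_risk = _ipcw_weights(time, event, t0)
    up = risk_new > risk_old
    down = risk_new < risk_old

    def compute(pw):
        w = base_w * pw
        wc, wn = w[is_case], w[at_risk]
        if wc.sum() == 0 or wn.sum() == 0:
            return np.nan, np.nan
        nri_case = (np.sum(wc * up[is_case]) - np.sum(wc * down[is_case])) / wc.sum()
        nri_ctrl = (np.sum(wn * down[at_risk]) - np.sum(wn * up[at_risk])) / wn.sum()
        nri = nri_case + nri_ctrl
        mean = lambda r, wt: np.sum(wt * r) / wt.sum()
        idi = ((mean(risk_new[is_case], wc) - mean(risk_new[at_risk], wn))
               - (mean(risk_old[is_case], wc) - mean(risk_old[at_risk], wn)))
        return nri, idi

    nri, idi = compute(np.ones(len(time)))
    rng = np.random.default_rng(seed)
    reps = np.array([compute(rng.exponential(1.0, len(time)))
                     for _ in range(n_perturb)])
    reps = reps[np.isfinite(reps).all(axis=1)]

    def pval(est, col):
        sd = reps[:, col].std(ddof=1)
        if sd == 0:
            return 1.0 if est == 0 else 0.0
        return float(np.clip(2 * stats.norm.sf(abs(est) / sd), 1e-300, 1.0))

    return {
        "nri": float(nri), "nri_p": pval(nri, 0),
        "idi": float(idi), "idi_p": pval(idi, 1),
        "t0": float(t0), "n_perturb": int(n_perturb),
    }


# ---------------------------------------------------------------------------
# Model ladder
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """One row of the model ladder: effect, discrimination, increments."""

    endpoint: str            # "asah_cox" or "ia_logistic"
    label: str
    effect_per_sd: float | None
    effect_ci: tuple | None
    discrimination: float
    discrimination_ci: tuple
    delta_auc: float | None = None
    delong_p: float | None = None
    nri: float | None = None
    nri_p: float | None = None
    idi: float | None = None
    idi_p: float | None = None


def _ladder_design(df, use_age, use_clinical, use_score):
    cols = {"sex_male": (df["sex"] == "male").astype(float).to_numpy()}
    if use_age:
        cols["age"] = df["age"].to_numpy()
    if use_clinical:
        sbp = rcs_basis(df["sbp"].to_numpy())
        smk = rcs_basis(df["smoking_packs_per_day"].to_numpy())
        for i in range(sbp.shape[1]):
            cols[f"sbp_rcs{i}"] = sbp[:, i]
        for i in range(smk.shape[1]):
            cols[f"smoking_rcs{i}"] = smk[:, i]
    if use_score:
        s = df["score"].to_numpy()
        cols["score"] = (s - s.mean()) / s.std()
    return pd.DataFrame(cols, index=df.index)


def model_ladder(cohort: pd.DataFrame, score, training_sample_ids=None,
                 t0: float | None = None, n_boot: int = 200,
                 n_perturb: int = 300, seed: int = 0) -> pd.DataFrame:
    """The five-model comparison ladder for both endpoints.

    ``cohort`` needs columns sample_id, sex, is_case, subtype,
    age_event_or_censor, sbp, smoking_packs_per_day.  The ASAH endpoint uses
    Cox regression (age at ASAH as outcome; age itself excluded as a
    covariate), the IA endpoint logistic regression with age as covariate.
    If ``training_sample_ids`` is given, overlap with the cohort raises.
    """
    if training_sample_ids is not None:
        overlap = set(training_sample_ids) & set(cohort["sample_id"])
        if overlap:
            raise ValidationError(
                f"validation cohort overlaps training ({len(overlap)} samples)")
    df = cohort.copy()
    df["score"] = np.asarray(score, float)
    df["age"] = df["age_event_or_censor"].to_numpy()
    df["time"] = df["age_event_or_censor"].to_numpy()
    df["event"] = (df["subtype"] == "ASAH").astype(int).to_numpy()
    df["ia"] = df["is_case"].astype(int).to_numpy()

    ladder = {
        "reference": dict(use_clinical=False, use_score=False),
        "reference+metaGRS": dict(use_clinical=False, use_score=True),
        "clinical": dict(use_clinical=True, use_score=False),
        "full": dict(use_clinical=True, use_score=True),
        "full-metaGRS": dict(use_clinical=True, use_score=False),
        "full-clinical": dict(use_clinical=False, use_score=True),
    }
    baselines = {"reference+metaGRS": "reference", "full": "clinical",
                 "full-metaGRS": "full", "full-clinical": "full"}

    rows, cox_risk, logit_prob = [], {}, {}
    for label, parts in ladder.items():
        # --- Cox endpoint (no age covariate)
        Xc = _ladder_design(df, use_age=False, **parts)
        cox_df = pd.concat([Xc, df[["time", "event"]]], axis=1)
        res = fit_cox(cox_df, list(Xc.columns))
        lp = res.linear_predictor(Xc)
        cox_risk[label] = lp
        c, c_ci = harrell_c(lp, df["time"], df["event"], n_boot=n_boot,
                            seed=seed)
        eff = ci = None
        if parts["use_score"]:
            eff = float(res.hr["score"])
            ci = (float(res.ci_lower["score"]), float(res.ci_upper["score"]))
        row = ModelComparison("asah_cox", label, eff, ci, c, c_ci)
        base = baselines.get(label)
        if base is not None:
            horizon = t0 if t0 is not None else float(np.quantile(df["time"], 0.9))
            out = nri_idi(_cox_risk_at(cox_risk[base], df, horizon),
                          _cox_risk_at(lp, df, horizon),
                          df["time"].to_numpy(), df["event"].to_numpy(),
                          t0=horizon, n_perturb=n_perturb, seed=seed)
            row.nri, row.nri_p = out["nri"], out["nri_p"]
            row.idi, row.idi_p = out["idi"], out["idi_p"]
        rows.append(row)

        # --- logistic endpoint (age as covariate)
        Xl = _ladder_design(df, use_age=True, **parts)
        lres = fit_logistic_auc(df["ia"].to_numpy(), Xl.to_numpy())
        logit_prob[label] = lres.fitted_prob
        eff = ci = None
        if parts["use_score"]:
            i = list(Xl.columns).index("score")
            eff = float(lres.odds_ratio.iloc[i])
            ci = (float(lres.ci_lower.iloc[i]), float(lres.ci_upper.iloc[i]))
        row = ModelComparison("ia_logistic", label, eff, ci, lres.auc,
                              lres.auc_ci)
        if base is not None:
            d, p = delong_test(logit_prob[label], logit_prob[base],
                               df["ia"].to_numpy())
            row.delta_auc, row.delong_p = d, p
        rows.append(row)

    return pd.DataFrame([r.__dict__ for r in rows])


def _cox_risk_at(lp, df, t0):
    """Breslow-baseline event probability by t0 from a linear predictor."""
    time = df["time"].to_numpy()
    event = df["event"].to_numpy()
    order = np.argsort(time)
    t_sorted, e_sorted = time[order], event[order]
    elp = np.exp(lp - lp.mean())
    elp_sorted = elp[order]
    at_risk = np.cumsum(elp_sorted[::-1])[::-1]
    h0 = np.where(e_sorted == 1, 1.0 / at_risk, 0.0)
    H0_t0 = h0[t_sorted <= t0].sum()
    return np.clip(1.0 - np.exp(-H0_t0 * elp), 0.0, 1.0)
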