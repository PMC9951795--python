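"""GWAS summary statistics: container, TSV I/O, allele harmonization,
single-variant association scans, and fixed-effect stratum meta-analysis.

The on-disk dialect is a GWAS-SSF-like tab-separated table with columns

    variant_id  chromosome  base_pair_location  effect_allele  other_allele
    beta  standard_error  p_value  effect_allele_frequency  n

``effect_allele_frequency`` may be absent; the table then loads with
``has_eaf`` False and downstream methods that need frequencies refuse.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlleleError,
    DuplicateVariantError,
    MissingColumnError,
    MonomorphicVariantError,
    ValidationError,
)

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
    "n",
]
OPTIONAL_COLUMNS = ["effect_allele_frequency"]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP identified by id, position and allele pair."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self):
        if self.effect_allele not in BASES or self.other_allele not in BASES:
            raise AlleleError(
                f"{self.id}: alleles must be single A/C/G/T bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise AlleleError(f"{self.id}: effect and other allele coincide")
        if self.pos <= 0:
            raise ValidationError(f"{self.id}: position must be positive")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


class SumStatsTable:
    """Marginal per-variant effects (beta, SE, p, N, EAF) for one trait.

    Wraps a :class:`pandas.DataFrame` in the column dialect above.

    Parameters
    ----------
    df : DataFrame
        One row per variant; ``variant_id`` unique; ``standard_error`` > 0.
    trait : str
        Trait label carried through to weight-file metadata.
    effect_scale : {"dosage", "standardized"}
        Scale of ``beta``: per effect-allele dosage, or per SD of the
        standardized genotype.
    """

    def __init__(self, df: pd.DataFrame, trait: str = "trait",
                 effect_scale: str = "dosage", validate: bool = True):
        if effect_scale not in ("dosage", "standardized"):
            raise ValidationError(f"unknown effect_scale {effect_scale!r}")
        self.df = df.reset_index(drop=True)
        self.trait = trait
        self.effect_scale = effect_scale
        if validate:
            self._validate()

    def _validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise MissingColumnError(f"missing required columns: {missing}")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise DuplicateVariantError(
                f"duplicate variant id(s): {sorted(set(dup))[:5]}"
            )
        for col in ("effect_allele", "other_allele"):
            bad = ~self.df[col].isin(list(BASES))
            if bad.any():
                raise AlleleError(
                    f"unparseable alleles in {col}: "
                    f"{self.df.loc[bad, col].unique()[:5].tolist()}"
                )
        same = self.df["effect_allele"] == self.df["other_allele"]
        if same.any():
            raise AlleleError(
                "effect and other allele coincide for "
                f"{self.df.loc[same, 'variant_id'].tolist()[:5]}"
            )
        if (self.df["standard_error"] <= 0).any():
            raise ValidationError("standard_error must be strictly positive")
        p = self.df["p_value"]
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("p_value must lie in (0, 1]")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_eaf(self) -> bool:
        return (
            "effect_allele_frequency" in self.df.columns
            and self.df["effect_allele_frequency"].notna().all()
        )

    def require_eaf(self, context: str = "this operation") -> None:
        if not self.has_eaf:
            raise ValidationError(
                f"{context} requires effect_allele_frequency, which this "
                "table does not carry"
            )

    def variants(self) -> list[Variant]:
        return [
            Variant(r.variant_id, str(r.chromosome), int(r.base_pair_location),
                    r.effect_allele, r.other_allele)
            for r in self.df.itertuples()
        ]

    def zscores(self) -> np.ndarray:
        return self.df["beta"].to_numpy() / self.df["standard_error"].to_numpy()


def write_sumstats(table: SumStatsTable, path) -> None:
    cols = REQUIRED_COLUMNS + [
        c for c in OPTIONAL_COLUMNS if c in table.df.columns
    ]
    with open(path, "w") as fh:
        fh.write(f"#trait={table.trait}\n#effect_scale={table.effect_scale}\n")
        table.df[cols].to_csv(fh, sep="\t", index=False)


def read_sumstats(path) -> SumStatsTable:
    meta = {"trait": "trait", "effect_scale": "dosage"}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].strip().partition("=")
            if key in meta:
                meta[key] = value
    df = pd.read_csv(path, sep="\t", skiprows=skip,
                     dtype={"chromosome": str, "variant_id": str})
    return SumStatsTable(df, trait=meta["trait"],
                         effect_scale=meta["effect_scale"])


# ---------------------------------------------------------------------------
# Harmonization against a reference variant set
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeReport:
    """Counts of rows kept/dropped by :func:`harmonize`, by reason."""

    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_strand_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0
    n_dropped_missing_reference: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def harmonize(table: SumStatsTable, reference_variants: list[Variant],
              drop_ambiguous: bool = True) -> tuple[SumStatsTable, HarmonizeReport]:
    """Align a summary-statistic table to a reference allele encoding.

    Rows whose effect/other alleles are swapped relative to the reference get
    their beta sign flipped and EAF complemented; strand flips (A<->T, C<->G)
    are resolved by complementing before matching; palindromic (A/T, C/G)
    variants are dropped when ``drop_ambiguous``; unresolvable rows are
    dropped and counted.  Never raises on allele mismatch — the report
    carries the drop reasons.
    """
    ref = {v.id: v for v in reference_variants}
    report = HarmonizeReport(n_input=len(table))
    rows = []
    has_eaf = "effect_allele_frequency" in table.df.columns
    for row in table.df.itertuples(index=False):
        v = ref.get(row.variant_id)
        if v is None:
            report.n_dropped_missing_reference += 1
            continue
        ea, oa = row.effect_allele, row.other_allele
        if COMPLEMENT[ea] == oa:  # palindromic: strand is unverifiable
            if drop_ambiguous:
                report.n_dropped_palindromic += 1
                continue
        d = row._asdict()
        if (ea, oa) == (v.effect_allele, v.other_allele):
            pass
        elif (ea, oa) == (v.other_allele, v.effect_allele):
            d["beta"] = -d["beta"]
            if has_eaf and d.get("effect_allele_frequency") is not None:
                d["effect_allele_frequency"] = 1 - d["effect_allele_frequency"]
            report.n_flipped += 1
        elif (COMPLEMENT[ea], COMPLEMENT[oa]) == (v.effect_allele, v.other_allele):
            report.n_strand_flipped += 1
        elif (COMPLEMENT[ea], COMPLEMENT[oa]) == (v.other_allele, v.effect_allele):
            d["beta"] = -d["beta"]
            if has_eaf and d.get("effect_allele_frequency") is not None:
                d["effect_allele_frequency"] = 1 - d["effect_allele_frequency"]
            report.n_strand_flipped += 1
            report.n_flipped += 1
        else:
            report.n_dropped_unmatched += 1
            continue
        d["effect_allele"] = v.effect_allele
        d["other_allele"] = v.other_allele
        rows.append(d)
    report.n_kept = len(rows)
    out = pd.DataFrame(rows, columns=table.df.columns)
    return (
        SumStatsTable(out, trait=table.trait, effect_scale=table.effect_scale,
                      validate=False),
        report,
    )


# ---------------------------------------------------------------------------
# Single-variant association scan
# ---------------------------------------------------------------------------

def run_gwas(genotypes, phenotype, covariates=None, family: str = "linear"
             ) -> SumStatsTable:
    """Per-variant marginal regression of a phenotype on allele dosage.

    Linear family: OLS Wald test, vectorized across variants with per-variant
    exclusion of samples missing that dosage.  Logistic family: per-variant
    Newton fit.  EAF is the mean observed dosage / 2; per-variant ``n`` is the
    non-missing sample count.

    Monomorphic variants are recorded as failures and omitted from the output.
    """
    if family not in ("linear", "logistic"):
        raise ValidationError(f"unknown family {family!r}")
    y = np.asarray(phenotype, dtype=float)
    if np.nanstd(y) == 0:
        raise ValidationError("phenotype is constant")
    D = genotypes.dosages  # n x m, NaN = missing
    n, m = D.shape
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    else:
        C = np.ones((n, 1))

    records, failures = [], []
    if family == "linear":
        # residualize y on covariates once; per-variant missing handled by
        # nan-aware cross products on covariate-residualized dosages
        Q, _ = np.linalg.qr(C)
        y_res = y - Q @ (Q.T @ y)
        obs = ~np.isnan(D)
        nv = obs.sum(axis=0)
        D0 = np.where(obs, D, 0.0)
        Dres = D0 - Q @ (Q.T @ D0)
        Dres = np.where(obs, Dres, 0.0)
        sxy = Dres.T @ y_res
        sx = Dres.sum(axis=0)
        sxx = (Dres**2).sum(axis=0)
        sy = obs.T @ y_res
        syy = obs.T @ y_res**2
        # per-variant simple regression on residualized scales
        mean_x = sx / nv
        mean_y = sy / nv
        var_x = sxx / nv - mean_x**2
        cov_xy = sxy / nv - mean_x * mean_y
        var_y = syy / nv - mean_y**2
        dof = nv - 1 - C.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = cov_xy / var_x
            resid_var = np.maximum(var_y - beta * cov_xy, 0.0) * nv / np.maximum(dof, 1)
            se = np.sqrt(resid_var / (var_x * nv))
        ok = (var_x > 0) & np.isfinite(se) & (se > 0)
        pvals = np.clip(2 * stats.norm.sf(np.abs(np.where(ok, beta / np.where(
            se > 0, se, 1.0), 0.0))), 1e-300, 1.0)
        eaf = np.nanmean(D, axis=0) / 2
        for j in range(m):
            if not ok[j]:
                failures.append((genotypes.variants[j].id, "monomorphic"))
                continue
            records.append(_gwas_row(genotypes.variants[j], beta[j], se[j],
                                     pvals[j], nv[j], eaf[j]))
    else:
        import statsmodels.api as sm
        for j in range(m):
            d = D[:, j]
            keep = ~np.isnan(d) & ~np.isnan(y)
            dj, yj = d[keep], y[keep]
            if np.std(dj) == 0:
                failures.append((genotypes.variants[j].id, "monomorphic"))
                continue
            X = np.column_stack([C[keep], dj])
            try:
                fit = sm.Logit(yj, X).fit(disp=0, maxiter=100)
                beta, se = fit.params[-1], fit.bse[-1]
            except Exception as exc:  # perfect separation etc.
                failures.append((genotypes.variants[j].id, str(exc)))
                continue
            if not np.isfinite(se) or se == 0:
                failures.append((genotypes.variants[j].id, "unstable fit"))
                continue
            records.append(_gwas_row(genotypes.variants[j], beta, se,
                                     _pnorm2(beta / se), keep.sum(),
                                     dj.mean() / 2))
    df = pd.DataFrame.from_records(
        records,
        columns=REQUIRED_COLUMNS[:5] + ["beta", "standard_error", "p_value",
                                        "n", "effect_allele_frequency"],
    )
    out = SumStatsTable(df, trait="gwas", effect_scale="dosage", validate=False)
    out.failures = failures
    return out


def _pnorm2(z: float) -> float:
    return float(np.clip(2 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def _gwas_row(v: Variant, beta, se, p, n, eaf):
    return (v.id, v.chrom, v.pos, v.effect_allele, v.other_allele,
            float(beta), float(se), float(p), int(n), float(eaf))


# ---------------------------------------------------------------------------
# Fixed-effect inverse-variance meta-analysis across strata
# ---------------------------------------------------------------------------

def ivw_meta(tables: list[SumStatsTable]) -> SumStatsTable:
    """Fixed-effect inverse-variance-weighted meta-analysis per variant.

    beta = Σ(β_i/se_i²)/Σ(1/se_i²), se = (Σ 1/se_i²)^(−1/2), p from a
    two-sided normal test; variants present in only some strata are combined
    over the strata that carry them; sample sizes are summed.
    """
    if not tables:
        raise ValidationError("ivw_meta requires at least one table")
    frames = [t.df for t in tables]
    cat = pd.concat(frames, ignore_index=True)
    w = 1.0 / cat["standard_error"] ** 2
    cat = cat.assign(_w=w, _wb=w * cat["beta"])
    if "effect_allele_frequency" in cat.columns:
        cat = cat.assign(_wf=cat["_w"] * cat["effect_allele_frequency"])
    grp = cat.groupby("variant_id", sort=False)
    agg = grp.agg(
        chromosome=("chromosome", "first"),
        base_pair_location=("base_pair_location", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
        _sw=("_w", "sum"),
        _swb=("_wb", "sum"),
        n=("n", "sum"),
    )
    beta = agg["_swb"] / agg["_sw"]
    se = 1.0 / np.sqrt(agg["_sw"])
    out = pd.DataFrame({
        "variant_id": agg.index,
        "chromosome": agg["chromosome"].to_numpy(),
        "base_pair_location": agg["base_pair_location"].to_numpy(),
        "effect_allele": agg["effect_allele"].to_numpy(),
        "other_allele": agg["other_allele"].to_numpy(),
        "beta": beta.to_numpy(),
        "standard_error": se.to_numpy(),
        "p_value": [_pnorm2(z) for z in (beta / se)],
        "n": agg["n"].to_numpy(),
    })
    if "_wf" in cat.columns:
        out["effect_allele_frequency"] = (
            grp["_wf"].sum() / agg["_sw"]).to_numpy()
    return SumStatsTable(out.reset_index(drop=True), trait=tables[0].trait,
                         effect_scale=tables[0].effect_scale, validate=False)


def leave_one_out_meta(tables: list[SumStatsTable], leave_out_index: int
                       ) -> SumStatsTable:
    """IVW meta-analysis of all strata except the indexed one."""
    if len(tables) < 2:
        raise ValidationError("leave-one-out needs at least two strata")
    if not 0 <= leave_out_index < len(tables):
        raise IndexError(f"leave_out_index {leave_out_index} out of range")
    rest = [t for i, t in enumerate(tables) if i != leave_out_index]
    return ivw_meta(rest)
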