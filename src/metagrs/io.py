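"""File formats: PGS-Catalog-style scoring files, phenotype and dosage TSVs,
PLINK1 BED/BIM/FAM, VCF genotype reading, and architecture config YAML.

Phenotype TSV columns: sample_id, sex, is_case, subtype,
age_event_or_censor, sbp, smoking_packs_per_day, stratum.

Dosage TSV: one row per variant with columns variant_id, chromosome,
base_pair_location, effect_allele, other_allele, block, then one column per
sample; missing dosages are written as NA.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .grs import WeightVector
from .simulate import ArchitectureConfig, GenotypeMatrix
from .sumstats import Variant

# ---------------------------------------------------------------------------
# PGS-Catalog-style scoring files
# ---------------------------------------------------------------------------

_WEIGHT_COLS = ["rsID", "chr_name", "chr_position", "effect_allele",
                "other_allele", "effect_weight"]


def write_weights(weights: WeightVector, path) -> None:
    """Write a scoring file with header comments carrying the metadata."""
    with open(path, "w") as fh:
        fh.write(f"#trait={weights.trait}\n#method={weights.method}\n")
        for k, v in weights.hyperparameters.items():
            fh.write(f"#hp_{k}={v}\n")
        if weights.seed is not None:
            fh.write(f"#seed={weights.seed}\n")
        out = weights.df.rename(columns={
            "variant_id": "rsID", "chromosome": "chr_name",
            "base_pair_location": "chr_position", "weight": "effect_weight"})
        out[_WEIGHT_COLS].to_csv(fh, sep="\t", index=False)


def read_weights(path) -> WeightVector:
    meta, hp, seed, skip = {}, {}, None, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].strip().partition("=")
            if key.startswith("hp_"):
                hp[key[3:]] = value
            elif key == "seed":
                seed = int(value)
            else:
                meta[key] = value
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"chr_name": str})
    missing = [c for c in _WEIGHT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"scoring file missing columns: {missing}")
    df = df.rename(columns={
        "rsID": "variant_id", "chr_name": "chromosome",
        "chr_position": "base_pair_location", "effect_weight": "weight"})
    return WeightVector(df, trait=meta.get("trait", "trait"),
                        method=meta.get("method", "unknown"),
                        hyperparameters=hp, seed=seed)


# ---------------------------------------------------------------------------
# Phenotype / dosage TSV
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["sample_id", "sex", "is_case", "subtype",
                     "age_event_or_censor", "sbp", "smoking_packs_per_day",
                     "stratum"]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    df["is_case"] = df["is_case"].astype(bool)
    return df


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    meta = pd.DataFrame({
        "variant_id": [v.id for v in genotypes.variants],
        "chromosome": [v.chrom for v in genotypes.variants],
        "base_pair_location": [v.pos for v in genotypes.variants],
        "effect_allele": [v.effect_allele for v in genotypes.variants],
        "other_allele": [v.other_allele for v in genotypes.variants],
        "block": genotypes.block_index,
    })
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.sample_ids)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False,
                                          na_rep="NA",
                                          float_format="%.6g")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str},
                     na_values=["NA"])
    meta_cols = ["variant_id", "chromosome", "base_pair_location",
                 "effect_allele", "other_allele", "block"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"dosage table missing columns: {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    variants = [Variant(r.variant_id, str(r.chromosome),
                        int(r.base_pair_location), r.effect_allele,
                        r.other_allele) for r in df.itertuples()]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(sample_ids, variants, dosages,
                          df["block"].to_numpy())


# ---------------------------------------------------------------------------
# PLINK1 BED/BIM/FAM (SNP-major 2-bit codec)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes, counting effect (BIM allele-1) dosage: 00=2 copies of a1,
# 01=missing, 10=1 copy, 11=0 copies.  PLINK counts A1; we store the
# effect allele as A1 so dosage = number of A1 alleles.
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write PLINK1 .bed/.bim/.fam; the effect allele is stored as A1."""
    prefix = str(prefix)
    with open(prefix + ".fam", "w") as fh:
        for sid in genotypes.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for v, b in zip(genotypes.variants, genotypes.block_index):
            fh.write(f"{v.chrom} {v.id} 0 {v.pos} "
                     f"{v.effect_allele} {v.other_allele}\n")
    n = genotypes.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(genotypes.n_variants):
            col = genotypes.dosages[:, j]
            buf = bytearray(n_bytes)
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[float(d)]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


def read_plink(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None)
    sample_ids = fam[1].astype(str).tolist()
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    variants = [Variant(r.id, r.chrom, int(r.pos), r.a1, r.a2)
                for r in bim.itertuples()]
    n, m = len(sample_ids), len(variants)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValidationError("not a SNP-major PLINK1 .bed file")
        data = fh.read()
    if len(data) != n_bytes * m:
        raise ValidationError(".bed size does not match .fam/.bim")
    dosages = np.empty((n, m))
    for j in range(m):
        chunk = data[j * n_bytes:(j + 1) * n_bytes]
        for i in range(n):
            code = (chunk[i // 4] >> (2 * (i % 4))) & 0b11
            dosages[i, j] = _CODE_TO_DOSAGE[code]
    return GenotypeMatrix(sample_ids, variants, dosages, np.zeros(m, int))


# ---------------------------------------------------------------------------
# VCF reading (GT-based dosages)
# ---------------------------------------------------------------------------

def read_vcf(path, effect_allele: str = "alt") -> GenotypeMatrix:
    """Read hard-call genotypes from a VCF; dosage counts ALT alleles by
    default (``effect_allele='alt'``).  Requires cyvcf2."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # biallelic SNPs only
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if effect_allele == "alt":
            variants.append(Variant(vid, rec.CHROM, rec.POS, alt, ref))
        else:
            variants.append(Variant(vid, rec.CHROM, rec.POS, ref, alt))
        gts = rec.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        d = np.where(gts == 0, 0.0,
                     np.where(gts == 1, 1.0,
                              np.where(gts == 3, 2.0, np.nan)))
        if effect_allele != "alt":
            d = 2.0 - d
        cols.append(d)
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, variants, dosages,
                          np.zeros(len(variants), int))


# ---------------------------------------------------------------------------
# Architecture config YAML
# ---------------------------------------------------------------------------

def write_architecture_config(config: ArchitectureConfig, path) -> None:
    payload = {
        "n_traits": int(config.n_traits),
        "h2": np.asarray(config.h2, float).tolist(),
        "rg": np.asarray(config.rg, float).tolist(),
        "causal_fraction": float(config.causal_fraction),
        "disease_trait_index": int(config.disease_trait_index),
        "prevalence": float(config.prevalence),
        "onset_log_hazard_per_sd": float(config.onset_log_hazard_per_sd),
        "asah_fraction": float(config.asah_fraction),
        "sbp_liability_corr": float(config.sbp_liability_corr),
        "smoking_liability_corr": float(config.smoking_liability_corr),
        "uia_detection_prob": float(config.uia_detection_prob),
        "seed": int(config.seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_architecture_config(path) -> ArchitectureConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return ArchitectureConfig(
        n_traits=payload["n_traits"],
        h2=np.asarray(payload["h2"], float),
        rg=np.asarray(payload["rg"], float),
        causal_fraction=payload.get("causal_fraction", 1.0),
        disease_trait_index=payload.get("disease_trait_index", 0),
        prevalence=payload.get("prevalence", 0.05),
        onset_log_hazard_per_sd=payload.get("onset_log_hazard_per_sd", 0.3),
        asah_fraction=payload.get("asah_fraction", 0.6),
        sbp_liability_corr=payload.get("sbp_liability_corr", 0.2),
        smoking_liability_corr=payload.get("smoking_liability_corr", 0.15),
        uia_detection_prob=payload.get("uia_detection_prob", 1.0),
        seed=payload.get("seed", 0),
    )
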