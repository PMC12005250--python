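"""File I/O and cross-cohort harmonization.

Summary statistics are exchanged as plain TSV. Three dialects are read:

* ``native``  — the package's own writer: ID CHROM POS A1 A2 FREQ N BETA SE Z P
* ``regenie`` — whitespace-delimited REGENIE output; effect allele is
  ALLELE1 and the p-value is 10^(-LOG10P)
* ``fastgwa`` — fastGWA-GLMM output; effect allele is A1

Genotypes can be round-tripped through PLINK1 BED/BIM/FAM (SNP-major,
2-bit codes) or a plain TSV dosage matrix.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    VARIANT_COLUMNS,
    SUMSTATS_COLUMNS,
    GenotypeData,
    HarmonizedSet,
    PhenotypeTable,
    SumStats,
    TrueEffects,
)
from .errors import ParseError, ValidationError

_P_FLOOR = 5e-324  # smallest subnormal; keeps p in (0, 1]

NATIVE_HEADER = ["ID", "CHROM", "POS", "A1", "A2", "FREQ", "N", "BETA", "SE", "Z", "P"]
_REGENIE_REQUIRED = ["CHROM", "GENPOS", "ID", "ALLELE0", "ALLELE1", "A1FREQ", "N", "BETA", "SE", "LOG10P"]
_FASTGWA_REQUIRED = ["CHR", "SNP", "POS", "A1", "A2", "N", "AF1", "BETA", "SE", "P"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")


def read_sumstats(path, dialect: str = "native", cohort_label: Optional[str] = None) -> SumStats:
    """Parse a summary-statistics file; rows with non-finite beta or
    non-positive se are dropped (count kept on ``.n_dropped``)."""
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty file")
    if dialect == "native":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, NATIVE_HEADER, path)
        rec = pd.DataFrame(
            {
                "id": df["ID"].astype(str),
                "chrom": df["CHROM"],
                "pos": df["POS"],
                "a1": df["A1"].astype(str),
                "a2": df["A2"].astype(str),
                "freq": df["FREQ"].astype(float),
                "n": df["N"].astype(int),
                "beta": df["BETA"].astype(float),
                "se": df["SE"].astype(float),
                "z": df["Z"].astype(float),
                "p": df["P"].astype(float),
            }
        )
    elif dialect == "regenie":
        df = pd.read_csv(path, sep=r"\s+")
        _require_columns(df, _REGENIE_REQUIRED, path)
        rec = pd.DataFrame(
            {
                "id": df["ID"].astype(str),
                "chrom": df["CHROM"],
                "pos": df["GENPOS"],
                "a1": df["ALLELE1"].astype(str),
                "a2": df["ALLELE0"].astype(str),
                "freq": df["A1FREQ"].astype(float),
                "n": df["N"].astype(int),
                "beta": df["BETA"].astype(float),
                "se": df["SE"].astype(float),
                "p": np.power(10.0, -df["LOG10P"].astype(float)),
            }
        )
    elif dialect == "fastgwa":
        df = pd.read_csv(path, sep=r"\s+")
        _require_columns(df, _FASTGWA_REQUIRED, path)
        rec = pd.DataFrame(
            {
                "id": df["SNP"].astype(str),
                "chrom": df["CHR"],
                "pos": df["POS"],
                "a1": df["A1"].astype(str),
                "a2": df["A2"].astype(str),
                "freq": df["AF1"].astype(float),
                "n": df["N"].astype(int),
                "beta": df["BETA"].astype(float),
                "se": df["SE"].astype(float),
                "p": df["P"].astype(float),
            }
        )
    else:
        raise ParseError(f"unknown sumstats dialect {dialect!r}")

    bad = ~np.isfinite(rec["beta"].to_numpy(float)) | (rec["se"].to_numpy(float) <= 0)
    bad |= ~np.isfinite(rec["se"].to_numpy(float))
    n_dropped = int(bad.sum())
    rec = rec.loc[~bad].reset_index(drop=True)
    if "p" in rec.columns:
        rec["p"] = rec["p"].clip(lower=_P_FLOOR, upper=1.0)
    label = cohort_label or os.path.splitext(os.path.basename(str(path)))[0]
    n_samples = int(rec["n"].max()) if len(rec) else 0
    ss = SumStats(cohort_label=label, n_samples=n_samples, records=rec)
    ss.n_dropped = n_dropped
    return ss


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_sumstats(sumstats: SumStats, path) -> None:
    """Write the native TSV dialect with 12-significant-digit floats."""
    rec = sumstats.records
    for col in ("beta", "se", "z"):
        if len(rec) and (~np.isfinite(rec[col].to_numpy(float))).any():
            raise ValidationError(f"non-finite {col} refused by writer")
    with open(path, "w") as fh:
        fh.write("\t".join(NATIVE_HEADER) + "\n")
        for row in rec.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.id),
                        str(int(row.chrom)),
                        str(int(row.pos)),
                        str(row.a1),
                        str(row.a2),
                        _fmt(row.freq),
                        str(int(row.n)),
                        _fmt(row.beta),
                        _fmt(row.se),
                        _fmt(row.z),
                        _fmt(row.p),
                    ]
                )
                + "\n"
            )


def harmonize(cohorts: List[SumStats], allow_partial: bool = False) -> HarmonizedSet:
    """Restrict cohorts to a common variant set with effect alleles
    aligned to the first cohort.

    A cohort whose (effect, other) alleles are swapped relative to the
    reference has its beta and z negated and frequency mapped to 1 - f;
    any other allele pair is dropped with reason ``allele_mismatch``.
    With ``allow_partial`` variants carried by only a subset of cohorts
    are kept (absent entries become NaN) and the combiner uses the
    sub-matrix of cohorts carrying each variant.
    """
    if len(cohorts) < 2:
        raise ValidationError("harmonize requires at least 2 cohorts")
    frames = [c.records.set_index("id", drop=False) for c in cohorts]

    if allow_partial:
        ordered_ids: List[str] = []
        seen = set()
        for f in frames:
            for vid in f.index:
                if vid not in seen:
                    seen.add(vid)
                    ordered_ids.append(vid)
    else:
        shared = set(frames[0].index)
        for f in frames[1:]:
            shared &= set(f.index)
        ordered_ids = [vid for vid in frames[0].index if vid in shared]

    dropped = []
    if not allow_partial:
        all_ids = set().union(*(set(f.index) for f in frames))
        for vid in sorted(all_ids - set(ordered_ids)):
            dropped.append((vid, "missing_in_cohort"))
    if not ordered_ids:
        raise ValidationError("no shared variants")

    # Reference orientation: first cohort carrying the variant.
    ref_a1, ref_a2, ref_meta = {}, {}, {}
    for vid in ordered_ids:
        for f in frames:
            if vid in f.index:
                row = f.loc[vid]
                ref_a1[vid], ref_a2[vid] = row["a1"], row["a2"]
                ref_meta[vid] = (row["chrom"], row["pos"])
                break

    mismatched = set()
    aligned_frames = []
    for f in frames:
        rows = []
        for vid in ordered_ids:
            if vid not in f.index:
                rows.append(None)
                continue
            row = f.loc[vid]
            a1, a2 = ref_a1[vid], ref_a2[vid]
            if row["a1"] == a1 and row["a2"] == a2:
                rows.append(row)
            elif row["a1"] == a2 and row["a2"] == a1:
                flipped = row.copy()
                flipped["a1"], flipped["a2"] = a1, a2
                flipped["beta"] = -row["beta"]
                flipped["z"] = -row["z"]
                flipped["freq"] = 1.0 - row["freq"]
                rows.append(flipped)
            else:
                mismatched.add(vid)
                rows.append(None)
        aligned_frames.append(rows)

    keep_ids = [vid for vid in ordered_ids if vid not in mismatched]
    for vid in sorted(mismatched):
        dropped.append((vid, "allele_mismatch"))
    if not keep_ids:
        raise ValidationError("no shared variants")

    out_cohorts = []
    keep_pos = [i for i, vid in enumerate(ordered_ids) if vid not in mismatched]
    for cohort, rows in zip(cohorts, aligned_frames):
        data = []
        for i in keep_pos:
            vid = ordered_ids[i]
            row = rows[i]
            if row is None:
                chrom, pos = ref_meta[vid]
                data.append(
                    {
                        "id": vid,
                        "chrom": chrom,
                        "pos": pos,
                        "a1": ref_a1[vid],
                        "a2": ref_a2[vid],
                        "freq": np.nan,
                        "n": 0,
                        "beta": np.nan,
                        "se": np.nan,
                        "z": np.nan,
                        "p": np.nan,
                    }
                )
            else:
                data.append({c: row[c] for c in SUMSTATS_COLUMNS})
        rec = pd.DataFrame(data, columns=SUMSTATS_COLUMNS)
        present = np.isfinite(rec["beta"].to_numpy(float))
        ss = SumStats.__new__(SumStats)  # bypass validation: NaN rows are deliberate
        ss.cohort_label = cohort.cohort_label
        ss.n_samples = cohort.n_samples
        ss.records = rec
        # validate the present rows only
        SumStats(cohort.cohort_label, cohort.n_samples, rec.loc[present])
        out_cohorts.append(ss)

    return HarmonizedSet(cohorts=out_cohorts, dropped_variants=dropped)


# ---------------------------------------------------------------------------
# PLINK1 BED/BIM/FAM
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 = hom allele1 (dosage 2), 01 = missing,
# 10 = het, 11 = hom allele2 (dosage 0). allele1 is the effect allele.
_CODE_FROM_DOSAGE = {2: 0, 1: 2, 0: 3}
_DOSAGE_FROM_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(geno: GenotypeData, prefix, phenotype: Optional[np.ndarray] = None) -> None:
    """Write BED/BIM/FAM. BIM positions are 1-based; allele1 = effect allele."""
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": phenotype if phenotype is not None else -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": geno.variants["chrom"],
            "id": geno.variants["id"],
            "cm": 0,
            "pos": geno.variants["pos"],
            "a1": geno.variants["a1"],
            "a2": geno.variants["a2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    d = geno.dosage_float()
    n, m = d.shape
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    for dose, code in _CODE_FROM_DOSAGE.items():
        codes[d == dose] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix) -> GenotypeData:
    """Read BED/BIM/FAM into a dosage matrix counting the effect (A1) allele."""
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"])
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ParseError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK1 BED)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if len(raw) != m * n_bytes:
        raise ParseError(f"{prefix}.bed: unexpected size {len(raw)} for {n} samples x {m} variants")
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, 4 * n_bytes), dtype=np.uint8)
    codes[:, 0::4] = raw & 0x3
    codes[:, 1::4] = (raw >> 2) & 0x3
    codes[:, 2::4] = (raw >> 4) & 0x3
    codes[:, 3::4] = (raw >> 6) & 0x3
    d = _DOSAGE_FROM_CODE[codes[:, :n]].T

    freq = np.nanmean(d, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": bim["id"].astype(str),
            "chrom": bim["chrom"].astype(int),
            "pos": bim["pos"].astype(int),
            "a1": bim["a1"].astype(str),
            "a2": bim["a2"].astype(str),
            "maf": np.minimum(freq, 1 - freq),
        }
    )[VARIANT_COLUMNS]
    if not np.isnan(d).any():
        d = d.astype(np.int8)
    return GenotypeData(fam["iid"].astype(str).to_numpy(object), variants, d)


# ---------------------------------------------------------------------------
# Plain-text genotype / phenotype tables
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeData, path) -> None:
    """Samples x variants dosage TSV: header of variant ids, first column
    ``sample_id``; missing entries written as NA."""
    df = pd.DataFrame(geno.dosage_float(), columns=geno.variants["id"])
    df.insert(0, "sample_id", geno.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_dosage_tsv(path, variants: Optional[pd.DataFrame] = None) -> GenotypeData:
    """Read a dosage TSV. Without a variant-metadata frame, placeholder
    chromosome/position/allele labels are synthesized (chrom 0)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing column sample_id")
    samples = df["sample_id"].astype(str).to_numpy(object)
    d = df.drop(columns=["sample_id"]).to_numpy(float)
    ids = [c for c in df.columns if c != "sample_id"]
    if variants is None:
        freq = np.nanmean(d, axis=0) / 2.0
        variants = pd.DataFrame(
            {
                "id": ids,
                "chrom": 0,
                "pos": np.arange(1, len(ids) + 1),
                "a1": "A",
                "a2": "G",
                "maf": np.minimum(freq, 1 - freq),
            }
        )
    if not np.isnan(d).any():
        d = d.astype(np.int8)
    return GenotypeData(samples, variants[VARIANT_COLUMNS], d)


def write_pheno(path, sample_ids, y) -> None:
    df = pd.DataFrame({"FID": sample_ids, "IID": sample_ids, "PHENO": y})
    df.to_csv(path, sep=" ", index=False, float_format="%.12g")


def read_pheno(path) -> pd.DataFrame:
    """Whitespace-delimited FID IID PHENO (header optional)."""
    first = open(path).readline().split()
    header = 0 if first[:2] == ["FID", "IID"] else None
    df = pd.read_csv(path, sep=r"\s+", header=header)
    if header is None:
        df.columns = ["FID", "IID", "PHENO"][: len(df.columns)]
    return df


def read_covar(path) -> pd.DataFrame:
    """Whitespace-delimited FID IID C1 C2 ... (header required)."""
    df = pd.read_csv(path, sep=r"\s+")
    if "IID" not in df.columns:
        raise ParseError(f"{path}: missing column IID")
    return df


def phenotype_from_files(pheno_path, covar_path=None, trait_type="quantitative") -> PhenotypeTable:
    ph = read_pheno(pheno_path)
    ids = ph["IID"].astype(str).to_numpy(object)
    y = ph["PHENO"].to_numpy(float)
    if covar_path is not None:
        cv = read_covar(covar_path).set_index("IID")
        cols = [c for c in cv.columns if c not in ("FID",)]
        cv = cv.loc[[str(i) for i in ids], cols]
        covariates = cv.to_numpy(float)
        names = list(cols)
    else:
        covariates = np.zeros((len(y), 0))
        names = []
    return PhenotypeTable(ids, y, covariates, trait_type, names)


def write_true_effects(path, effects: TrueEffects, geno: GenotypeData) -> None:
    """TSV with id, chromosome and both effect scales: the simulated
    per-standardized-genotype beta and the per-allele conversion
    beta / sqrt(2 f (1 - f))."""
    meta = geno.variants.set_index("id")
    cols = [meta.index.get_loc(v) for v in effects.causal_ids]
    f = geno.allele_freq()[cols]
    per_allele = effects.beta_true / np.sqrt(2 * f * (1 - f))
    df = pd.DataFrame(
        {
            "id": effects.causal_ids,
            "chromosome": meta.loc[effects.causal_ids, "chrom"].to_numpy(int),
            "beta_true": effects.beta_true,
            "beta_true_per_allele": per_allele,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_true_effects(path) -> TrueEffects:
    df = pd.read_csv(path, sep="\t")
    return TrueEffects(df["id"].astype(str).to_numpy(object), df["beta_true"].to_numpy(float))
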