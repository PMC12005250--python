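"""Core in-memory containers shared across the pipeline.

The currency of the package is the summary-statistics table
(:class:`SumStats`): per-variant effect estimates exchanged between the
per-sub-cohort association stage and the corrected meta-analysis.
Genotypes are held as a dense samples x variants dosage matrix
(:class:`GenotypeData`), adequate for the desk-scale cohorts the
simulator produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, ValidationError

#: Column order of a variant-metadata frame.
VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "maf"]

#: Column order of a summary-statistics record frame (a1 = effect allele).
SUMSTATS_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "freq", "n", "beta", "se", "z", "p"]


@dataclass
class Variant:
    """A single bi-allelic variant; ``a1`` is the effect allele."""

    id: str
    chrom: int
    pos: int
    a1: str
    a2: str
    maf: float

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ValidationError(f"variant {self.id}: effect and other allele are equal")
        if not (0 < self.maf <= 0.5):
            raise ValidationError(f"variant {self.id}: maf {self.maf} outside (0, 0.5]")


@dataclass
class GenotypeData:
    """Dosage matrix plus variant metadata.

    ``dosages`` has shape (n_samples, n_variants) with entries in
    {0, 1, 2}; missing genotypes are NaN (float matrices only).
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.variants["id"].duplicated().any():
            raise ValidationError("duplicate variant ids")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage_float(self) -> np.ndarray:
        return np.asarray(self.dosages, dtype=np.float64)

    def allele_freq(self) -> np.ndarray:
        """Observed effect-allele (a1) frequency, ignoring missing entries."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def mac(self) -> np.ndarray:
        """Minor allele count over observed genotypes."""
        d = self.dosage_float()
        obs = np.sum(~np.isnan(d), axis=0)
        cnt = np.nansum(d, axis=0)
        return np.minimum(cnt, 2 * obs - cnt)

    def missing_rate(self) -> np.ndarray:
        d = self.dosage_float()
        return np.mean(np.isnan(d), axis=0)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids], dtype=int)
        return GenotypeData(np.asarray(list(ids), dtype=object), self.variants.copy(), self.dosages[rows])

    def subset_variants(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask.astype(int)
        return GenotypeData(
            self.sample_ids.copy(),
            self.variants.iloc[cols].reset_index(drop=True),
            self.dosages[:, cols],
        )


@dataclass
class RelatednessMap:
    """Known related pairs with pedigree kinship coefficients."""

    pairs: pd.DataFrame  # columns: id_a, id_b, kinship

    def __post_init__(self) -> None:
        p = self.pairs
        if len(p):
            if (p["id_a"] == p["id_b"]).any():
                raise ValidationError("relatedness pair with identical members")
            if not ((p["kinship"] >= 0) & (p["kinship"] <= 0.5)).all():
                raise ValidationError("kinship outside [0, 0.5]")
            key = p.apply(lambda r: tuple(sorted((r["id_a"], r["id_b"]))), axis=1)
            if key.duplicated().any():
                raise ValidationError("duplicate relatedness pair")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``h2`` is the narrow-sense heritability of the simulated additive
    trait; for binary traits it lives on the liability scale and
    ``prevalence_K`` sets the case fraction.
    """

    n_unrelated: int
    n_sib_pairs: int
    n_variants: int
    n_causal: int
    maf_range: tuple = (0.01, 0.5)
    h2: float = 0.2
    trait_type: str = "quantitative"
    prevalence_K: Optional[float] = None
    mac_min_causal: int = 100
    odd_chromosomes_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_unrelated < 0 or self.n_sib_pairs < 0:
            raise InvalidConfigError("negative sample counts")
        if self.n_unrelated + 2 * self.n_sib_pairs < 1:
            raise InvalidConfigError("zero total samples")
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise InvalidConfigError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not (0 <= self.h2 <= 1):
            raise InvalidConfigError(f"h2 {self.h2} outside [0, 1]")
        if self.n_causal > self.n_variants:
            raise InvalidConfigError("n_causal exceeds n_variants")
        if self.trait_type not in ("quantitative", "binary"):
            raise InvalidConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.prevalence_K is None or not (0 < self.prevalence_K < 1):
                raise InvalidConfigError("binary trait requires prevalence_K in (0, 1)")


@dataclass
class TrueEffects:
    """Causal variant ids and their per-standardized-genotype effects."""

    causal_ids: np.ndarray
    beta_true: np.ndarray

    def __post_init__(self) -> None:
        self.causal_ids = np.asarray(self.causal_ids, dtype=object)
        self.beta_true = np.asarray(self.beta_true, dtype=np.float64)
        if len(self.causal_ids) != len(self.beta_true):
            raise ValidationError("causal_ids and beta_true lengths differ")
        if len(self.beta_true) and (~np.isfinite(self.beta_true) | (self.beta_true == 0)).any():
            raise ValidationError("beta_true entries must be finite and nonzero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.causal_ids, "beta_true": self.beta_true})


@dataclass
class SumStats:
    """Per-variant, per-cohort GWAS summary statistics.

    ``records`` follows :data:`SUMSTATS_COLUMNS`; the z-score is
    recomputed as beta/se when absent and must agree with it to 1e-6
    relative otherwise.
    """

    cohort_label: str
    n_samples: int
    records: pd.DataFrame

    def __post_init__(self) -> None:
        rec = self.records.copy().reset_index(drop=True)
        missing = [c for c in SUMSTATS_COLUMNS if c not in rec.columns and c != "z"]
        if missing:
            raise ValidationError(f"sumstats records missing columns {missing}")
        if rec["id"].duplicated().any():
            dup = rec.loc[rec["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r} in sumstats")
        if len(rec):
            if (~np.isfinite(rec["beta"].to_numpy(float))).any():
                raise ValidationError("non-finite beta in sumstats")
            if (rec["se"].to_numpy(float) <= 0).any() or (~np.isfinite(rec["se"].to_numpy(float))).any():
                raise ValidationError("se must be finite and > 0")
            if "z" not in rec.columns or rec["z"].isna().all():
                rec["z"] = rec["beta"] / rec["se"]
            else:
                zref = rec["beta"].to_numpy(float) / rec["se"].to_numpy(float)
                z = rec["z"].to_numpy(float)
                scale = np.maximum(np.abs(zref), 1.0)
                if np.nanmax(np.abs(z - zref) / scale) > 1e-6:
                    raise ValidationError("z inconsistent with beta/se beyond 1e-6")
        elif "z" not in rec.columns:
            rec["z"] = pd.Series(dtype=float)
        self.records = rec[SUMSTATS_COLUMNS]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HarmonizedSet:
    """Cohort summary statistics restricted to a common, allele-aligned
    variant set (effect alleles follow the first cohort)."""

    cohorts: list
    dropped_variants: list = field(default_factory=list)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.cohorts[0].records["id"].to_numpy(object)

    @property
    def labels(self) -> list:
        return [c.cohort_label for c in self.cohorts]

    def matrix(self, column: str) -> np.ndarray:
        """(n_variants, k) matrix of ``column`` across cohorts."""
        return np.column_stack([c.records[column].to_numpy(float) for c in self.cohorts])


@dataclass
class CohortAssignment:
    """Random partition of samples into k equally sized sub-cohorts."""

    k: int
    assignment: pd.Series  # index: sample_id, value: sub-cohort in 1..k
    seed: int

    def ids_for(self, index: int) -> np.ndarray:
        return self.assignment.index[self.assignment.to_numpy() == index].to_numpy(object)

    def sizes(self) -> dict:
        return self.assignment.value_counts().sort_index().to_dict()


@dataclass
class CohortCorrelation:
    """Pairwise between-cohort z-score correlation and its
    overlap-equivalent sample count n12 = r * sqrt(n_j * n_k)."""

    labels: list
    r: np.ndarray          # clamped to [0, 1] off-diagonal, diag 1
    r_raw: np.ndarray      # unclamped Pearson estimates
    n12: np.ndarray
    n: np.ndarray
    n_variants_used: int
    snp_selection: str = "all"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        if not np.allclose(r, r.T):
            raise ValidationError("correlation matrix not symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValidationError("correlation diagonal must be 1")
        off = r[~np.eye(len(r), dtype=bool)]
        if len(off) and ((off < 0) | (off > 1)).any():
            raise ValidationError("off-diagonal correlations outside [0, 1]")
        expect = r * np.sqrt(np.outer(self.n, self.n))
        if np.nanmax(np.abs(self.n12 - expect)) > 1e-9 * max(1.0, np.nanmax(np.abs(expect))):
            raise ValidationError("n12 inconsistent with r * sqrt(n_j n_k)")


@dataclass
class MetaResult:
    """Combined per-variant statistics at one of three stages:
    raw, gc_applied, or inflated."""

    table: pd.DataFrame
    stage: str = "raw"
    lambda_gc: Optional[float] = None
    inflation_factor: Optional[float] = None
    skipped: list = field(default_factory=list)
    method: str = "CMA"

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            T = t["T"].to_numpy(float)
            z = t["z"].to_numpy(float)
            if np.nanmax(np.abs(T - z**2)) > 1e-9 * max(1.0, np.nanmax(np.abs(T))):
                raise ValidationError("T inconsistent with z^2")
            p = t["p"].to_numpy(float)
            if ((p <= 0) | (p > 1)).any():
                raise ValidationError("p outside (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class InflationConfig:
    """Genomic-control + heritability power-inflation settings.

    The offsets 0.95 (continuous) and 0.85 (binary) are the method's
    published constants; override only for sensitivity analysis.
    """

    h2_prior: float
    trait_type: str = "quantitative"
    continuous_offset: float = 0.95
    binary_offset: float = 0.85
    lambda_mode: str = "median_unit"

    def validate(self) -> None:
        if not (0 <= self.h2_prior <= 1):
            raise InvalidConfigError(f"h2_prior {self.h2_prior} outside [0, 1]")
        if self.trait_type not in ("quantitative", "binary"):
            raise InvalidConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.lambda_mode not in ("median_unit", "classical"):
            raise InvalidConfigError(f"unknown lambda_mode {self.lambda_mode!r}")


@dataclass
class PhenotypeTable:
    """Phenotype plus covariates; the intercept is implicit."""

    sample_ids: np.ndarray
    y: np.ndarray
    covariates: np.ndarray  # (n, c); c may be 0
    trait_type: str = "quantitative"
    covariate_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
        if self.covariates.size == 0:
            self.covariates = np.zeros((len(self.y), 0))
        if len(self.sample_ids) != len(self.y) or self.covariates.shape[0] != len(self.y):
            raise ValidationError("phenotype/covariate lengths disagree")
        if self.trait_type == "binary":
            vals = set(np.unique(self.y))
            if not vals <= {0.0, 1.0}:
                raise ValidationError("binary phenotype must be coded 0/1")
            if len(vals) < 2:
                raise ValidationError("binary phenotype contains a single class")
        if not self.covariate_names:
            self.covariate_names = [f"C{i+1}" for i in range(self.covariates.shape[1])]

    def subset(self, ids: Sequence[str]) -> "PhenotypeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids], dtype=int)
        return PhenotypeTable(
            np.asarray(list(ids), dtype=object),
            self.y[rows],
            self.covariates[rows],
            self.trait_type,
            list(self.covariate_names),
        )


@dataclass
class EvalReport:
    """Predictivity and discovery summary of one analysis."""

    r2_effects: float = float("nan")
    mu_gamma: float = float("nan")
    power: float = float("nan")
    fdr: float = float("nan")
    prs_r2: float = float("nan")
    alpha_threshold: float = 5e-8
    n_causal_matched: int = 0

    def to_dict(self) -> dict:
        return {
            "r2_effects": self.r2_effects,
            "mu_gamma": self.mu_gamma,
            "power": self.power,
            "fdr": self.fdr,
            "prs_r2": self.prs_r2,
            "alpha_threshold": self.alpha_threshold,
            "n_causal_matched": self.n_causal_matched,
        }
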