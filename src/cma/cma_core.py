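"""Corrected meta-analysis (CMA).

Splitting one cohort into sub-cohorts and recombining with classical
inverse-variance meta-analysis silently assumes the sub-cohorts are
independent. Relatives separated across sub-cohorts violate that: the
two z-scores of a variant share a component, so the combined variance is
understated and type I error inflates. CMA estimates the between-cohort
correlation of z-scores genome-wide, converts it to an overlap-equivalent
sample count n12 = r * sqrt(n1 * n2), and plugs the implied covariance
into a generalized-least-squares combination. Per variant the
off-diagonal covariance is sign-calibrated: gamma_jk = -1 when the two
effect estimates disagree in direction, +1 otherwise.

An optional post-combination step restores discovery power: genomic
control (rescale test scores so their median is 1) followed by
multiplication with Max(1, offset + h2), offset 0.95 for continuous and
0.85 for binary traits. Effect estimates are never touched by this step
— discovery and predictivity are decoupled.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CohortCorrelation,
    HarmonizedSet,
    InflationConfig,
    MetaResult,
    SumStats,
)
from .errors import InvalidConfigError, ValidationError

_P_FLOOR = 5e-324

META_COLUMNS = [
    "id", "chrom", "pos", "a1", "a2", "freq",
    "n_eff", "n_cohorts", "beta", "se", "z", "T", "p",
]


def estimate_correlation(
    harmonized: HarmonizedSet,
    snp_selection: str = "all",
    min_variants: int = 100,
    warn_below: int = 1000,
) -> CohortCorrelation:
    """Pearson correlation of per-variant z-scores for every cohort pair.

    ``snp_selection='null_like'`` restricts each pair to variants with
    |z| < 2 in both cohorts. Negative estimates are clamped to zero (the
    model form sqrt(alpha_j alpha_k) is nonnegative; negatives are
    sampling noise); the raw estimates are kept on ``r_raw``.
    """
    if snp_selection not in ("all", "null_like"):
        raise InvalidConfigError(f"unknown snp_selection {snp_selection!r}")
    k = len(harmonized.cohorts)
    if k < 2:
        raise ValidationError("correlation estimation needs >= 2 cohorts")
    Z = harmonized.matrix("z")
    n = np.array([c.n_samples for c in harmonized.cohorts], dtype=float)

    r_raw = np.eye(k)
    used = []
    for j in range(k):
        for l in range(j + 1, k):
            mask = np.isfinite(Z[:, j]) & np.isfinite(Z[:, l])
            if snp_selection == "null_like":
                mask &= (np.abs(Z[:, j]) < 2) & (np.abs(Z[:, l]) < 2)
            zj, zl = Z[mask, j], Z[mask, l]
            if len(zj) < min_variants:
                raise ValidationError(
                    f"only {len(zj)} shared variants for cohorts "
                    f"({harmonized.labels[j]}, {harmonized.labels[l]}); floor is {min_variants}"
                )
            if len(zj) < warn_below:
                warnings.warn(
                    f"correlation for pair ({j}, {l}) estimated from only {len(zj)} variants",
                    stacklevel=2,
                )
            if zj.std() == 0 or zl.std() == 0:
                raise ValidationError("degenerate z vector (constant) in correlation estimation")
            r_raw[j, l] = r_raw[l, j] = float(np.corrcoef(zj, zl)[0, 1])
            used.append(int(mask.sum()))

    r = r_raw.copy()
    off = ~np.eye(k, dtype=bool)
    r[off] = np.clip(r[off], 0.0, 1.0)
    n12 = r * np.sqrt(np.outer(n, n))
    return CohortCorrelation(
        labels=list(harmonized.labels),
        r=r,
        r_raw=r_raw,
        n12=n12,
        n=n,
        n_variants_used=int(min(used)) if used else 0,
        snp_selection=snp_selection,
    )


def _solve_pd(omega: np.ndarray, b: np.ndarray, ones: np.ndarray):
    """Solve Omega x = [b, 1] for a PD (or PSD-singular) Omega.

    Cholesky first; an exactly singular but PSD matrix (e.g. two fully
    overlapping cohorts, r = 1) falls back to the pseudo-inverse, which
    is the exact GLS limit. Indefinite matrices get ridge escalation and
    return None if that never succeeds.
    """
    try:
        L = np.linalg.cholesky(omega)
        rhs = np.column_stack([b, ones])
        sol = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
        return sol[:, 0], sol[:, 1]
    except np.linalg.LinAlgError:
        pass
    scale = float(np.max(np.diag(omega)))
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin >= -1e-12 * scale:
        pinv = np.linalg.pinv(omega, hermitian=True)
        return pinv @ b, pinv @ ones
    delta = 1e-8
    while delta <= 1e-4:
        try:
            L = np.linalg.cholesky(omega + delta * scale * np.eye(len(omega)))
            rhs = np.column_stack([b, ones])
            sol = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            return sol[:, 0], sol[:, 1]
        except np.linalg.LinAlgError:
            delta *= 10
    return None


def combine(
    harmonized: HarmonizedSet,
    corr: Optional[CohortCorrelation] = None,
    method: str = "CMA",
) -> MetaResult:
    """Per-variant GLS combination of cohort effect estimates.

    Builds Omega with Omega_jj = se_j^2 and, for CMA,
    Omega_jk = gamma_jk * r_jk * se_j * se_k; MA zeroes the
    off-diagonals (classical inverse-variance). Then
    beta = (1' Omega^-1 b) / (1' Omega^-1 1) and
    se = (1' Omega^-1 1)^(-1/2). Variants with a non-positive-definite
    Omega even after ridge escalation are failed with reason ``non_pd``.
    """
    if method not in ("CMA", "MA"):
        raise InvalidConfigError(f"unknown method {method!r}")
    if method == "CMA":
        if corr is None:
            raise InvalidConfigError("CMA requires a CohortCorrelation")
        if list(corr.labels) != list(harmonized.labels):
            raise ValidationError("correlation labels do not match harmonized cohorts")

    k = len(harmonized.cohorts)
    B = harmonized.matrix("beta")
    S = harmonized.matrix("se")
    F = harmonized.matrix("freq")
    n_per = np.array([c.n_samples for c in harmonized.cohorts], dtype=float)
    r = corr.r if (corr is not None and method == "CMA") else np.eye(k)
    n12 = corr.n12 if corr is not None else np.zeros((k, k))

    ids = harmonized.variant_ids
    base = harmonized.cohorts[0].records
    out = {c: [] for c in META_COLUMNS}
    skipped = []

    for v in range(len(ids)):
        present = np.flatnonzero(np.isfinite(B[v]) & np.isfinite(S[v]))
        if len(present) < 1:
            skipped.append((ids[v], "missing_everywhere"))
            continue
        b = B[v, present]
        s = S[v, present]
        if len(present) == 1:
            beta_meta, se_meta = float(b[0]), float(s[0])
        else:
            sub_r = r[np.ix_(present, present)]
            gamma = np.where(np.outer(b, b) < 0, -1.0, 1.0)
            omega = sub_r * gamma * np.outer(s, s)
            np.fill_diagonal(omega, s**2)
            sol = _solve_pd(omega, b, np.ones(len(present)))
            if sol is None:
                skipped.append((ids[v], "non_pd"))
                continue
            oib, oi1 = sol
            denom = float(np.sum(oi1))
            if denom <= 0:
                skipped.append((ids[v], "non_pd"))
                continue
            beta_meta = float(np.sum(oib)) / denom
            se_meta = denom ** -0.5

        if method == "CMA":
            sub_n12 = n12[np.ix_(present, present)]
            n_eff = float(n_per[present].sum() - np.triu(sub_n12, 1).sum())
        else:
            n_eff = float(n_per[present].sum())
        z = beta_meta / se_meta
        T = z * z
        p = max(float(stats.chi2.sf(T, 1)), _P_FLOOR)

        row = base.iloc[v]
        out["id"].append(ids[v])
        out["chrom"].append(row["chrom"])
        out["pos"].append(row["pos"])
        out["a1"].append(row["a1"])
        out["a2"].append(row["a2"])
        fv = F[v, present]
        out["freq"].append(float(np.nanmean(fv)))
        out["n_eff"].append(n_eff)
        out["n_cohorts"].append(len(present))
        out["beta"].append(beta_meta)
        out["se"].append(se_meta)
        out["z"].append(z)
        out["T"].append(T)
        out["p"].append(p)

    if not out["id"]:
        raise ValidationError("all variants skipped in combination")
    table = pd.DataFrame(out)
    return MetaResult(table=table, stage="raw", skipped=skipped, method=method)


def sumstats_to_meta(ss: SumStats) -> MetaResult:
    """Passthrough: wrap a single cohort's summary statistics as a raw
    MetaResult (the k=1 / standard-GWAS case). Numeric fields are copied
    bit-for-bit; only T = z^2 is added."""
    rec = ss.records
    table = pd.DataFrame(
        {
            "id": rec["id"],
            "chrom": rec["chrom"],
            "pos": rec["pos"],
            "a1": rec["a1"],
            "a2": rec["a2"],
            "freq": rec["freq"],
            "n_eff": rec["n"].astype(float),
            "n_cohorts": 1,
            "beta": rec["beta"],
            "se": rec["se"],
            "z": rec["z"],
            "T": rec["z"] ** 2,
            "p": rec["p"],
        }
    )
    return MetaResult(table=table, stage="raw", method="standard")


def as_pseudo_cohort(meta: MetaResult, label: str) -> SumStats:
    """Re-package a combined result as a cohort for incremental
    meta-analysis; the per-variant sample size is the overlap-corrected
    effective n."""
    t = meta.table
    rec = pd.DataFrame(
        {
            "id": t["id"],
            "chrom": t["chrom"],
            "pos": t["pos"],
            "a1": t["a1"],
            "a2": t["a2"],
            "freq": t["freq"],
            "n": t["n_eff"].round().astype(int),
            "beta": t["beta"],
            "se": t["se"],
            "z": t["z"],
            "p": t["p"],
        }
    )
    return SumStats(cohort_label=label, n_samples=int(rec["n"].max()), records=rec)


def genomic_control(T: np.ndarray, lambda_mode: str = "median_unit") -> Tuple[np.ndarray, float]:
    """Rescale test scores by the genomic-control factor.

    ``median_unit``: lambda = median(T), so the rescaled median is
    exactly 1. ``classical``: lambda = median(T) / qchisq(0.5, 1), the
    textbook genomic-control convention.
    """
    T = np.asarray(T, dtype=float)
    med = float(np.median(T))
    if med <= 0:
        raise ValidationError("median test score is not positive; genomic control undefined")
    if lambda_mode == "median_unit":
        lam = med
    elif lambda_mode == "classical":
        lam = med / float(stats.chi2.ppf(0.5, 1))
    else:
        raise InvalidConfigError(f"unknown lambda_mode {lambda_mode!r}")
    return T / lam, lam


def inflate(meta: MetaResult, config: InflationConfig) -> MetaResult:
    """Genomic control followed by the heritability-based power inflation.

    T -> T / lambda, then T -> T * Max(1, offset + h2) with offset 0.95
    (continuous) or 0.85 (binary). z and p are recomputed from the new T;
    beta and se are left untouched (a T-consistent se is emitted as the
    diagnostic column ``se_t``).
    """
    config.validate()
    if meta.stage != "raw":
        raise ValidationError(f"inflate expects a raw MetaResult, got stage {meta.stage!r}")
    if len(meta.table) < 10:
        raise ValidationError("fewer than 10 variants; genomic-control median is unstable")

    t = meta.table.copy()
    T_gc, lam = genomic_control(t["T"].to_numpy(float), config.lambda_mode)
    offset = config.continuous_offset if config.trait_type == "quantitative" else config.binary_offset
    factor = max(1.0, offset + config.h2_prior)
    T_new = T_gc * factor

    beta = t["beta"].to_numpy(float)
    z_new = np.sign(beta) * np.sqrt(T_new)
    # sign(0) = 0 would zero the score of an exactly-null estimate; keep its
    # magnitude with positive sign instead (direction is meaningless there).
    z_new = np.where(beta == 0, np.sqrt(T_new), z_new)
    p_new = np.clip(stats.chi2.sf(T_new, 1), _P_FLOOR, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_t = np.where(T_new > 0, np.abs(beta) / np.sqrt(T_new), np.nan)

    t["z"] = z_new
    t["T"] = T_new
    t["p"] = p_new
    t["se_t"] = se_t
    return MetaResult(
        table=t,
        stage="inflated",
        lambda_gc=lam,
        inflation_factor=factor,
        skipped=list(meta.skipped),
        method=meta.method,
    )
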