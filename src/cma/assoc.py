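"""Per-sub-cohort association engine.

A deliberately plain fixed-effects engine: quantitative traits use
covariate-residualized per-variant OLS (Frisch-Waugh, so the estimates
equal those of the full multiple regression), binary traits per-variant
logistic regression with Wald statistics. Within-cohort mixed-model
corrections are the job of external tools whose summary output the
package ingests; this engine exists so the whole pipeline runs
self-contained on simulated cohorts.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeData, PhenotypeTable, SumStats
from .errors import ValidationError

_P_FLOOR = 5e-324


def qc_filter(
    geno: GenotypeData,
    maf_min: float = 0.01,
    mac_min: int = 20,
    missing_max: float = 0.1,
) -> Tuple[GenotypeData, pd.DataFrame]:
    """Drop variants failing MAF, MAC or missingness thresholds.

    Returns the filtered genotypes and a report of removed variants with
    the first failing filter; removing everything is a warning, not an
    error.
    """
    if maf_min < 0 or mac_min < 0 or missing_max < 0:
        raise ValidationError("QC thresholds must be nonnegative")
    freq = geno.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    mac = geno.mac()
    miss = geno.missing_rate()

    reasons = np.full(geno.n_variants, "", dtype=object)
    reasons[np.where(miss > missing_max)] = "missingness"
    reasons[np.where(mac < mac_min)] = "mac"
    reasons[np.where(maf < maf_min)] = "maf"
    keep = reasons == ""
    report = pd.DataFrame(
        {"id": geno.variants.loc[~keep, "id"].to_numpy(object), "reason": reasons[~keep]}
    )
    if not keep.any():
        import warnings

        warnings.warn("QC removed every variant", stacklevel=2)
    return geno.subset_variants(keep), report


def _check_covariates(X: np.ndarray, names) -> None:
    # QR with column pivoting would be overkill; flag the first column
    # whose residual norm after projecting on the previous ones vanishes.
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * max(diag.max(), 1.0)
    bad = np.flatnonzero(diag < tol)
    if len(bad):
        idx = bad[0] - 1  # column 0 is the intercept
        name = names[idx] if 0 <= idx < len(names) else f"column {bad[0]}"
        raise ValidationError(f"collinear covariate: {name}")


def run_gwas(geno: GenotypeData, pheno: PhenotypeTable, cohort_label: str = "cohort") -> SumStats:
    """Single-variant association tests for every polymorphic variant.

    Quantitative: residualize the phenotype and each genotype vector on
    the covariates (with intercept), then simple OLS of the residuals
    with n - c - 2 degrees of freedom (c user covariates). Binary:
    per-variant logistic regression, Wald test. Missing dosages are
    mean-imputed per variant. Skipped variants (monomorphic or failed
    fits) are listed on ``.skipped``.
    """
    common = [s for s in geno.sample_ids if s in set(pheno.sample_ids)]
    if len(common) < 10:
        raise ValidationError(
            f"genotype and phenotype samples overlap on {len(common)} < 10 samples"
        )
    geno = geno.subset_samples(common)
    pheno = pheno.subset(common)

    n = len(common)
    X = np.column_stack([np.ones(n), pheno.covariates])
    _check_covariates(X, pheno.covariate_names)
    y = pheno.y

    G = geno.dosage_float().copy()
    nanmask = np.isnan(G)
    if nanmask.any():
        colmean = np.nanmean(G, axis=0)
        G[nanmask] = np.take(colmean, np.where(nanmask)[1])

    freq_obs = np.where(nanmask.all(axis=0), np.nan, np.nanmean(np.where(nanmask, np.nan, G), axis=0) / 2.0)
    poly = G.std(axis=0) > 0
    skipped = [(vid, "monomorphic") for vid in geno.variants.loc[~poly, "id"]]

    if pheno.trait_type == "quantitative":
        beta, se = _ols_scan(y, G[:, poly], X)
    elif pheno.trait_type == "binary":
        beta, se, failed = _logistic_scan(y, G[:, poly], X)
        ids_poly = geno.variants.loc[poly, "id"].to_numpy(object)
        skipped += [(ids_poly[i], "logistic_failure") for i in np.flatnonzero(failed)]
        ok = ~failed
        poly_idx = np.flatnonzero(poly)
        poly = np.zeros(geno.n_variants, dtype=bool)
        poly[poly_idx[ok]] = True
        beta, se = beta[ok], se[ok]
    else:
        raise ValidationError(f"unknown trait_type {pheno.trait_type!r}")

    # A perfect fit yields a zero residual variance; floor the se so z
    # stays finite and downstream p-values remain in (0, 1].
    se = np.maximum(se, 1e-150)
    z = beta / se
    p = np.clip(2 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)

    keep = geno.variants.loc[poly]
    rec = pd.DataFrame(
        {
            "id": keep["id"].to_numpy(object),
            "chrom": keep["chrom"].to_numpy(int),
            "pos": keep["pos"].to_numpy(int),
            "a1": keep["a1"].to_numpy(object),
            "a2": keep["a2"].to_numpy(object),
            "freq": freq_obs[poly],
            "n": n,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
        }
    )
    ss = SumStats(cohort_label=cohort_label, n_samples=n, records=rec)
    ss.skipped = skipped
    return ss


def _ols_scan(y: np.ndarray, G: np.ndarray, X: np.ndarray):
    """Vectorized residualized OLS across variants."""
    n, p = X.shape
    q, _ = np.linalg.qr(X)
    ry = y - q @ (q.T @ y)
    RG = G - q @ (q.T @ G)
    sxx = np.einsum("ij,ij->j", RG, RG)
    sxy = RG.T @ ry
    syy = float(ry @ ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, 0.0)
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    df = n - p - 1
    if df <= 0:
        raise ValidationError(f"not enough residual degrees of freedom (n={n}, covariates={p - 1})")
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(sxx > 0, sigma2 / sxx, np.inf))
    return beta, se


def _logistic_scan(y: np.ndarray, G: np.ndarray, X: np.ndarray):
    """Per-variant logistic regression via statsmodels; Wald beta/se."""
    import statsmodels.api as sm

    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    failed = np.zeros(m, dtype=bool)
    for j in range(m):
        design = np.column_stack([X, G[:, j]])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            if not np.isfinite(fit.bse[-1]) or fit.bse[-1] <= 0:
                raise ValueError("degenerate Wald se")
            beta[j] = fit.params[-1]
            se[j] = fit.bse[-1]
        except Exception:
            failed[j] = True
    return beta, se, failed
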