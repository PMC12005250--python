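"""Predictivity and discovery metrics.

Predictivity: R^2 of the regression beta_true ~ beta_hat over causal
variants, and the winner's-curse summary mu_gamma = mean |1 - gamma_i|
with gamma_i = beta_hat_i / beta_true_i (the effect inflation factor).
Discovery: empirical power and false-discovery proportion at a fixed
p-value threshold. PRS: significance-thresholded weighted dosage score
on a held-out target cohort, summarized as R^2 of phenotype ~ score.

True effects live on the per-standardized-genotype scale while the
association engine reports per-allele effects; metrics convert with
beta_std = beta_allele * sqrt(2 f (1 - f)) using the reported allele
frequency (``effect_scale='per_allele'``, the default).
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd

from .datatypes import EvalReport, GenotypeData, MetaResult, TrueEffects
from .errors import InvalidConfigError, ValidationError


def _matched_effects(true: TrueEffects, meta: MetaResult, effect_scale: str) -> pd.DataFrame:
    if effect_scale not in ("per_allele", "standardized"):
        raise InvalidConfigError(f"unknown effect_scale {effect_scale!r}")
    df = meta.table.set_index("id")
    present = [v for v in true.causal_ids if v in df.index]
    if len(present) < len(true.causal_ids):
        warnings.warn(
            f"{len(true.causal_ids) - len(present)} causal variants missing from meta result",
            stacklevel=3,
        )
    if not present:
        raise ValidationError("no causal variant matched the meta result")
    sub = df.loc[present]
    beta_hat = sub["beta"].to_numpy(float)
    if effect_scale == "per_allele":
        f = sub["freq"].to_numpy(float)
        beta_hat = beta_hat * np.sqrt(2 * f * (1 - f))
    idx = {v: i for i, v in enumerate(true.causal_ids)}
    beta_true = np.array([true.beta_true[idx[v]] for v in present])
    return pd.DataFrame({"id": present, "beta_true": beta_true, "beta_hat": beta_hat})


def effect_regression_r2(true: TrueEffects, meta: MetaResult, effect_scale: str = "per_allele") -> float:
    """Coefficient of determination of OLS beta_true ~ beta_hat (with
    intercept) over matched causal variants."""
    m = _matched_effects(true, meta, effect_scale)
    if len(m) < 3:
        raise ValidationError(f"only {len(m)} causal variants matched; need >= 3")
    bh = m["beta_hat"].to_numpy()
    bt = m["beta_true"].to_numpy()
    if np.var(bh) == 0:
        warnings.warn("zero variance in estimated effects; R^2 defined as 0", stacklevel=2)
        return 0.0
    # simple regression with intercept: R^2 equals squared Pearson correlation
    return float(np.corrcoef(bt, bh)[0, 1] ** 2)


def mu_gamma(true: TrueEffects, meta: MetaResult, effect_scale: str = "per_allele"):
    """Winner's-curse summary: gamma_i = beta_hat_i / beta_true_i and
    mu_gamma = mean |1 - gamma_i| over matched causal variants."""
    m = _matched_effects(true, meta, effect_scale)
    gammas = m["beta_hat"].to_numpy() / m["beta_true"].to_numpy()
    mu = float(np.mean(np.abs(1.0 - gammas)))
    return mu, pd.DataFrame({"id": m["id"], "gamma": gammas})


def power_fdr(meta: MetaResult, true: TrueEffects, alpha: float) -> Tuple[float, float]:
    """Empirical power and false-discovery proportion at threshold alpha.

    power = #{causal with p < alpha} / #{causal tested};
    fdr = #{non-causal with p < alpha} / #{all with p < alpha}, defined
    as 0 when nothing is significant.
    """
    if not (0 < alpha < 1):
        raise InvalidConfigError(f"alpha {alpha} outside (0, 1)")
    t = meta.table
    causal = set(true.causal_ids)
    is_causal = t["id"].isin(causal).to_numpy()
    sig = (t["p"].to_numpy(float) < alpha)
    n_causal_tested = int(is_causal.sum())
    if n_causal_tested == 0:
        raise ValidationError("no causal variant present in the meta result")
    power = float((sig & is_causal).sum() / n_causal_tested)
    n_sig = int(sig.sum())
    fdr = float((sig & ~is_causal).sum() / n_sig) if n_sig else 0.0
    return power, fdr


def false_positive_rate(meta: MetaResult, alpha: float, causal_ids=()) -> float:
    """Fraction of null (non-causal) variants with p < alpha."""
    if not (0 < alpha < 1):
        raise InvalidConfigError(f"alpha {alpha} outside (0, 1)")
    t = meta.table
    null_mask = ~t["id"].isin(set(causal_ids)).to_numpy()
    if null_mask.sum() == 0:
        raise ValidationError("no null variants")
    return float((t["p"].to_numpy(float)[null_mask] < alpha).mean())


def prs_evaluate(
    geno_target: GenotypeData,
    pheno_target: np.ndarray,
    meta: MetaResult,
    p_threshold: float = 5e-8,
    effect_scale: str = "per_allele",
):
    """Polygenic score on a target cohort from thresholded meta effects.

    score_i = sum_j beta_hat_j * dosage_ij over variants with
    p < p_threshold, alleles matched to the target (swapped orientation
    negates the weight). Returns (scores, prs_r2) with prs_r2 the R^2 of
    phenotype ~ score; an empty SNP set yields zero scores with a
    warning. Binary phenotypes use the same linear R^2 on 0/1 coding.
    """
    if effect_scale not in ("per_allele", "standardized"):
        raise InvalidConfigError(f"unknown effect_scale {effect_scale!r}")
    y = np.asarray(pheno_target, dtype=float)
    if len(y) != geno_target.n_samples:
        raise ValidationError("target phenotype length does not match genotypes")
    t = meta.table
    sel = t.loc[t["p"].to_numpy(float) < p_threshold]
    gvar = geno_target.variants.set_index("id")
    target_freq = geno_target.allele_freq()
    col_of = {v: i for i, v in enumerate(geno_target.variants["id"])}

    cols, weights = [], []
    for row in sel.itertuples(index=False):
        if row.id not in col_of:
            continue
        g = gvar.loc[row.id]
        if row.a1 == g["a1"] and row.a2 == g["a2"]:
            sign = 1.0
        elif row.a1 == g["a2"] and row.a2 == g["a1"]:
            sign = -1.0
        else:
            continue
        j = col_of[row.id]
        beta = float(row.beta)
        if effect_scale == "standardized":
            f = target_freq[j]
            if not (0 < f < 1):
                continue
            beta = beta / np.sqrt(2 * f * (1 - f))
        cols.append(j)
        weights.append(sign * beta)

    if not cols:
        warnings.warn("no variants passed the PRS threshold; scores are zero", stacklevel=2)
        return np.zeros(geno_target.n_samples), 0.0

    D = geno_target.dosage_float()[:, cols]
    nanmask = np.isnan(D)
    if nanmask.any():
        colmean = np.nanmean(D, axis=0)
        D[nanmask] = np.take(colmean, np.where(nanmask)[1])
    scores = D @ np.asarray(weights)
    if np.var(scores) == 0 or np.var(y) == 0:
        return scores, 0.0
    r2 = float(np.corrcoef(y, scores)[0, 1] ** 2)
    return scores, r2


def discovery_target_split(sample_ids, target_frac: float = 0.2, seed: int = 0):
    """Seeded 80/20 (by default) split into discovery and target samples,
    performed before any sub-cohort splitting."""
    if not (0 < target_frac < 1):
        raise InvalidConfigError(f"target_frac {target_frac} outside (0, 1)")
    sample_ids = np.asarray(list(sample_ids), dtype=object)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sample_ids))
    n_target = int(round(target_frac * len(sample_ids)))
    target = sample_ids[perm[:n_target]]
    discovery = sample_ids[perm[n_target:]]
    return discovery, target


def evaluate(
    meta: MetaResult,
    true: TrueEffects,
    alpha: float = 5e-8,
    geno_target: GenotypeData | None = None,
    pheno_target: np.ndarray | None = None,
    prs_threshold: float = 5e-8,
    effect_scale: str = "per_allele",
) -> EvalReport:
    """Assemble the full report for one analysis."""
    matched = _matched_effects(true, meta, effect_scale)
    r2 = effect_regression_r2(true, meta, effect_scale)
    mu, _ = mu_gamma(true, meta, effect_scale)
    power, fdr = power_fdr(meta, true, alpha)
    prs_r2 = float("nan")
    if geno_target is not None and pheno_target is not None:
        _, prs_r2 = prs_evaluate(geno_target, pheno_target, meta, prs_threshold, effect_scale)
    return EvalReport(
        r2_effects=r2,
        mu_gamma=mu,
        power=power,
        fdr=fdr,
        prs_r2=prs_r2,
        alpha_threshold=alpha,
        n_causal_matched=len(matched),
    )
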