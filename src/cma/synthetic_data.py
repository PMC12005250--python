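"""Synthetic cohort generator: genotypes with controllable relatedness and
GCTA-style additive traits.

Variants are simulated independently (linkage equilibrium), with
chromosome labels 1..22 assigned round-robin so that odd/even causal
selection is meaningful. Relatedness is injected as full-sibling pairs
produced by Mendelian transmission from two simulated parents (who are
not emitted), giving pedigree kinship 0.25 per pair.

Quantitative traits follow the standard additive model on standardized
genotypes: y = sum_j w_j beta_j + e with beta_j ~ N(0, h2/n_causal) and
e ~ N(0, 1 - h2), so the total trait variance is ~1 and the genetic
fraction is h2. Binary traits threshold the same liability at the
(1 - K) quantile, K the target prevalence.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenotypeData, RelatednessMap, SimulationConfig, TrueEffects
from .errors import InvalidConfigError

# Independent child streams of the config seed, one per operation, so
# that e.g. re-drawing a trait does not perturb the genotypes.
_GENO_STREAM = 0
_CAUSAL_STREAM = 1
_TRAIT_STREAM = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def _variant_frame(m: int, mafs: np.ndarray) -> pd.DataFrame:
    idx = np.arange(m)
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in idx],
            "chrom": (idx % 22 + 1).astype(int),
            "pos": (idx // 22 + 1).astype(int),
            "a1": "A",
            "a2": "G",
            "maf": mafs,
        }
    )


def simulate_genotypes(config: SimulationConfig) -> Tuple[GenotypeData, RelatednessMap]:
    """Draw founder and sibling genotypes at independent bi-allelic variants.

    Founders are Binomial(2, maf) per variant. Each sibling pair shares
    two fresh simulated parents; every sib inherits one allele per parent
    per variant, independently across variants.
    """
    config.validate()
    m = config.n_variants
    rng = _rng(config.seed, _GENO_STREAM)
    low, high = config.maf_range
    mafs = rng.uniform(low, high, m)

    blocks: List[np.ndarray] = []
    ids: List[str] = []
    if config.n_unrelated:
        founders = rng.binomial(2, mafs, size=(config.n_unrelated, m)).astype(np.int8)
        blocks.append(founders)
        ids.extend(f"U{i + 1:06d}" for i in range(config.n_unrelated))

    pairs = []
    P = config.n_sib_pairs
    if P:
        # Parental haplotypes: (pairs, m, 2) allele indicators per parent.
        father = (rng.random((P, m, 2)) < mafs[None, :, None]).astype(np.int8)
        mother = (rng.random((P, m, 2)) < mafs[None, :, None]).astype(np.int8)

        def _child() -> np.ndarray:
            ci = rng.integers(0, 2, size=(P, m, 1))
            cj = rng.integers(0, 2, size=(P, m, 1))
            return (
                np.take_along_axis(father, ci, axis=2)[..., 0]
                + np.take_along_axis(mother, cj, axis=2)[..., 0]
            ).astype(np.int8)

        sib1, sib2 = _child(), _child()
        inter = np.empty((2 * P, m), dtype=np.int8)
        inter[0::2] = sib1
        inter[1::2] = sib2
        blocks.append(inter)
        for p in range(P):
            a, b = f"S{p + 1:06d}a", f"S{p + 1:06d}b"
            ids.extend([a, b])
            pairs.append((a, b, 0.25))

    dosages = np.vstack(blocks)
    geno = GenotypeData(np.asarray(ids, dtype=object), _variant_frame(m, mafs), dosages)
    relmap = RelatednessMap(pd.DataFrame(pairs, columns=["id_a", "id_b", "kinship"]))
    return geno, relmap


def select_causal(geno: GenotypeData, config: SimulationConfig) -> np.ndarray:
    """Seeded uniform draw of causal variant ids among those passing the
    minor-allele-count filter (MAC > mac_min_causal) and, optionally,
    lying on an odd chromosome."""
    config.validate()
    mac = geno.mac()
    eligible = mac > config.mac_min_causal
    filters = f"MAC > {config.mac_min_causal}"
    if config.odd_chromosomes_only:
        eligible &= geno.variants["chrom"].to_numpy() % 2 == 1
        filters += " on odd chromosomes"
    n_eligible = int(eligible.sum())
    if n_eligible < config.n_causal:
        raise InvalidConfigError(
            f"only {n_eligible} variants satisfy {filters}; {config.n_causal} causal requested"
        )
    rng = _rng(config.seed, _CAUSAL_STREAM)
    candidates = geno.variants.loc[eligible, "id"].to_numpy(object)
    chosen = rng.choice(candidates, size=config.n_causal, replace=False)
    return np.sort(chosen)


def simulate_trait(
    geno: GenotypeData, causal_ids, config: SimulationConfig
) -> Tuple[np.ndarray, TrueEffects]:
    """Simulate an additive trait with heritability h2 on the causal set.

    Effects are per-standardized-genotype: w_j = (g_j - 2 f_j) / sqrt(2 f_j (1 - f_j))
    with f_j the sample allele frequency. Binary traits threshold the
    liability at the realized (1 - K) quantile so the case fraction
    matches the prevalence up to rounding.
    """
    config.validate()
    causal_ids = np.asarray(causal_ids, dtype=object)
    if config.h2 == 0 and len(causal_ids) > 0:
        raise InvalidConfigError(
            "h2 = 0 with causal variants would produce zero true effects; "
            "use n_causal = 0 for a pure-noise trait"
        )
    id_to_col = {v: i for i, v in enumerate(geno.variants["id"])}
    missing = [v for v in causal_ids if v not in id_to_col]
    if missing:
        raise InvalidConfigError(f"causal ids not present in genotypes: {missing[:5]}")

    rng = _rng(config.seed, _TRAIT_STREAM)
    n = geno.n_samples
    nc = len(causal_ids)
    if nc:
        cols = np.array([id_to_col[v] for v in causal_ids], dtype=int)
        g = geno.dosage_float()[:, cols]
        f = np.nanmean(g, axis=0) / 2.0
        if ((f <= 0) | (f >= 1)).any():
            bad = causal_ids[(f <= 0) | (f >= 1)][0]
            raise InvalidConfigError(f"causal variant {bad!r} is monomorphic in the sample")
        w = (g - 2 * f) / np.sqrt(2 * f * (1 - f))
        beta = rng.normal(0.0, np.sqrt(config.h2 / nc), size=nc)
        genetic = w @ beta
    else:
        beta = np.empty(0)
        genetic = np.zeros(n)
    resid = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=n)
    liability = genetic + resid

    effects = TrueEffects(causal_ids, beta)
    if config.trait_type == "quantitative":
        return liability, effects
    # Liability-threshold binary trait: the top round(n*K) liabilities are cases.
    n_cases = int(round(n * config.prevalence_K))
    n_cases = min(max(n_cases, 1), n - 1)
    order = np.argsort(liability)
    y = np.zeros(n)
    y[order[n - n_cases:]] = 1.0
    return y, effects


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, relatedness, causal set, trait.

    Returns (geno, relmap, phenotype, effects).
    """
    geno, relmap = simulate_genotypes(config)
    if config.n_causal > 0:
        causal = select_causal(geno, config)
    else:
        causal = np.empty(0, dtype=object)
    y, effects = simulate_trait(geno, causal, config)
    return geno, relmap, y, effects
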