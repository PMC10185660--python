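"""Comparator polygenic scores built from published summary statistics.

Two constructions are provided:

* a case-case contrast PRS for ER-negative versus ER-positive disease: the
  per-SNP contrast is ``beta_ER- - beta_ER+`` (both log-odds against the same
  control group, so the difference is the case-case log-odds);
* likelihood-ratio (LR) scores: each SNP contributes a per-genotype
  likelihood ratio derived from its per-allele odds ratio and risk-allele
  frequency, and the score is the product of LRs across SNPs. With HWE
  genotype prior (q^2, 2pq, p^2) and mean multiplicative risk
  mu = (p*OR + q)^2, the genotype-g likelihood ratio is OR^g / mu, which
  makes the population-mean score exactly 1. The same machinery scores an
  overall-risk PRS from any published OR/frequency weight table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InputError
from .prs import ld_prune
from .simulate import GenotypeMatrix


def case_case_beta(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP case-case contrast: beta_er_neg - beta_er_pos (and its OR).

    SNPs missing either coefficient are dropped with a warning.
    """
    required = {"snp", "beta_er_neg", "beta_er_pos"}
    missing = required - set(stats.columns)
    if missing:
        raise InputError(f"summary statistics missing columns: {sorted(missing)}")
    ok = stats["beta_er_neg"].notna() & stats["beta_er_pos"].notna()
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} SNPs lacking one of the two beta columns",
            stacklevel=2,
        )
    out = stats.loc[ok].copy()
    out["beta_contrast"] = out["beta_er_neg"] - out["beta_er_pos"]
    out["or_contrast"] = np.exp(out["beta_contrast"])
    return out


def build_lr_weights(
    snp: pd.Series | np.ndarray,
    effect_allele: pd.Series | np.ndarray,
    or_per_allele: pd.Series | np.ndarray,
    freq: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Population-calibrated per-genotype likelihood ratios.

    For risk-allele frequency p (q = 1-p) and per-allele odds ratio OR, the
    mean multiplicative risk is mu = (p*OR + q)^2 and LR_g = OR^g / mu for
    g in {0, 1, 2}; E[LR] under HWE equals 1 identically.
    """
    orr = np.asarray(or_per_allele, dtype=float)
    p = np.asarray(freq, dtype=float)
    if np.any(orr <= 0):
        raise InputError("odds ratios must be positive")
    if np.any((p <= 0) | (p >= 1)):
        raise InputError("risk-allele frequencies must lie strictly inside (0, 1)")
    q = 1 - p
    mu = (p * orr + q) ** 2
    return pd.DataFrame(
        {
            "snp": np.asarray(snp),
            "effect_allele": np.asarray(effect_allele),
            "or": orr,
            "freq": p,
            "lr0": 1.0 / mu,
            "lr1": orr / mu,
            "lr2": orr**2 / mu,
        }
    )


def score_lr_prs(
    genotypes: GenotypeMatrix | pd.DataFrame,
    weights: pd.DataFrame,
    on_missing: str = "skip",
) -> tuple[pd.Series, float]:
    """Product of per-SNP likelihood ratios, via an exponentiated log sum.

    SNPs absent from the genotypes contribute a factor of 1 (skipped);
    coverage is the fraction of weight SNPs available.
    """
    if on_missing != "skip":
        raise InputError(f"unsupported on_missing policy: {on_missing}")
    dos = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    avail = [s for s in weights["snp"] if s in dos.columns]
    if not avail:
        raise InputError("no weight SNPs present in the genotype matrix")
    w = weights.set_index("snp").loc[avail]
    log_lr = np.log(w[["lr0", "lr1", "lr2"]].to_numpy(dtype=float))  # (snps, 3)
    G = dos[avail].to_numpy(dtype=float)
    if np.isnan(G).any():
        raise InputError("genotypes contain missing values; run fill_missing_genotypes first")
    g = np.rint(G).astype(int)
    if np.any((g < 0) | (g > 2)):
        raise InputError("dosages must be genotype counts in {0, 1, 2}")
    per_snp = log_lr[np.arange(len(avail))[None, :], g]  # (n, snps) log LR lookup
    scores = pd.Series(np.exp(per_snp.sum(axis=1)), index=dos.index, name="lr_prs")
    return scores, len(avail) / len(weights)


def prune_and_weight_er_prs(
    stats: pd.DataFrame, ld: pd.DataFrame, r2_threshold: float = 0.2
) -> pd.DataFrame:
    """ER-/ER+ case-case PRS weights: LD prune, contrast, likelihood ratios."""
    contrasts = case_case_beta(stats)
    cand = contrasts.rename(columns={"pub_p": "pub_p"})[["snp", "pub_p"]]
    if "pub_p" not in contrasts.columns:
        raise InputError("summary statistics need a pub_p column for LD pruning")
    kept = ld_prune(cand, ld, r2_threshold)
    pruned = contrasts[contrasts["snp"].isin(kept["snp"])]
    return build_lr_weights(
        pruned["snp"], pruned["effect_allele"], pruned["or_contrast"], pruned["freq"]
    )
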