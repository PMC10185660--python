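"""Construction of a polygenic score for a quantitative tumor phenotype (ROR-P).

The pipeline follows the case-only PRS recipe: LD-prune candidate SNPs
(r2 >= 0.2, keeping the lower published GWAS p-value), fill sporadic missing
genotypes from per-SNP Hardy-Weinberg probabilities (excluding SNPs with >5%
missingness), residualize the phenotype on ancestry principal components and
a study indicator, regress the residual on each SNP, choose the p-value
inclusion threshold by repeated k-fold cross-validation over a grid, refit
per-SNP weights on the full data with covariate adjustment, and score
samples as the weighted sum of risk-allele dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .simulate import GenotypeMatrix

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.1, 0.6 + 1e-9, 0.025), 4)

PC_COLUMNS = [f"PC{i}" for i in range(1, 11)]


def ld_prune(
    candidates: pd.DataFrame, ld: pd.DataFrame, r2_threshold: float = 0.2
) -> pd.DataFrame:
    """Greedy LD clumping: keep the SNP with the lower published p-value.

    Candidates are visited in ascending published p-value (ties broken by
    snp id); a SNP is kept iff its r2 with every already-kept SNP is below
    ``r2_threshold``. Pairs absent from ``ld`` are treated as r2 = 0.
    """
    if len(ld):
        r2 = ld["r2"].to_numpy(dtype=float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise InputError("LD r2 values must lie in [0, 1]")
    pair_r2: dict[frozenset, float] = {}
    for _, row in ld.iterrows():
        pair_r2[frozenset((row["snp_a"], row["snp_b"]))] = float(row["r2"])
    order = candidates.sort_values(["pub_p", "snp"], kind="mergesort")
    kept: list[str] = []
    for snp in order["snp"]:
        if all(pair_r2.get(frozenset((snp, k)), 0.0) < r2_threshold for k in kept):
            kept.append(snp)
    return candidates[candidates["snp"].isin(kept)].reset_index(drop=True)


def fill_missing_genotypes(
    genotypes: GenotypeMatrix, max_missing: float = 0.05, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Exclude SNPs with missingness above ``max_missing``; HWE-fill the rest.

    Remaining missing entries are drawn from (q^2, 2pq, p^2) with p the
    observed effect-allele frequency among non-missing samples for that SNP.
    Returns the completed matrix and a per-SNP exclusion report.
    """
    rng = np.random.default_rng(None if seed is None else [11, seed])
    miss = genotypes.missingness()
    all_missing = miss.index[miss == 1.0].tolist()
    if all_missing:
        warnings.warn(f"removing {len(all_missing)} SNPs with all genotypes missing", stacklevel=2)
    excluded = miss.index[(miss > max_missing)].tolist()
    report = pd.DataFrame(
        {"missingness": miss, "excluded": miss.index.isin(excluded)}
    )
    kept = [s for s in genotypes.snps if s not in excluded]
    dos = genotypes.dosages[kept].copy()
    for snp in kept:
        col = dos[snp]
        na = col.isna()
        if not na.any():
            continue
        p = col.mean(skipna=True) / 2.0
        probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        probs /= probs.sum()
        dos.loc[na, snp] = rng.choice(3, size=int(na.sum()), p=probs).astype(float)
    return (
        GenotypeMatrix(dosages=dos, snp_info=genotypes.snp_info.loc[kept].copy()),
        report,
    )


def _covariate_design(
    covars: pd.DataFrame, study_levels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + PC1-10 + study dummies (first level dropped)."""
    missing = [c for c in PC_COLUMNS if c not in covars.columns]
    if missing:
        raise InputError(f"covariate table missing columns: {missing}")
    cols = [np.ones(len(covars))] + [covars[c].to_numpy(dtype=float) for c in PC_COLUMNS]
    names = ["intercept"] + PC_COLUMNS
    if "study" in covars.columns:
        levels = study_levels or sorted(covars["study"].astype(str).unique())
        for lev in levels[1:]:
            cols.append((covars["study"].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"study[{lev}]")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise InputError(f"rank-deficient covariate design; collinear columns: {bad}")


def residualize_rorp(
    rorp: pd.Series, covars: pd.DataFrame, study_levels: list[str] | None = None
) -> pd.Series:
    """OLS residuals of ROR-P on PC1-10 plus study dummies (mean ~0)."""
    X, names = _covariate_design(covars.loc[rorp.index], study_levels)
    if len(rorp) <= X.shape[1]:
        raise InputError(f"need more than {X.shape[1]} samples to residualize")
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, rorp.to_numpy(dtype=float), rcond=None)
    return pd.Series(rorp.to_numpy(dtype=float) - X @ beta, index=rorp.index, name="residual")


def snp_association_scan(
    residuals: pd.Series, genotypes: GenotypeMatrix | pd.DataFrame
) -> pd.DataFrame:
    """Simple linear regression of the residual on each SNP dosage.

    Vectorized across SNPs; returns per-SNP beta, SE and two-sided p from the
    t statistic. Zero-variance (monomorphic) dosage columns are flagged
    ``excluded`` with NaN statistics.
    """
    dos = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    G = dos.loc[residuals.index].to_numpy(dtype=float)
    if np.isnan(G).any():
        raise InputError("genotypes contain missing values; run fill_missing_genotypes first")
    y = residuals.to_numpy(dtype=float)
    n = len(y)
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    sxx = (Gc**2).sum(axis=0)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    sxy = Gc.T @ yc
    beta = sxy / sxx_safe
    rss = (yc**2).sum() - beta * sxy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "excluded": mono}, index=dos.columns
    )
    out.loc[mono, ["beta", "se", "p"]] = np.nan
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs flagged and excluded", stacklevel=2)
    return out


def _adjusted_weights(
    y: np.ndarray, G: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP dosage coefficient from single-SNP models y ~ dosage + covariates.

    Computed by Frisch-Waugh-Lovell: residualize y and every dosage column on
    the covariate design, then take per-SNP slopes. Identical to fitting each
    single-SNP multiple regression. Returns (beta, se, p).
    """
    n, p_cov = X.shape
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    ry = y - X @ coef_y
    coef_g, *_ = np.linalg.lstsq(X, G, rcond=None)
    RG = G - X @ coef_g
    sxx = (RG**2).sum(axis=0)
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    sxy = RG.T @ ry
    beta = sxy / sxx_safe
    rss = (ry**2).sum() - beta * sxy
    df = n - p_cov - 1
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2, 0) / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pval = 2 * stats.t.sf(np.abs(t), df=df)
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan
    return beta, se, pval


def fit_final_weights(
    rorp: pd.Series,
    covars: pd.DataFrame,
    genotypes: GenotypeMatrix,
    selected_snps: list[str],
    study_levels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP weights: dosage coefficient of ROR-P ~ dosage + PC1-10 + study."""
    if not selected_snps:
        raise InputError("selected SNP set is empty")
    X, names = _covariate_design(covars.loc[rorp.index], study_levels)
    _check_rank(X, names)
    G = genotypes.dosages.loc[rorp.index, selected_snps].to_numpy(dtype=float)
    beta, se, p = _adjusted_weights(rorp.to_numpy(dtype=float), G, X)
    info = genotypes.snp_info
    return pd.DataFrame(
        {
            "snp": selected_snps,
            "effect_allele": [
                info.loc[s, "effect_allele"] if s in info.index else pd.NA
                for s in selected_snps
            ],
            "beta": beta,
            "se": se,
            "p": p,
        }
    )


@dataclass
class CVResult:
    """Cross-validated threshold selection outcome."""

    grid: np.ndarray
    mean_r2: np.ndarray                 # per threshold, averaged over folds x repeats
    fold_r2: np.ndarray                 # (repeats, k, n_thresholds)
    selected_threshold: float
    selected_snps: list[str]
    scan: pd.DataFrame                  # full-data scan used for final selection
    in_sample_r2: float

    @property
    def n_selected(self) -> int:
        return len(self.selected_snps)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "cv_r2": self.mean_r2})


def cv_threshold_selection(
    rorp: pd.Series,
    covars: pd.DataFrame,
    genotypes: GenotypeMatrix,
    candidates: pd.DataFrame,
    grid: np.ndarray | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Select the scan p-value inclusion threshold by repeated k-fold CV.

    Within every training fold the phenotype is residualized, scanned against
    each candidate SNP, and covariate-adjusted per-SNP weights are fit; the
    held-out fold is scored at each threshold and the fold r2 is the squared
    Pearson correlation between the held-out PRS and held-out residuals
    (residuals from the training-fold covariate model applied to the held-out
    covariates). The selected threshold maximizes the mean r2, ties going to
    the smaller threshold; the final SNP set comes from a full-data scan at
    that threshold.
    """
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("threshold grid is empty")
    if k < 2:
        raise InputError("k must be >= 2")
    rng = np.random.default_rng(None if seed is None else [13, seed])
    snps = [s for s in candidates["snp"] if s in genotypes.snps]
    if not snps:
        raise InputError("no candidate SNPs present in the genotype matrix")
    G_all = genotypes.dosages.loc[rorp.index, snps].to_numpy(dtype=float)
    if np.isnan(G_all).any():
        raise InputError("genotypes contain missing values; run fill_missing_genotypes first")
    y_all = rorp.to_numpy(dtype=float)
    study_levels = (
        sorted(covars["study"].astype(str).unique()) if "study" in covars.columns else None
    )
    X_all, names = _covariate_design(covars.loc[rorp.index], study_levels)
    n = len(y_all)
    fold_r2 = np.zeros((repeats, k, grid.size))
    empty_warned = False
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
            X_tr, X_te = X_all[train_idx], X_all[test_idx]
            y_tr, y_te = y_all[train_idx], y_all[test_idx]
            coef, *_ = np.linalg.lstsq(X_tr, y_tr, rcond=None)
            r_tr = y_tr - X_tr @ coef
            r_te = y_te - X_te @ coef
            G_tr, G_te = G_all[train_idx], G_all[test_idx]
            # scan on the training residuals
            Gc = G_tr - G_tr.mean(axis=0)
            sxx = (Gc**2).sum(axis=0)
            mono = sxx == 0
            sxx_safe = np.where(mono, 1.0, sxx)
            rc = r_tr - r_tr.mean()
            b_scan = (Gc.T @ rc) / sxx_safe
            rss = (rc**2).sum() - b_scan * (Gc.T @ rc)
            se = np.sqrt(rss / (len(r_tr) - 2) / sxx_safe)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = b_scan / se
            p_scan = 2 * stats.t.sf(np.abs(tstat), df=len(r_tr) - 2)
            p_scan[mono] = np.nan
            # covariate-adjusted weights on the training fold
            b_w, _, _ = _adjusted_weights(y_tr, G_tr, X_tr)
            for ti, thr in enumerate(grid):
                sel = np.flatnonzero((p_scan < thr) & ~np.isnan(b_w))
                if sel.size == 0:
                    if not empty_warned:
                        warnings.warn(
                            f"no SNP passed threshold {thr}; fold r2 recorded as 0",
                            stacklevel=2,
                        )
                        empty_warned = True
                    continue
                prs_te = G_te[:, sel] @ b_w[sel]
                if prs_te.std() == 0 or r_te.std() == 0:
                    continue
                r = np.corrcoef(prs_te, r_te)[0, 1]
                fold_r2[rep, fi, ti] = r**2
    mean_r2 = fold_r2.mean(axis=(0, 1))
    sel_idx = int(np.argmax(mean_r2))  # first max -> smaller threshold on ties
    selected_threshold = float(grid[sel_idx])
    resid_full = residualize_rorp(rorp, covars, study_levels)
    scan_full = snp_association_scan(resid_full, genotypes.dosages.loc[rorp.index, snps])
    selected = scan_full.index[
        (scan_full["p"] < selected_threshold) & ~scan_full["excluded"]
    ].tolist()
    in_sample_r2 = 0.0
    if selected:
        w = fit_final_weights(rorp, covars, genotypes, selected, study_levels)
        prs = genotypes.dosages.loc[rorp.index, selected].to_numpy() @ w["beta"].to_numpy()
        if prs.std() > 0:
            in_sample_r2 = float(
                np.corrcoef(prs, resid_full.to_numpy())[0, 1] ** 2
            )
    return CVResult(
        grid=grid,
        mean_r2=mean_r2,
        fold_r2=fold_r2,
        selected_threshold=selected_threshold,
        selected_snps=selected,
        scan=scan_full,
        in_sample_r2=in_sample_r2,
    )


def score_prs(
    genotypes: GenotypeMatrix | pd.DataFrame,
    weights: pd.DataFrame,
    on_missing: str = "drop",
) -> tuple[pd.Series, float]:
    """Weighted sum of risk-allele dosages; returns (scores, SNP coverage).

    SNPs in the weight table but absent from the genotypes are dropped
    without reweighting (``on_missing='drop'``); coverage is the fraction of
    weight SNPs available.
    """
    if on_missing != "drop":
        raise InputError(f"unsupported on_missing policy: {on_missing}")
    dos = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    w = weights.dropna(subset=["beta"])
    avail = [s for s in w["snp"] if s in dos.columns]
    if not avail:
        raise InputError("no weight SNPs present in the genotype matrix")
    wmap = dict(zip(w["snp"], w["beta"]))
    beta = np.array([wmap[s] for s in avail])
    G = dos[avail].to_numpy(dtype=float)
    if np.isnan(G).any():
        raise InputError("genotypes contain missing values; run fill_missing_genotypes first")
    scores = pd.Series(G @ beta, index=dos.index, name="prs")
    return scores, len(avail) / len(w)


def standardize_prs(prs: pd.Series, mode: str = "zscore") -> pd.Series:
    """Z-score the PRS over the case set; ``log-zscore`` takes ln first."""
    x = prs.to_numpy(dtype=float)
    if len(x) < 2:
        raise InputError("need at least 2 samples to standardize")
    if mode == "log-zscore":
        if np.any(x <= 0):
            raise InputError("log-zscore requires strictly positive scores")
        x = np.log(x)
    elif mode != "zscore":
        raise InputError(f"unknown standardization mode: {mode}")
    sd = x.std()
    if sd == 0:
        raise InputError("PRS has zero standard deviation")
    return pd.Series((x - x.mean()) / sd, index=prs.index, name=prs.name)
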