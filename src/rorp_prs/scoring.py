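"""ROR-P scoring from tumor gene expression.

Implements the PAM50-style nearest-centroid workflow used to compute the
risk-of-recurrence score weighted on proliferation (ROR-P):

1. probe-to-gene collapsing (mean across probes),
2. ER-balanced median-of-medians normalization, which addresses the
   "population assumption" of centroid-based subtyping by referencing each
   gene to the median expression in repeated subsamples containing all
   ER-negative tumors plus an equal number of random ER-positive tumors,
3. Spearman rank correlation of each sample against the five intrinsic
   subtype centroids (Basal, Her2, LumA, LumB, Normal), with the subtype
   call taken as the highest correlation,
4. a proliferation index (mean normalized expression of an 11-gene subset),
5. the ROR-P linear combination

   ROR-P = -0.001*Basal + 0.7*Her2 - 0.95*LumA + 0.49*LumB + 0.34*Prolif

   where the first four terms are subtype-centroid correlations and Prolif
   is the proliferation index. The Normal correlation participates in the
   subtype call but carries zero weight in the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError

SUBTYPE_LABELS = ("Basal", "Her2", "LumA", "LumB", "Normal")

#: Published weights of the ROR-P linear combination. Normal-like carries no
#: weight; Prolif multiplies the proliferation index rather than a correlation.
RORP_COEFFICIENTS = {
    "Basal": -0.001,
    "Her2": 0.7,
    "LumA": -0.95,
    "LumB": 0.49,
    "Prolif": 0.34,
}


@dataclass
class Centroids:
    """Subtype centroid matrix (genes x 5 subtypes) plus the proliferation-gene subset."""

    values: pd.DataFrame
    proliferation_genes: list[str]

    def __post_init__(self) -> None:
        cols = tuple(self.values.columns)
        if cols != SUBTYPE_LABELS:
            raise InputError(
                f"centroid matrix must have exactly the columns {SUBTYPE_LABELS}, got {cols}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise InputError(f"duplicate genes in centroid matrix: {dups}")
        missing = set(self.proliferation_genes) - set(self.values.index)
        if missing:
            raise InputError(
                f"proliferation genes absent from centroid matrix: {sorted(missing)}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "proliferation", out.index.isin(self.proliferation_genes).astype(int))
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Centroids":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        prolif = df.index[df.pop("proliferation").astype(int) == 1].tolist()
        return cls(values=df[list(SUBTYPE_LABELS)], proliferation_genes=prolif)


@dataclass
class RORPModel:
    """ROR-P linear model: fixed published coefficients, optional affine rescale and cutoffs.

    The raw score from the coefficients above lives on roughly [-2.2, 2.2]
    (correlations bounded by 1; proliferation on the normalized expression
    scale). Clinical reports place ROR-P on a 0-100 scale via an affine
    transform that is not part of the published combination; ``rescale``
    applies ``slope * raw + intercept`` when set. ``cutoffs = (low, high)``
    optionally buckets the (rescaled) score into Low/Medium/High.
    """

    coefficients: dict[str, float] = field(default_factory=lambda: dict(RORP_COEFFICIENTS))
    rescale: tuple[float, float] | None = None
    cutoffs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cutoffs is not None and not self.cutoffs[0] < self.cutoffs[1]:
            raise InputError(f"low cutoff must be below high cutoff, got {self.cutoffs}")


def affine_rescale_to_0_100(prolif_range: tuple[float, float] = (-2.0, 2.0)) -> tuple[float, float]:
    """(slope, intercept) mapping the theoretical ROR-P range onto [0, 100].

    Correlation components are bounded by [-1, 1]; the proliferation index is
    clamped to ``prolif_range`` (an estimate of its plausible normalized-
    expression range).
    """
    corr_span = sum(abs(RORP_COEFFICIENTS[k]) for k in ("Basal", "Her2", "LumA", "LumB"))
    lo = -corr_span + RORP_COEFFICIENTS["Prolif"] * prolif_range[0]
    hi = corr_span + RORP_COEFFICIENTS["Prolif"] * prolif_range[1]
    slope = 100.0 / (hi - lo)
    return slope, -slope * lo


def collapse_probes(
    expr: pd.DataFrame, probe_map: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Collapse probe-level expression to gene level by the mean across probes.

    Parameters
    ----------
    expr : samples x probes matrix.
    probe_map : two columns, ``probe`` and ``gene``. A probe mapping to more
        than one gene is an input error; probes absent from the map are
        dropped with a warning.

    Returns the gene-level matrix and a report dict with the number of
    unmapped probes dropped. Columns already named at gene level pass through
    unchanged when the probe map maps them to themselves.
    """
    pm = probe_map[["probe", "gene"]].dropna()
    multi = pm.groupby("probe")["gene"].nunique()
    bad = multi.index[multi > 1].tolist()
    if bad:
        raise InputError(f"probes mapped to multiple genes: {bad}")
    mapping = dict(zip(pm["probe"], pm["gene"]))
    unmapped = [c for c in expr.columns if c not in mapping]
    if unmapped:
        warnings.warn(f"dropping {len(unmapped)} unmapped probes", stacklevel=2)
    kept = [c for c in expr.columns if c in mapping]
    if not kept:
        raise InputError("no probes could be mapped to genes")
    collapsed = expr[kept].T.groupby([mapping[c] for c in kept]).mean().T
    return collapsed, {"n_unmapped_dropped": len(unmapped), "n_genes": collapsed.shape[1]}


def er_balanced_median_normalize(
    expr: pd.DataFrame,
    er_status: pd.Series,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract an ER-balanced per-gene reference median from expression.

    For each of ``n_reps`` repetitions a subsample is formed from all
    ER-negative samples plus an equal number of ER-positive samples drawn
    without replacement; the per-gene median of the subsample is recorded.
    The reference is the per-gene median of the ``n_reps`` medians, and the
    returned matrix is ``expr - reference``.

    ``er_status`` is boolean-like (truthy = ER-positive), aligned to
    ``expr.index``. If fewer ER-positive than ER-negative samples exist the
    ER-positive draw falls back to sampling with replacement, with a warning.
    """
    er = er_status.reindex(expr.index).astype(bool).to_numpy()
    n_neg = int((~er).sum())
    n_pos = int(er.sum())
    if n_neg == 0:
        raise InputError("ER-balanced normalization requires at least one ER-negative sample")
    if n_pos == 0:
        raise InputError("ER-balanced normalization requires ER-positive samples")
    replace = n_pos < n_neg
    if replace:
        warnings.warn(
            f"only {n_pos} ER-positive samples for {n_neg} ER-negative; "
            "sampling ER-positive cases with replacement",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    vals = expr.to_numpy(dtype=float)
    neg_vals = vals[~er]
    pos_idx = np.flatnonzero(er)
    n_genes = vals.shape[1]
    medians = np.empty((n_reps, n_genes))
    # chunk repetitions to bound the (chunk, 2*n_neg, n_genes) working array
    chunk = max(1, int(5e6 / max(1, 2 * n_neg * n_genes)))
    for start in range(0, n_reps, chunk):
        c = min(chunk, n_reps - start)
        if replace:
            pick = rng.choice(pos_idx, size=(c, n_neg), replace=True)
        else:
            pick = np.empty((c, n_neg), dtype=int)
            for j in range(c):
                pick[j] = rng.choice(pos_idx, size=n_neg, replace=False)
        sub = np.concatenate(
            [np.broadcast_to(neg_vals, (c, n_neg, n_genes)), vals[pick]], axis=1
        )
        medians[start : start + c] = np.median(sub, axis=1)
    reference = pd.Series(np.median(medians, axis=0), index=expr.columns, name="reference")
    return expr - reference, reference


def subtype_correlations(
    expr_norm: pd.DataFrame, centroids: Centroids
) -> pd.DataFrame:
    """Per-sample Spearman correlations with each subtype centroid, plus the call.

    Uses the intersection of genes between the expression matrix and the
    centroid matrix (at least 3 required). The call is the argmax over the
    five correlations with ties broken in the fixed label order
    (Basal, Her2, LumA, LumB, Normal). Samples with a constant expression
    vector have undefined rank correlations; they get NaN correlations and a
    missing call.
    """
    shared = [g for g in centroids.genes if g in expr_norm.columns]
    if len(shared) < 3:
        raise InputError(
            f"only {len(shared)} genes shared between expression and centroids; need >= 3"
        )
    x = expr_norm[shared].to_numpy(dtype=float)
    c = centroids.values.loc[shared].to_numpy(dtype=float)
    rx = rankdata(x, axis=1)
    rc = rankdata(c, axis=0)
    rx = rx - rx.mean(axis=1, keepdims=True)
    rc = rc - rc.mean(axis=0, keepdims=True)
    sx = np.sqrt((rx**2).sum(axis=1))
    sc = np.sqrt((rc**2).sum(axis=0))
    degenerate = sx == 0
    sx_safe = np.where(degenerate, 1.0, sx)
    corr = (rx @ rc) / (sx_safe[:, None] * sc[None, :])
    corr[degenerate] = np.nan
    out = pd.DataFrame(corr, index=expr_norm.index, columns=list(SUBTYPE_LABELS))
    calls = pd.Series(
        np.array(SUBTYPE_LABELS)[np.nanargmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)]
        if len(out)
        else [],
        index=expr_norm.index,
        dtype=object,
    )
    calls[degenerate] = pd.NA
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} samples with constant expression excluded from calls",
            stacklevel=2,
        )
    out["call"] = calls
    out.attrs["n_shared_genes"] = len(shared)
    return out


def proliferation_index(expr_norm: pd.DataFrame, centroids: Centroids) -> pd.Series:
    """Mean normalized expression over the flagged proliferation genes."""
    missing = [g for g in centroids.proliferation_genes if g not in expr_norm.columns]
    if missing:
        raise InputError(f"proliferation genes absent from expression: {missing}")
    return expr_norm[centroids.proliferation_genes].mean(axis=1).rename("Prolif")


def compute_rorp(profile: pd.DataFrame, model: RORPModel | None = None) -> pd.DataFrame:
    """Evaluate the ROR-P combination on a subtype-correlation profile.

    ``profile`` must contain columns Basal, Her2, LumA, LumB and Prolif
    (the Normal correlation, if present, is ignored by the score). Returns a
    frame with ``rorp`` and, when the model configures cutoffs, ``rorp_group``.
    """
    model = model or RORPModel()
    needed = [k for k in model.coefficients if k != "Normal"]
    missing = [k for k in needed if k not in profile.columns]
    if missing:
        raise InputError(f"profile missing ROR-P components: {missing}")
    raw = sum(model.coefficients[k] * profile[k] for k in needed)
    if model.rescale is not None:
        slope, intercept = model.rescale
        raw = slope * raw + intercept
    out = pd.DataFrame({"rorp": raw})
    if model.cutoffs is not None:
        low, high = model.cutoffs
        out["rorp_group"] = pd.cut(
            out["rorp"], [-np.inf, low, high, np.inf], labels=["Low", "Medium", "High"]
        )
    return out


def score_expression(
    expr: pd.DataFrame,
    er_status: pd.Series,
    centroids: Centroids,
    probe_map: pd.DataFrame | None = None,
    model: RORPModel | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full ROR-P chain: collapse, normalize, correlate, score.

    Returns a frame with the five centroid correlations, the subtype call,
    the proliferation index and the ROR-P score (plus group when configured).
    """
    if probe_map is not None:
        expr, _ = collapse_probes(expr, probe_map)
    norm, _ = er_balanced_median_normalize(expr, er_status, n_reps=n_reps, seed=seed)
    prof = subtype_correlations(norm, centroids)
    prof["Prolif"] = proliferation_index(norm, centroids)
    scored = compute_rorp(prof, model)
    return pd.concat([prof, scored], axis=1)
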