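"""Seeded synthetic cohorts with paired germline genotypes, tumor expression and outcomes.

The generator emulates the statistical structure the downstream analysis
assumes, with recorded ground truth so parameter recovery can be tested:

* genotypes: independent SNPs in Hardy-Weinberg equilibrium, MAF uniform on a
  configurable range; optional LD partner SNPs for pruning exercises; optional
  i.i.d. missingness;
* tumor state: intrinsic subtype from a multinomial logit whose linear
  predictor moves along an "aggressiveness" axis driven by a causal-SNP
  score; proliferation as a subtype-shifted additive genetic score plus
  Gaussian noise; a latent ROR-P defined on the true subtype indicator and
  proliferation through the published ROR-P coefficient pattern;
* the genetic strength is calibrated by root-finding so the fraction of
  latent ROR-P variance explained by genotype (its narrow-sense
  heritability) equals the configured value (default 0.17, inside the
  13-21% range reported for ROR-P);
* expression: centroid of the true subtype plus Gaussian noise, with
  proliferation genes shifted by the sample's proliferation value, optional
  per-study location shifts and probe-level expansion;
* outcomes: exponential event times whose hazard is log-linear in the
  standardized latent ROR-P, administratively censored; clinical covariates
  (age, BMI, stage, treatments, receptor status, grade) with simple stated
  dependencies so nested covariate models are exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigurationError
from .scoring import Centroids, RORP_COEFFICIENTS, SUBTYPE_LABELS

# Multinomial-logit baseline prevalences, loosely patterned on intrinsic
# subtype mixes in breast cancer case series.
SUBTYPE_BASE_PREV = {"Basal": 0.18, "Her2": 0.12, "LumA": 0.40, "LumB": 0.22, "Normal": 0.08}
# Direction of the genetic aggressiveness axis per subtype: positive values
# become more likely as the causal-subtype score rises.
SUBTYPE_DIRECTION = {"Basal": 1.0, "Her2": 0.3, "LumA": -1.0, "LumB": 0.5, "Normal": -0.3}
# Subtype-conditional proliferation means (normalized expression units).
SUBTYPE_PROLIF_MEAN = {"Basal": 1.2, "Her2": 0.8, "LumA": -0.8, "LumB": 0.6, "Normal": -0.5}
# Receptor-status probabilities conditional on true subtype.
ER_POS_GIVEN_SUBTYPE = {"Basal": 0.10, "Her2": 0.35, "LumA": 0.95, "LumB": 0.85, "Normal": 0.70}
HER2_POS_GIVEN_SUBTYPE = {"Basal": 0.08, "Her2": 0.85, "LumA": 0.05, "LumB": 0.25, "Normal": 0.08}

_KAPPA_SUBTYPE = 0.6   # base multinomial-logit slope, scaled by the calibrated strength
_KAPPA_PROLIF = 1.0    # base genetic slope on proliferation
_PROLIF_NOISE_SD = 1.0 # non-genetic proliferation noise

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

# fixed stream tags so each generator stage has its own independent substream
_STREAM_GENO, _STREAM_TUMOR, _STREAM_EXPR, _STREAM_OUTCOME, _STREAM_MISS = range(5)


def _rng(seed: int | None, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, 0 if seed is None else seed])


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the package's study conditions."""

    n_samples: int = 2500
    n_snps: int = 226
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_subtype: int = 10
    n_causal_prolif: int = 10
    genetic_variance_fraction: float = 0.17
    n_genes: int = 50
    n_prolif_genes: int = 11
    n_studies: int = 3
    er_positive_fraction: float = 0.75
    hr_per_sd: float = 1.3
    baseline_hazard: float = 0.03
    admin_censor_time: float = 12.0
    missing_rate: float = 0.02
    probe_multiplicity: int = 1
    n_ld_pairs: int = 0
    ld_r2: float = 0.5
    expression_noise_sd: float = 1.0
    study_shift_sd: float = 0.3
    probe_noise_sd: float = 0.3
    pc_rorp_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within [0, 0.5], got {self.maf_range}")
        if not 0 <= self.genetic_variance_fraction < 1:
            raise ConfigurationError("genetic_variance_fraction must be in [0, 1)")
        if not 0 < self.er_positive_fraction < 1:
            raise ConfigurationError("er_positive_fraction must be in (0, 1)")
        if self.hr_per_sd <= 0:
            raise ConfigurationError("hr_per_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_prolif_genes > self.n_genes:
            raise ConfigurationError("n_prolif_genes cannot exceed n_genes")
        if self.n_samples < 1 or self.n_snps < 1:
            raise ConfigurationError("n_samples and n_snps must be >= 1")
        if self.n_causal_subtype + self.n_causal_prolif > self.n_snps:
            raise ConfigurationError("causal SNP counts exceed n_snps")
        if self.probe_multiplicity < 1:
            raise ConfigurationError("probe_multiplicity must be >= 1")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs risk-allele dosages (NaN = missing) with per-SNP metadata."""

    dosages: pd.DataFrame
    snp_info: pd.DataFrame  # index snp; effect_allele, other_allele, maf_true, pub_p

    @property
    def snps(self) -> pd.Index:
        return self.dosages.columns

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    def missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    def allele_freq(self) -> pd.Series:
        """Observed effect-allele frequency among non-missing genotypes."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def candidates(self) -> pd.DataFrame:
        """Candidate-SNP table (snp, risk_allele, pub_p) for PRS construction."""
        return pd.DataFrame(
            {
                "snp": self.snp_info.index,
                "risk_allele": self.snp_info["effect_allele"].to_numpy(),
                "pub_p": self.snp_info["pub_p"].to_numpy(),
            }
        )


@dataclass
class Population:
    """Population-level parameters shared by development and validation cohorts."""

    snp_info: pd.DataFrame
    subtype_weights: np.ndarray   # per-SNP effect on the subtype aggressiveness score
    prolif_weights: np.ndarray    # per-SNP effect on proliferation
    strength: float | None = None  # calibrated genetic strength multiplier
    er_offset: float | None = None


@dataclass
class GroundTruth:
    """Per-sample latent state plus the per-SNP effects that generated it."""

    samples: pd.DataFrame  # subtype_true, prolif_true, latent_rorp, genetic_value, er, her2, grade, study, PC1-10
    snp_effects: pd.DataFrame
    population: Population
    target_r2: float
    population_r2: float


def simulate_genotypes(
    config: SimulationConfig, population: Population | None = None
) -> GenotypeMatrix:
    """Draw HWE genotypes; i.i.d. per sample, MAF uniform on ``maf_range``.

    When ``population`` is given its SNP metadata (ids, alleles, MAFs,
    published p-values) is reused, so validation cohorts share the
    development cohort's loci.
    """
    rng = _rng(config.seed, _STREAM_GENO)
    if population is not None:
        info = population.snp_info
    else:
        n = config.n_snps
        ids = [f"rs{100000 + i}" for i in range(n)]
        pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n)]
        info = pd.DataFrame(
            {
                "effect_allele": [p[0] for p in pairs],
                "other_allele": [p[1] for p in pairs],
                "maf_true": rng.uniform(*config.maf_range, n),
                # published GWAS p-values for breast cancer susceptibility:
                # genome-wide significant by construction, unrelated to the
                # simulated ROR-P effects
                "pub_p": 10.0 ** (-rng.uniform(8, 30, n)),
            },
            index=pd.Index(ids, name="snp"),
        )
    mafs = info["maf_true"].to_numpy()
    # allele-level draws so LD partners can be constructed by allele copying
    alleles = rng.random((config.n_samples, len(mafs), 2)) < mafs[None, :, None]
    dosages = alleles.sum(axis=2).astype(float)
    sample_ids = [f"S{i:06d}" for i in range(config.n_samples)]
    gm = GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=pd.Index(sample_ids, name="sample"), columns=info.index),
        snp_info=info.copy(),
    )
    if population is None and config.n_ld_pairs > 0:
        gm = _add_ld_partners(gm, alleles, config, rng)
    return gm


def _add_ld_partners(
    gm: GenotypeMatrix, alleles: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Append LD partner SNPs: allele copies refreshed with prob 1 - sqrt(r2)."""
    n_pairs = min(config.n_ld_pairs, gm.dosages.shape[1])
    src = rng.choice(gm.dosages.shape[1], n_pairs, replace=False)
    keep_prob = np.sqrt(config.ld_r2)  # allele correlation = sqrt(r2) target
    cols, infos = {}, []
    for j in src:
        maf = gm.snp_info["maf_true"].iloc[j]
        fresh = rng.random(alleles.shape[0] * 2).reshape(-1, 2) < maf
        keep = rng.random((alleles.shape[0], 2)) < keep_prob
        partner = np.where(keep, alleles[:, j, :], fresh).sum(axis=1).astype(float)
        sid = gm.snp_info.index[j]
        pid = f"{sid}_ld"
        cols[pid] = partner
        infos.append(
            {
                "snp": pid,
                "effect_allele": gm.snp_info["effect_allele"].iloc[j],
                "other_allele": gm.snp_info["other_allele"].iloc[j],
                "maf_true": maf,
                # partner published p is strictly larger, so pruning keeps the source
                "pub_p": min(1.0, gm.snp_info["pub_p"].iloc[j] * 10 ** rng.uniform(1, 4)),
            }
        )
    part = pd.DataFrame(cols, index=gm.dosages.index)
    info = pd.concat([gm.snp_info, pd.DataFrame(infos).set_index("snp")])
    return GenotypeMatrix(dosages=pd.concat([gm.dosages, part], axis=1), snp_info=info)


def ld_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Empirical r2 table for the simulated LD partner pairs (PLINK-style columns)."""
    rows = []
    for pid in gm.snps:
        if pid.endswith("_ld"):
            sid = pid[: -len("_ld")]
            r = np.corrcoef(gm.dosages[sid], gm.dosages[pid])[0, 1]
            rows.append({"snp_a": sid, "snp_b": pid, "r2": float(r**2)})
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _subtype_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    base = np.log([SUBTYPE_BASE_PREV[k] for k in SUBTYPE_LABELS])
    direction = np.array([SUBTYPE_DIRECTION[k] for k in SUBTYPE_LABELS])
    prolif_mean = np.array([SUBTYPE_PROLIF_MEAN[k] for k in SUBTYPE_LABELS])
    coeff = np.array([RORP_COEFFICIENTS.get(k, 0.0) for k in SUBTYPE_LABELS])
    return base, direction, prolif_mean, coeff


def _subtype_probs(z_sub: np.ndarray, strength: float) -> np.ndarray:
    base, direction, _, _ = _subtype_arrays()
    lp = base[None, :] + strength * _KAPPA_SUBTYPE * direction[None, :] * z_sub[:, None]
    lp -= lp.max(axis=1, keepdims=True)
    p = np.exp(lp)
    return p / p.sum(axis=1, keepdims=True)


def _latent_moments(
    z_sub: np.ndarray, z_pro: np.ndarray, strength: float
) -> tuple[np.ndarray, float]:
    """Per-sample E[latent ROR-P | genotype] and mean conditional variance.

    The latent score is u_S + c_P * (strength * kappa_p * z_pro + eps) with
    u_k = coeff_k + c_P * prolif_mean_k, so both conditional moments are
    available in closed form from the multinomial-logit subtype probabilities.
    """
    _, _, prolif_mean, coeff = _subtype_arrays()
    c_p = RORP_COEFFICIENTS["Prolif"]
    u = coeff + c_p * prolif_mean
    p = _subtype_probs(z_sub, strength)
    e_sub = p @ u
    var_sub = p @ (u**2) - e_sub**2
    gv = e_sub + c_p * strength * _KAPPA_PROLIF * z_pro
    mean_cond_var = float(np.mean(var_sub) + (c_p * _PROLIF_NOISE_SD) ** 2)
    return gv, mean_cond_var


def _genetic_r2(z_sub: np.ndarray, z_pro: np.ndarray, strength: float) -> float:
    gv, cond_var = _latent_moments(z_sub, z_pro, strength)
    v = float(np.var(gv))
    return v / (v + cond_var)


def simulate_tumor_state(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    population: Population | None = None,
) -> GroundTruth:
    """Sample true subtype, proliferation and the latent ROR-P per tumor.

    The single genetic-strength multiplier is solved (Brent root-finding on
    the closed-form variance decomposition) so that the fraction of latent
    ROR-P variance attributable to genotype equals
    ``config.genetic_variance_fraction``. When ``population`` supplies
    previously calibrated weights and strength they are reused.
    """
    rng = _rng(config.seed, _STREAM_TUMOR)
    n = genotypes.dosages.shape[0]
    n_snps = genotypes.dosages.shape[1]
    h2 = config.genetic_variance_fraction

    if population is not None:
        w_sub = population.subtype_weights
        w_pro = population.prolif_weights
    else:
        n_causal = config.n_causal_subtype + config.n_causal_prolif
        if n_causal == 0 and h2 > 0:
            raise ConfigurationError(
                "genetic_variance_fraction > 0 requires at least one causal SNP"
            )
        causal = rng.choice(n_snps, n_causal, replace=False) if n_causal else np.array([], int)
        w_sub = np.zeros(n_snps)
        w_pro = np.zeros(n_snps)
        w_sub[causal[: config.n_causal_subtype]] = rng.normal(
            0, 1, config.n_causal_subtype
        )
        w_pro[causal[config.n_causal_subtype :]] = rng.normal(0, 1, config.n_causal_prolif)

    x = np.nan_to_num(genotypes.dosages.to_numpy(dtype=float))
    p_hat = x.mean(axis=0) / 2.0
    sd = np.sqrt(np.maximum(2 * p_hat * (1 - p_hat), 1e-12))
    xs = (x - 2 * p_hat) / sd
    z_sub = _standardize(xs @ w_sub) if w_sub.any() else np.zeros(n)
    z_pro = _standardize(xs @ w_pro) if w_pro.any() else np.zeros(n)

    if population is not None and population.strength is not None:
        strength = population.strength
    elif h2 == 0:
        strength = 0.0
    else:
        hi = 1.0
        while _genetic_r2(z_sub, z_pro, hi) < h2:
            hi *= 2
            if hi > 1e4:
                raise ConfigurationError(
                    f"genetic_variance_fraction={h2} unreachable with this architecture"
                )
        strength = brentq(lambda t: _genetic_r2(z_sub, z_pro, t) - h2, 0.0, hi, xtol=1e-10)

    base, direction, prolif_mean, coeff = _subtype_arrays()
    probs = _subtype_probs(z_sub, strength)
    u = rng.random(n)
    cum = probs.cumsum(axis=1)
    subtype_idx = (u[:, None] > cum).sum(axis=1)
    c_p = RORP_COEFFICIENTS["Prolif"]
    prolif = (
        prolif_mean[subtype_idx]
        + strength * _KAPPA_PROLIF * z_pro
        + rng.normal(0, _PROLIF_NOISE_SD, n)
    )
    latent = coeff[subtype_idx] + c_p * prolif
    gv, _ = _latent_moments(z_sub, z_pro, strength)

    pcs = rng.normal(0, 1, (n, 10))
    if config.pc_rorp_effect:
        latent = latent + config.pc_rorp_effect * pcs[:, 0]

    # ER-positive probability conditional on subtype, shifted on the logit
    # scale so the marginal matches er_positive_fraction
    er_base = np.array([ER_POS_GIVEN_SUBTYPE[k] for k in SUBTYPE_LABELS])
    if population is not None and population.er_offset is not None:
        offset = population.er_offset
    else:
        marginal = probs.mean(axis=0)

        def _er_gap(d: float) -> float:
            return float(marginal @ expit(logit(er_base) + d)) - config.er_positive_fraction

        offset = brentq(_er_gap, -12.0, 12.0)
    er = (rng.random(n) < expit(logit(er_base) + offset)[subtype_idx]).astype(int)
    her2_base = np.array([HER2_POS_GIVEN_SUBTYPE[k] for k in SUBTYPE_LABELS])
    her2 = (rng.random(n) < her2_base[subtype_idx]).astype(int)
    # cumulative-logit grade driven by proliferation (higher prolif -> higher grade)
    p_le1 = expit(-0.8 - 1.0 * prolif)
    p_le2 = expit(0.9 - 1.0 * prolif)
    ug = rng.random(n)
    grade = np.where(ug < p_le1, 1, np.where(ug < p_le2, 2, 3))
    study = rng.integers(0, config.n_studies, n)

    samples = pd.DataFrame(
        {
            "subtype_true": np.array(SUBTYPE_LABELS)[subtype_idx],
            "prolif_true": prolif,
            "latent_rorp": latent,
            "genetic_value": gv,
            "er_status": er,
            "her2_status": her2,
            "grade": grade,
            "study": [f"study{int(s)}" for s in study],
        },
        index=genotypes.samples,
    )
    for i in range(10):
        samples[f"PC{i + 1}"] = pcs[:, i]

    pop = Population(
        snp_info=genotypes.snp_info.copy(),
        subtype_weights=w_sub,
        prolif_weights=w_pro,
        strength=strength,
        er_offset=offset,
    )
    effects = pd.DataFrame(
        {
            "subtype_weight": strength * _KAPPA_SUBTYPE * w_sub / np.where(sd > 0, sd, 1.0),
            "prolif_weight": strength * _KAPPA_PROLIF * w_pro / np.where(sd > 0, sd, 1.0),
        },
        index=genotypes.snps,
    )
    return GroundTruth(
        samples=samples,
        snp_effects=effects,
        population=pop,
        target_r2=h2,
        population_r2=_genetic_r2(z_sub, z_pro, strength),
    )


def synthetic_centroids(
    n_genes: int = 50, n_prolif_genes: int = 11, seed: int = 17, scale: float = 1.0
) -> Centroids:
    """A seeded synthetic centroid matrix: 5 subtype profiles over ``n_genes`` genes.

    Subtype-discriminating genes get independent standard-normal centroid
    values; the proliferation subset (the last ``n_prolif_genes`` genes) gets
    near-flat centroids so those genes track proliferation rather than
    subtype, mirroring how the proliferation index reads on real signatures.
    Synthetic stand-in: not the published centroid values.
    """
    rng = np.random.default_rng([99, seed])
    genes = [f"g{i + 1:03d}" for i in range(n_genes)]
    vals = rng.normal(0, scale, (n_genes, 5))
    vals[n_genes - n_prolif_genes :] = rng.normal(0, 0.2 * scale, (n_prolif_genes, 5))
    df = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=list(SUBTYPE_LABELS))
    return Centroids(values=df, proliferation_genes=genes[n_genes - n_prolif_genes :])


def simulate_expression(
    truth: GroundTruth, centroids: Centroids, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Expression = true-subtype centroid + noise (+ prolif shift, study shift, probes).

    Returns ``(matrix, probe_map)`` where ``probe_map`` is None when
    ``probe_multiplicity == 1`` (gene-level output).
    """
    if centroids.values.shape[0] < config.n_genes:
        raise ConfigurationError(
            f"centroid matrix covers {centroids.values.shape[0]} genes; "
            f"config requests {config.n_genes}"
        )
    rng = _rng(config.seed, _STREAM_EXPR)
    genes = list(centroids.genes[: config.n_genes])
    cent = centroids.values.loc[genes].to_numpy()
    sub_idx = pd.Categorical(
        truth.samples["subtype_true"], categories=list(SUBTYPE_LABELS)
    ).codes
    n = len(truth.samples)
    vals = cent[:, sub_idx].T + rng.normal(0, config.expression_noise_sd, (n, len(genes)))
    prolif_cols = [genes.index(g) for g in centroids.proliferation_genes if g in genes]
    vals[:, prolif_cols] += truth.samples["prolif_true"].to_numpy()[:, None]
    if config.study_shift_sd > 0 and config.n_studies > 1:
        shifts = rng.normal(0, config.study_shift_sd, (config.n_studies, len(genes)))
        study_idx = (
            truth.samples["study"].str.removeprefix("study").astype(int).to_numpy()
        )
        vals += shifts[study_idx]
    expr = pd.DataFrame(vals, index=truth.samples.index, columns=genes)
    if config.probe_multiplicity == 1:
        return expr, None
    cols, rows = {}, []
    for g in genes:
        n_probes = int(rng.integers(1, config.probe_multiplicity + 1))
        for p in range(n_probes):
            pid = f"{g}_p{p + 1}"
            cols[pid] = expr[g].to_numpy() + rng.normal(0, config.probe_noise_sd, n)
            rows.append({"probe": pid, "gene": g})
    return pd.DataFrame(cols, index=expr.index), pd.DataFrame(rows)


def simulate_outcomes(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Survival records with hazard log-linear in standardized latent ROR-P.

    Event times are exponential with rate
    ``baseline_hazard * exp(ln(hr_per_sd) * z)`` where ``z`` is the latent
    ROR-P standardized over the cohort; administrative censoring applies at
    ``admin_censor_time`` years. Clinical covariates carry simple
    dependencies: stage increases mildly with latent ROR-P, treatments
    depend on stage/receptor status, grade and receptor status come from the
    tumor-state stage.
    """
    rng = _rng(config.seed, _STREAM_OUTCOME)
    s = truth.samples
    n = len(s)
    z = _standardize(s["latent_rorp"].to_numpy())
    rate = config.baseline_hazard * np.exp(np.log(config.hr_per_sd) * z)
    t_event = rng.exponential(1.0 / rate)
    event = (t_event <= config.admin_censor_time).astype(int)
    time = np.minimum(t_event, config.admin_censor_time)
    # guard against exact zeros from floating underflow
    time = np.maximum(time, 1e-9)

    age = rng.normal(60, 10, n).clip(25, 90)
    bmi = rng.normal(27, 5, n).clip(15, 55)
    # stage 1-4, cumulative logit mildly increasing in latent ROR-P
    cut = np.array([0.3, 1.9, 3.2])
    p_le = expit(cut[None, :] - 0.3 * z[:, None])
    ustg = rng.random(n)
    stage = 1 + (ustg[:, None] > p_le).sum(axis=1)
    er = s["er_status"].to_numpy()
    her2 = s["her2_status"].to_numpy()
    grade = s["grade"].to_numpy()
    chemo = (rng.random(n) < expit(-1.0 + 0.8 * (stage - 1) + 0.8 * (1 - er))).astype(int)
    radiation = (rng.random(n) < 0.6).astype(int)
    trastuzumab = (rng.random(n) < np.where(her2 == 1, 0.8, 0.02)).astype(int)
    hormone = (rng.random(n) < np.where(er == 1, 0.85, 0.05)).astype(int)

    lum = er == 1
    intrinsic_like = np.where(
        lum & (her2 == 0) & (grade <= 2),
        "LumA",
        np.where(
            lum,
            "LumB",
            np.where(her2 == 1, "HER2-enriched", "Basal"),
        ),
    )
    out = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": age,
            "bmi": bmi,
            "stage": stage,
            "radiation": radiation,
            "chemotherapy": chemo,
            "trastuzumab": trastuzumab,
            "hormone_therapy": hormone,
            "er_status": er,
            "her2_status": her2,
            "grade": grade,
            "intrinsic_like": intrinsic_like,
            "study": s["study"].to_numpy(),
        },
        index=s.index,
    )
    for i in range(10):
        out[f"PC{i + 1}"] = s[f"PC{i + 1}"].to_numpy()
    return out


def inject_missingness(
    genotypes: GenotypeMatrix, missing_rate: float, seed: int | None = None
) -> GenotypeMatrix:
    """Mask dosage entries i.i.d. at ``missing_rate``; deterministic given seed."""
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if missing_rate == 0:
        return GenotypeMatrix(genotypes.dosages.copy(), genotypes.snp_info.copy())
    rng = _rng(seed, _STREAM_MISS)
    mask = rng.random(genotypes.dosages.shape) < missing_rate
    dosages = genotypes.dosages.mask(mask)
    return GenotypeMatrix(dosages=dosages, snp_info=genotypes.snp_info.copy())


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated cohort produces."""

    config: SimulationConfig
    genotypes: GenotypeMatrix          # post-missingness, as consumed downstream
    genotypes_complete: GenotypeMatrix # pre-missingness ground truth
    truth: GroundTruth
    centroids: Centroids
    expression: pd.DataFrame
    probe_map: pd.DataFrame | None
    clinical: pd.DataFrame
    ld: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_cohort(
    config: SimulationConfig,
    population: Population | None = None,
    centroids: Centroids | None = None,
) -> SyntheticCohort:
    """Run every generator stage in order and bundle the results."""
    geno = simulate_genotypes(config, population)
    truth = simulate_tumor_state(geno, config, population)
    cents = centroids or synthetic_centroids(config.n_genes, config.n_prolif_genes)
    expr, probe_map = simulate_expression(truth, cents, config)
    clinical = simulate_outcomes(truth, config)
    missing = inject_missingness(geno, config.missing_rate, config.seed)
    return SyntheticCohort(
        config=config,
        genotypes=missing,
        genotypes_complete=geno,
        truth=truth,
        centroids=cents,
        expression=expr,
        probe_map=probe_map,
        clinical=clinical,
        ld=ld_table(geno),
    )


def simulate_summary_stats(
    population: Population, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Case-case GWAS summary statistics coherent with the simulated architecture.

    SNPs pushing tumors along the aggressiveness axis raise ER-negative
    relative to ER-positive risk, so ``beta_er_neg - beta_er_pos`` is
    proportional to the subtype weight (plus estimation noise). Frequencies
    are the population MAFs; published p-values are carried over.
    """
    rng = _rng(seed if seed is not None else config.seed, 7)
    info = population.snp_info
    n = len(info)
    contrast = 0.25 * population.subtype_weights[:n] if len(population.subtype_weights) >= n else np.zeros(n)
    noise = rng.normal(0, 0.02, (n, 2))
    beta_neg = 0.05 + contrast / 2 + noise[:, 0]
    beta_pos = 0.05 - contrast / 2 + noise[:, 1]
    return pd.DataFrame(
        {
            "snp": info.index,
            "effect_allele": info["effect_allele"].to_numpy(),
            "beta_er_neg": beta_neg,
            "beta_er_pos": beta_pos,
            "freq": info["maf_true"].to_numpy(),
            "pub_p": info["pub_p"].to_numpy(),
        }
    )
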