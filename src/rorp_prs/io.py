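"""Reading and writing the external table formats, with strict validation.

All tables are TSV with a header row; floats are written at 17 significant
digits so write-then-read round-trips are lossless at double precision.
Genotypes additionally round-trip through a minimal VCF 4.2 with per-sample
GT fields; dosage orientation is always resolved against the effect-allele
column of the governing candidate/weight table, never the VCF REF.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import GenotypeMatrix

_FLOAT_FMT = "%.17g"

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(
    path: str | Path,
    required: list[str],
    numeric: list[str] | None = None,
    id_col: str | None = None,
) -> pd.DataFrame:
    """Read a TSV, check required columns, coerce numeric ones, check id uniqueness."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    for c in numeric or []:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.upper() != "NA")
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise InputError(f"{path}: non-numeric values in column {c!r}, rows {rows}")
        n_na = int(coerced.isna().sum())
        if n_na:
            warnings.warn(f"{path}: {n_na} missing values in column {c!r}", stacklevel=2)
        df[c] = coerced
    if id_col is not None:
        dup = df[id_col][df[id_col].duplicated()]
        if len(dup):
            raise InputError(f"{path}: duplicate {id_col} values: {dup.tolist()[:5]}")
    return df


# ---------------------------------------------------------------- genotypes


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: rows = samples, columns = SNPs; missing written as NA."""
    gm.dosages.to_csv(path, sep="\t", index_label="sample", float_format="%g", na_rep="NA")


def write_snp_info_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    gm.snp_info.to_csv(path, sep="\t", index_label="snp", float_format=_FLOAT_FMT)


def read_genotypes_tsv(
    path: str | Path, snp_info_path: str | Path | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample", na_values=["NA"]).astype(float)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise InputError(f"{path}: duplicate sample ids {dups[:5]}")
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        raise InputError(f"{path}: dosages must be in {{0, 1, 2}} or missing")
    if snp_info_path is not None:
        info = pd.read_csv(snp_info_path, sep="\t", index_col="snp")
        info = info.loc[[s for s in df.columns if s in info.index]]
    else:
        info = pd.DataFrame(
            {"effect_allele": pd.NA, "other_allele": pd.NA, "maf_true": np.nan, "pub_p": np.nan},
            index=pd.Index(df.columns, name="snp"),
        )
    return GenotypeMatrix(dosages=df, snp_info=info)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2: ALT = effect allele, GT encodes the effect-allele count."""
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        samples = "\t".join(gm.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for pos, snp in enumerate(gm.snps, start=1):
            info = gm.snp_info.loc[snp]
            col = gm.dosages[snp]
            gts = "\t".join(
                "./." if np.isnan(v) else gt_codes[float(v)] for v in col.to_numpy()
            )
            fh.write(
                f"1\t{pos}\t{snp}\t{info['other_allele']}\t{info['effect_allele']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | Path, effect_alleles: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read genotypes from a VCF; orient dosages to the governing effect allele.

    ``effect_alleles`` maps snp id -> effect allele (columns ``snp`` and one
    of ``effect_allele``/``risk_allele``). Per SNP: if the effect allele is
    the ALT, the dosage is the ALT count; if it is the REF, dosages are
    flipped (2 - count) and the flip is logged; A/T and C/G SNPs are flagged
    strand-ambiguous; an effect allele matching neither REF nor ALT drops
    the SNP with a reason. Without a table, ALT is taken as the effect
    allele. Returns the matrix and a per-SNP orientation report.
    """
    from cyvcf2 import VCF

    allele_map = {}
    if effect_alleles is not None:
        col = "effect_allele" if "effect_allele" in effect_alleles.columns else "risk_allele"
        allele_map = dict(zip(effect_alleles["snp"], effect_alleles[col]))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    info_rows, report_rows = [], []
    for var in vcf:
        snp = var.ID
        ref, alt = var.REF, var.ALT[0] if var.ALT else None
        if alt is None:
            report_rows.append({"snp": snp, "status": "dropped", "reason": "no ALT allele"})
            continue
        gts = np.array(var.genotypes, dtype=object)
        counts = np.array(
            [np.nan if g[0] == -1 else float(g[0] + g[1]) for g in gts], dtype=float
        )
        effect = allele_map.get(snp, alt)
        ambiguous = frozenset((ref, alt)) in _AMBIGUOUS_PAIRS
        if effect == alt:
            dosage, status = counts, "kept"
        elif effect == ref:
            dosage, status = 2.0 - counts, "flipped"
        else:
            report_rows.append(
                {"snp": snp, "status": "dropped", "reason": f"effect allele {effect} matches neither {ref} nor {alt}"}
            )
            continue
        other = ref if effect == alt else alt
        if ambiguous:
            report_rows.append(
                {"snp": snp, "status": status, "reason": "strand-ambiguous (A/T or C/G)"}
            )
        else:
            report_rows.append({"snp": snp, "status": status, "reason": ""})
        cols[snp] = dosage
        info_rows.append(
            {"snp": snp, "effect_allele": effect, "other_allele": other,
             "maf_true": np.nan, "pub_p": np.nan}
        )
    report = pd.DataFrame(report_rows, columns=["snp", "status", "reason"])
    n_flip = int((report["status"] == "flipped").sum())
    if n_flip:
        warnings.warn(f"{n_flip} SNPs flipped to effect-allele orientation", stacklevel=2)
    if not cols:
        raise InputError(f"{path}: no usable variants")
    gm = GenotypeMatrix(
        dosages=pd.DataFrame(cols, index=pd.Index(samples, name="sample")),
        snp_info=pd.DataFrame(info_rows).set_index("snp"),
    )
    return gm, report


# ---------------------------------------------------------------- other tables


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample", na_values=["NA"], float_precision="round_trip")
    if df.index.duplicated().any():
        raise InputError(f"{path}: duplicate sample ids")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="sample", float_format=_FLOAT_FMT)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = read_table(
        path,
        required=["sample", "time", "event"],
        numeric=["time", "event"],
        id_col="sample",
    )
    return df.set_index("sample")


def read_candidates_tsv(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=["snp", "pub_p"], numeric=["pub_p"], id_col="snp")
    if ((df["pub_p"] <= 0) | (df["pub_p"] > 1)).any():
        raise InputError(f"{path}: published p-values must lie in (0, 1]")
    return df


def read_ld_tsv(path: str | Path) -> pd.DataFrame:
    """LD table; accepts PLINK --r2 column naming (SNP_A, SNP_B, R2)."""
    df = pd.read_csv(path, sep="\t")
    renames = {"SNP_A": "snp_a", "SNP_B": "snp_b", "R2": "r2"}
    df = df.rename(columns=renames)
    missing = [c for c in ("snp_a", "snp_b", "r2") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing LD columns {missing}")
    return df[["snp_a", "snp_b", "r2"]]


def read_weights_tsv(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=["snp", "beta"], numeric=["beta"], id_col="snp")


def read_lr_weights_tsv(path: str | Path) -> pd.DataFrame:
    return read_table(
        path,
        required=["snp", "effect_allele", "or", "freq", "lr0", "lr1", "lr2"],
        numeric=["or", "freq", "lr0", "lr1", "lr2"],
        id_col="snp",
    )


def read_summary_stats_tsv(path: str | Path) -> pd.DataFrame:
    return read_table(
        path,
        required=["snp", "effect_allele", "beta_er_neg", "beta_er_pos", "freq", "pub_p"],
        numeric=["beta_er_neg", "beta_er_pos", "freq", "pub_p"],
        id_col="snp",
    )
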