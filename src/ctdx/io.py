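"""Table schemas and readers/writers.

Tab-separated tables with fixed headers are the canonical exchange format:
a cohort table (one row per patient) and a long variants table (one row per
variant per plasma sample).  A minimal single-sample VCF can be mapped into
variant records as a convenience.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "COHORT_REQUIRED",
    "VARIANTS_REQUIRED",
    "read_cohort",
    "read_variants",
    "write_cohort",
    "write_variants",
    "read_vcf_variants",
]

COHORT_REQUIRED = (
    "patient_id", "pfs_months", "progressed", "recist_first",
    "btmb", "cfdna_baseline_ng_ml", "cfdna_on_ng_ml", "day_on_treatment",
)
VARIANTS_REQUIRED = (
    "patient_id", "timepoint", "gene", "variant_id", "vaf", "functional_class",
)
RECIST_VOCAB = {"CR", "PR", "SD", "PD", "NA"}
TIMEPOINTS = {"baseline", "on_treatment"}

_COHORT_NUMERIC = ("pfs_months", "btmb", "cfdna_baseline_ng_ml", "cfdna_on_ng_ml")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _lines(df: pd.DataFrame, mask) -> list[int]:
    # +2: header line plus 1-based numbering
    return [int(i) + 2 for i in np.nonzero(np.asarray(mask))[0]]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table (TSV, one row per patient)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "recist_first": str})
    _require_columns(df, COHORT_REQUIRED, path)
    dup = df["patient_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(f"{path}: duplicate patient_id on lines {_lines(df, dup)}")
    for col in _COHORT_NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(f"{path}: unparsable {col} on lines {_lines(df, bad)}")
        df[col] = vals
    bad = ~(df["pfs_months"] > 0)
    if bad.any():
        raise ValidationError(f"{path}: pfs_months must be > 0 on lines {_lines(df, bad)}")
    recist = df["recist_first"].fillna("NA")
    bad = ~recist.isin(RECIST_VOCAB)
    if bad.any():
        raise ValidationError(
            f"{path}: recist_first outside {sorted(RECIST_VOCAB)} on lines {_lines(df, bad)}"
        )
    df["recist_first"] = recist
    df["progressed"] = df["progressed"].astype(int)
    return df


def read_variants(path) -> pd.DataFrame:
    """Read and validate a long variants table (TSV, one row per variant per
    sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, VARIANTS_REQUIRED, path)
    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    bad = vaf.isna() | (vaf < 0) | (vaf > 1)
    if bad.any():
        raise ValidationError(f"{path}: vaf outside [0, 1] on lines {_lines(df, bad)}")
    df["vaf"] = vaf
    bad = ~df["timepoint"].isin(TIMEPOINTS)
    if bad.any():
        raise ValidationError(f"{path}: unknown timepoint on lines {_lines(df, bad)}")
    dup = df.duplicated(subset=["patient_id", "timepoint", "variant_id"], keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (patient_id, timepoint, variant_id) on lines {_lines(df, dup)}"
        )
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_vcf_variants(path, patient_id: str, timepoint: str) -> pd.DataFrame:
    """Map a minimal single-sample VCF into variants-table rows.

    The allele fraction is taken from FORMAT/AF when present, else INFO/AF;
    the gene symbol from INFO/GENE when present, else ".".  All records are
    treated as nonsynonymous unless INFO/CLASS says otherwise.
    """
    import pysam

    if timepoint not in TIMEPOINTS:
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            af = None
            if rec.samples and "AF" in rec.format:
                v = rec.samples[0]["AF"]
                af = float(v[0] if isinstance(v, tuple) else v)
            elif "AF" in rec.info:
                v = rec.info["AF"]
                af = float(v[0] if isinstance(v, tuple) else v)
            if af is None:
                raise ValidationError(f"{path}: record {rec.chrom}:{rec.pos} has no AF field")
            if not (0.0 <= af <= 1.0):
                raise ValidationError(f"{path}: AF outside [0, 1] at {rec.chrom}:{rec.pos}")
            gene = rec.info["GENE"] if "GENE" in rec.info else "."
            fclass = rec.info["CLASS"] if "CLASS" in rec.info else "nonsynonymous"
            alt = rec.alts[0] if rec.alts else "."
            rows.append({
                "patient_id": patient_id,
                "timepoint": timepoint,
                "gene": gene,
                "variant_id": f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}",
                "vaf": af,
                "functional_class": fclass,
            })
    return pd.DataFrame(rows, columns=list(VARIANTS_REQUIRED))
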