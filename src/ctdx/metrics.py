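"""Liquid-biopsy statistics: ctDNA concentration, bTMB, ΔctDNA, ΔVAF,
molecular response and dynamics categories.

The ctDNA concentration of a plasma sample is expressed in haploid genome
equivalents per millilitre (hGE/mL):

    conc = maxVAF × cfDNA[pg/mL] / 3.3 pg

where maxVAF is the maximal variant allele frequency among detected somatic
variants and 3.3 pg is the mass of one haploid genome.  ΔctDNA is the
on-treatment concentration divided by the baseline concentration, with the
cohort limit of detection substituted for an undetectable baseline.  Blood
tumor mutational burden (bTMB) is the count of nonsynonymous variants per
megabase of panel, and normalized bTMB divides it by the baseline ctDNA
concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import MetricsConfig
from .errors import ConfigError, ValidationError

__all__ = [
    "VariantCall",
    "PlasmaSample",
    "CtdnaMetrics",
    "ctdna_concentration",
    "compute_btmb",
    "delta_ctdna",
    "delta_vaf",
    "normalized_btmb",
    "classify_molecular_response",
    "classify_dynamics",
    "cohort_lod",
    "compute_cohort_metrics",
    "PERSISTENTLY_NEGATIVE",
    "DECREASED",
    "INCREASED",
]

logger = logging.getLogger(__name__)

PERSISTENTLY_NEGATIVE = "persistently_negative"
DECREASED = "decreased"
INCREASED = "increased"

FUNCTIONAL_CLASSES = ("nonsynonymous", "synonymous", "other")


@dataclass
class VariantCall:
    """One somatic variant observed in one plasma sample."""

    gene: str
    vaf: float
    functional_class: str = "nonsynonymous"
    variant_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"VAF must be in [0, 1], got {self.vaf!r} for {self.gene}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(
                f"functional_class must be one of {FUNCTIONAL_CLASSES}, got {self.functional_class!r}"
            )


@dataclass
class PlasmaSample:
    """One timepoint's cfDNA measurement and its detected variants."""

    sample_id: str
    timepoint: Literal["baseline", "on_treatment"]
    cfdna_ng_per_ml: float
    variants: list[VariantCall] = field(default_factory=list)
    day_from_start: int = 0

    def __post_init__(self) -> None:
        if self.timepoint not in ("baseline", "on_treatment"):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.cfdna_ng_per_ml < 0:
            raise ValidationError(f"cfdna_ng_per_ml must be >= 0, got {self.cfdna_ng_per_ml}")
        if self.day_from_start < 0:
            raise ValidationError("day_from_start must be >= 0")
        if self.timepoint == "baseline" and self.day_from_start != 0:
            raise ValidationError("baseline samples must have day_from_start == 0")

    @property
    def detected(self) -> bool:
        return len(self.variants) > 0

    @property
    def max_vaf(self) -> float:
        return max((v.vaf for v in self.variants), default=0.0)


@dataclass
class CtdnaMetrics:
    """Derived per-patient liquid-biopsy metrics."""

    conc_baseline: float
    conc_on: float
    delta_ctdna: float
    delta_vaf: float          # NaN when the baseline VAF is 0
    btmb: float
    normalized_btmb: float
    dynamics: str
    molecular_responder: bool
    lod_used: bool


def ctdna_concentration(sample: PlasmaSample, config: MetricsConfig | None = None) -> float:
    """ctDNA concentration of one plasma sample in hGE/mL.

    Returns 0 for a sample with no detected variants (undetectable ctDNA).
    """
    config = config or MetricsConfig()
    if not sample.detected:
        return 0.0
    cfdna_pg_per_ml = sample.cfdna_ng_per_ml * 1000.0
    return sample.max_vaf * cfdna_pg_per_ml / config.hge_pg


def compute_btmb(variants: Iterable[VariantCall], config: MetricsConfig | None = None) -> float:
    """Blood tumor mutational burden: nonsynonymous variants per megabase."""
    config = config or MetricsConfig()
    n = sum(1 for v in variants if v.functional_class == "nonsynonymous")
    return n / config.panel_mb


def delta_ctdna(
    conc_baseline: float,
    detected_baseline: bool,
    conc_on: float,
    detected_on: bool,
    config: MetricsConfig | None = None,
    lod: float | None = None,
) -> tuple[float, bool, str | None]:
    """ΔctDNA: on-treatment over baseline concentration.

    The cohort limit of detection (LOD) replaces an undetectable baseline;
    an undetectable on-treatment sample counts as concentration 0.  Both
    undetectable gives Δ = 0 with a ``persistently_negative`` hint.

    Returns ``(delta, lod_used, dynamics_hint)``.
    """
    config = config or MetricsConfig()
    if conc_baseline < 0 or conc_on < 0:
        raise ValidationError("concentrations must be >= 0")
    if not detected_on:
        conc_on = 0.0
    if not detected_baseline:
        if not detected_on:
            return 0.0, False, PERSISTENTLY_NEGATIVE
        if lod is None:
            if config.lod_hge_per_ml == "auto":
                raise ConfigError(
                    "baseline undetected: an explicit LOD is required "
                    "(pass lod= or set MetricsConfig.lod_hge_per_ml)"
                )
            lod = float(config.lod_hge_per_ml)
        if lod <= 0:
            raise ConfigError("LOD must be positive")
        return conc_on / lod, True, None
    if conc_baseline == 0:
        raise ValidationError("detected baseline with zero concentration")
    return conc_on / conc_baseline, False, None


def delta_vaf(maxvaf_baseline: float, maxvaf_on: float) -> float:
    """ΔVAF: on-treatment over baseline maximal VAF; NaN when baseline is 0."""
    if maxvaf_baseline < 0 or maxvaf_on < 0:
        raise ValidationError("VAFs must be >= 0")
    if maxvaf_baseline == 0:
        logger.warning("delta_vaf undefined for zero baseline VAF; returning NaN")
        return float("nan")
    return maxvaf_on / maxvaf_baseline


def normalized_btmb(
    btmb: float,
    conc_baseline: float,
    config: MetricsConfig | None = None,
    detected_baseline: bool = True,
    lod: float | None = None,
) -> float:
    """ctDNA-normalized bTMB: bTMB over the baseline ctDNA concentration.

    The LOD substitutes for an undetectable baseline, as for ΔctDNA.
    """
    config = config or MetricsConfig()
    if not detected_baseline:
        if lod is None:
            if config.lod_hge_per_ml == "auto":
                raise ConfigError("baseline undetected: an explicit LOD is required")
            lod = float(config.lod_hge_per_ml)
        conc_baseline = lod
    if conc_baseline <= 0:
        raise ConfigError("baseline concentration (or LOD) must be positive")
    return btmb / conc_baseline


def classify_molecular_response(delta: float, config: MetricsConfig | None = None) -> bool:
    """Molecular responder iff ΔctDNA ≤ the response threshold (0.2 ≙ 80% drop)."""
    config = config or MetricsConfig()
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    return delta <= config.response_threshold


def classify_dynamics(
    detected_baseline: bool,
    detected_on: bool,
    delta: float,
    config: MetricsConfig | None = None,
) -> str:
    """Dynamics category: persistently negative, decreased (Δ < 1) or increased."""
    config = config or MetricsConfig()
    if not detected_baseline and not detected_on:
        return PERSISTENTLY_NEGATIVE
    return DECREASED if delta < config.decrease_threshold else INCREASED


def cohort_lod(
    baseline_concentrations: Sequence[float],
    config: MetricsConfig | None = None,
) -> float:
    """Cohort limit of detection used as the undetectable-baseline substitute.

    Default policy: the minimum positive baseline concentration across the
    cohort.  An explicit ``MetricsConfig.lod_hge_per_ml`` overrides the data.
    """
    config = config or MetricsConfig()
    if config.lod_hge_per_ml != "auto":
        return float(config.lod_hge_per_ml)
    pos = [c for c in baseline_concentrations if c > 0]
    if not pos:
        raise ValidationError(
            "no detected baseline samples in the cohort; set an explicit lod_hge_per_ml"
        )
    return min(pos)


def _max_vaf_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, timepoint) maximal VAF and detection flag."""
    g = variants.groupby(["patient_id", "timepoint"])["vaf"]
    out = g.max().unstack("timepoint")
    for tp in ("baseline", "on_treatment"):
        if tp not in out.columns:
            out[tp] = np.nan
    return out[["baseline", "on_treatment"]]


def compute_cohort_metrics(
    cohort: pd.DataFrame,
    variants: pd.DataFrame,
    config: MetricsConfig | None = None,
) -> pd.DataFrame:
    """Compute every per-patient metric for a whole cohort.

    Parameters
    ----------
    cohort:
        One row per patient with at least ``patient_id``,
        ``cfdna_baseline_ng_ml``, ``cfdna_on_ng_ml`` and ``btmb`` (when
        ``btmb`` is absent it is computed from the baseline nonsynonymous
        variant count).
    variants:
        Long table with ``patient_id``, ``timepoint``, ``gene``,
        ``variant_id``, ``vaf``, ``functional_class``; patients absent from
        it at a timepoint are treated as ctDNA-undetectable there.

    Returns a copy of ``cohort`` with columns ``conc_baseline``, ``conc_on``,
    ``delta_ctdna``, ``delta_vaf``, ``btmb``, ``normalized_btmb``,
    ``dynamics``, ``molecular_responder``, ``lod_used`` appended, plus the
    scalar cohort LOD in ``df.attrs["lod_hge_per_ml"]``.
    """
    config = config or MetricsConfig()
    if (variants["vaf"] < 0).any() or (variants["vaf"] > 1).any():
        raise ValidationError("variants table contains VAF outside [0, 1]")

    out = cohort.copy().set_index("patient_id", drop=False)
    mv = _max_vaf_table(variants).reindex(out.index)
    maxvaf_b = mv["baseline"].to_numpy(dtype=float)
    maxvaf_on = mv["on_treatment"].to_numpy(dtype=float)
    det_b = ~np.isnan(maxvaf_b)
    det_on = ~np.isnan(maxvaf_on)
    maxvaf_b = np.nan_to_num(maxvaf_b)
    maxvaf_on = np.nan_to_num(maxvaf_on)

    conc_b = maxvaf_b * out["cfdna_baseline_ng_ml"].to_numpy(dtype=float) * 1000.0 / config.hge_pg
    conc_on = maxvaf_on * out["cfdna_on_ng_ml"].to_numpy(dtype=float) * 1000.0 / config.hge_pg
    conc_b[~det_b] = 0.0
    conc_on[~det_on] = 0.0

    lod = cohort_lod(conc_b, config)

    eff_base = np.where(det_b, conc_b, lod)
    delta = np.where(det_on, conc_on, 0.0) / eff_base
    both_neg = ~det_b & ~det_on
    delta[both_neg] = 0.0
    lod_used = ~det_b & ~both_neg

    if "btmb" in out.columns:
        btmb = out["btmb"].to_numpy(dtype=float)
    else:
        nonsyn = (
            variants[(variants["timepoint"] == "baseline")
                     & (variants["functional_class"] == "nonsynonymous")]
            .groupby("patient_id").size().reindex(out.index).fillna(0)
        )
        btmb = nonsyn.to_numpy(dtype=float) / config.panel_mb
        out["btmb"] = btmb

    norm_btmb = btmb / eff_base

    with np.errstate(divide="ignore", invalid="ignore"):
        dvaf = np.where(maxvaf_b > 0, maxvaf_on / np.where(maxvaf_b > 0, maxvaf_b, 1.0), np.nan)

    dynamics = np.where(
        both_neg, PERSISTENTLY_NEGATIVE,
        np.where(delta < config.decrease_threshold, DECREASED, INCREASED),
    )
    responder = delta <= config.response_threshold
    if not config.negative_is_responder:
        responder = responder & ~both_neg

    out["conc_baseline"] = conc_b
    out["conc_on"] = conc_on
    out["delta_ctdna"] = delta
    out["delta_vaf"] = dvaf
    out["normalized_btmb"] = norm_btmb
    out["dynamics"] = dynamics
    out["molecular_responder"] = responder
    out["lod_used"] = lod_used
    out = out.reset_index(drop=True)
    out.attrs["lod_hge_per_ml"] = lod
    return out
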