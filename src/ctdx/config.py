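"""Configuration objects for the simulator, the metrics layer and the classifier.

All configs are plain frozen-ish dataclasses with an explicit ``validate()``
called on construction, so that a bad value fails loudly at the boundary and
names the offending field.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from typing import Literal, Mapping, Sequence

from .errors import ConfigError

__all__ = [
    "GeneratorConfig",
    "MetricsConfig",
    "FeatureSpec",
    "AnalysisConfig",
]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p!r}")


def _check_simplex(name: str, v: Sequence[float], k: int = 3) -> None:
    if len(v) != k:
        raise ConfigError(f"{name} must have {k} entries, got {len(v)}")
    for p in v:
        _check_prob(name, p)
    if abs(sum(v) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 (got {sum(v)})")


def _check_positive(name: str, x: float) -> None:
    if not (x > 0):
        raise ConfigError(f"{name} must be > 0, got {x!r}")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic immunotherapy cohort generator.

    Defaults encode the study conditions the generator emulates: a durable
    clinical benefit (DCB) prevalence of 67.5%, class-conditional ΔctDNA bin
    frequencies (83.9% of DCB patients at or below the 0.2-fold molecular
    response threshold, 63.0% of NDB patients at or above 1-fold), RECIST
    first-assessment rates (41.5% PR among DCB; no PD among DCB), and median
    progression-free survival of 13.6 months (DCB) vs 4.2 months (NDB) with a
    6-month benefit window.

    Parameters
    ----------
    n_patients:
        Cohort size.
    dcb_prevalence:
        Marginal probability of the latent DCB class.
    delta_bin_probs_dcb, delta_bin_probs_ndb:
        Class-conditional probabilities over the three ΔctDNA bins
        (0, 0.2], (0.2, 1) and [1, ∞), applied to patients that are not
        persistently ctDNA-negative.
    delta_bin_bounds:
        Four increasing positive bounds ``(lo, t_resp, t_incr, hi)`` used for
        the log-uniform within-bin draw; ``t_resp`` and ``t_incr`` are the
        molecular-response and increase cut-points (0.2 and 1 by default).
    persistently_negative_prob_dcb, persistently_negative_prob_ndb:
        Probability that a patient has no detectable ctDNA at either
        timepoint (ΔctDNA fixed at 0).
    recist_probs_dcb, recist_probs_ndb:
        Class-conditional probabilities over first RECIST response {PR, SD, PD}.
    pfs_median_dcb, pfs_median_ndb:
        Target median PFS per class, months.
    dcb_window:
        Months of progression-free survival required for the DCB label.
    censor_prob:
        Expected fraction of DCB patients administratively censored; censoring
        times are drawn from an independent shifted exponential so the
        Kaplan-Meier estimate of the event distribution stays consistent.
    btmb_logmean_*, btmb_logsd_*:
        Log-normal parameters of blood tumor mutational burden (mutations/Mb)
        per class; DCB is centred higher.
    cfdna_logmean, cfdna_logsd:
        Log-normal parameters of plasma cfDNA concentration (ng/mL), shared
        across classes and timepoints.
    maxvaf_logmean_*, maxvaf_logsd_*:
        Log-normal parameters of the baseline maximal variant allele
        frequency per class; DCB is centred lower (lower tumor burden).
    n_variants_mean:
        Poisson mean of the baseline variant count (truncated to >= 1 for
        ctDNA-positive patients).
    sample_day_logmean, sample_day_logsd:
        Log-normal parameters of the on-treatment sampling day; calibrated to
        a median of 26 days, with a floor of 14 days.
    seed:
        Seed for the single generator every draw flows from.
    """

    n_patients: int = 100
    dcb_prevalence: float = 0.675
    delta_bin_probs_dcb: tuple[float, float, float] = (0.839, 0.054, 0.107)
    delta_bin_probs_ndb: tuple[float, float, float] = (0.296, 0.074, 0.630)
    delta_bin_bounds: tuple[float, float, float, float] = (1e-3, 0.2, 1.0, 10.0)
    persistently_negative_prob_dcb: float = 0.05
    persistently_negative_prob_ndb: float = 0.0
    recist_probs_dcb: tuple[float, float, float] = (0.415, 0.585, 0.0)
    recist_probs_ndb: tuple[float, float, float] = (0.136, 0.546, 0.318)
    pfs_median_dcb: float = 13.6
    pfs_median_ndb: float = 4.2
    dcb_window: float = 6.0
    censor_prob: float = 0.3
    btmb_logmean_dcb: float = math.log(8.0)
    btmb_logsd_dcb: float = 0.8
    btmb_logmean_ndb: float = math.log(4.0)
    btmb_logsd_ndb: float = 0.8
    cfdna_logmean: float = math.log(10.0)
    cfdna_logsd: float = 0.6
    maxvaf_logmean_dcb: float = math.log(0.02)
    maxvaf_logsd_dcb: float = 1.0
    maxvaf_logmean_ndb: float = math.log(0.05)
    maxvaf_logsd_ndb: float = 1.0
    n_variants_mean: float = 4.0
    sample_day_logmean: float = math.log(26.0)
    sample_day_logsd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.delta_bin_probs_dcb = tuple(self.delta_bin_probs_dcb)
        self.delta_bin_probs_ndb = tuple(self.delta_bin_probs_ndb)
        self.recist_probs_dcb = tuple(self.recist_probs_dcb)
        self.recist_probs_ndb = tuple(self.recist_probs_ndb)
        self.delta_bin_bounds = tuple(self.delta_bin_bounds)
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int,)) or self.n_patients < 0:
            raise ConfigError(f"n_patients must be a nonnegative integer, got {self.n_patients!r}")
        if self.n_patients == 0:
            raise ConfigError("n_patients must be >= 1")
        _check_prob("dcb_prevalence", self.dcb_prevalence)
        _check_simplex("delta_bin_probs_dcb", self.delta_bin_probs_dcb)
        _check_simplex("delta_bin_probs_ndb", self.delta_bin_probs_ndb)
        _check_simplex("recist_probs_dcb", self.recist_probs_dcb)
        _check_simplex("recist_probs_ndb", self.recist_probs_ndb)
        _check_prob("persistently_negative_prob_dcb", self.persistently_negative_prob_dcb)
        _check_prob("persistently_negative_prob_ndb", self.persistently_negative_prob_ndb)
        _check_prob("censor_prob", self.censor_prob)
        b = self.delta_bin_bounds
        if len(b) != 4 or not all(x > 0 for x in b) or not all(b[i] < b[i + 1] for i in range(3)):
            raise ConfigError(f"delta_bin_bounds must be 4 increasing positive values, got {b}")
        _check_positive("dcb_window", self.dcb_window)
        if self.pfs_median_dcb < self.dcb_window:
            raise ConfigError("pfs_median_dcb must be >= dcb_window")
        if not (0 < self.pfs_median_ndb < self.dcb_window):
            raise ConfigError("pfs_median_ndb must lie in (0, dcb_window)")
        for name in ("btmb_logsd_dcb", "btmb_logsd_ndb", "cfdna_logsd",
                     "maxvaf_logsd_dcb", "maxvaf_logsd_ndb", "sample_day_logsd"):
            _check_positive(name, getattr(self, name))
        _check_positive("n_variants_mean", self.n_variants_mean)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, m: Mapping) -> "GeneratorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(m) - known
        if unknown:
            raise ConfigError(f"unknown GeneratorConfig fields: {sorted(unknown)}")
        return cls(**m)


@dataclass
class MetricsConfig:
    """Constants and thresholds of the liquid-biopsy metrics.

    ``hge_pg`` is the mass of one haploid genome equivalent (3.3 pg), so a
    ctDNA concentration in hGE/mL is ``maxVAF × cfDNA[pg/mL] / hge_pg``.
    ``response_threshold`` is the ΔctDNA molecular-response cut-point (0.2,
    i.e. an 80% drop from baseline, boundary inclusive) and
    ``decrease_threshold`` the decreased/increased cut-point (1.0, with
    "decreased" strictly below).  ``lod_hge_per_ml`` is the baseline
    limit-of-detection substitute; ``"auto"`` means the cohort minimum
    positive baseline concentration.
    """

    hge_pg: float = 3.3
    panel_mb: float = 1.5
    response_threshold: float = 0.2
    decrease_threshold: float = 1.0
    lod_hge_per_ml: float | Literal["auto"] = "auto"
    normalized_btmb_cutoff: float = 0.0975
    btmb_cutoff: float = 6.720
    negative_is_responder: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_positive("hge_pg", self.hge_pg)
        _check_positive("panel_mb", self.panel_mb)
        if not (0 < self.response_threshold < self.decrease_threshold):
            raise ConfigError(
                "need 0 < response_threshold < decrease_threshold, got "
                f"{self.response_threshold} and {self.decrease_threshold}"
            )
        if self.lod_hge_per_ml != "auto":
            _check_positive("lod_hge_per_ml", float(self.lod_hge_per_ml))


#: Features the classifier knows how to build.
KNOWN_FEATURES = ("normalized_btmb", "delta_ctdna", "recist_responder")


@dataclass
class FeatureSpec:
    """Which features enter the logistic model and how they are transformed.

    Continuous ratio features (ΔctDNA, normalized bTMB) span orders of
    magnitude and contain exact zeros, so the default transform is
    ``log10(max(x, floor))``.  ``recist_responder`` is always the 0/1 coding
    of CR/PR at the first assessment.
    """

    features: tuple[str, ...] = ("normalized_btmb", "delta_ctdna", "recist_responder")
    transform: Literal["log10_floor", "identity"] = "log10_floor"
    floor: float = 1e-4
    standardize: bool = False

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.validate()

    def validate(self) -> None:
        for f in self.features:
            if f not in KNOWN_FEATURES:
                raise ConfigError(f"unknown feature {f!r}; known: {KNOWN_FEATURES}")
        if len(set(self.features)) != len(self.features):
            raise ConfigError("duplicate features in FeatureSpec")
        if not self.features:
            raise ConfigError("FeatureSpec.features must be nonempty")
        if self.transform not in ("log10_floor", "identity"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        if self.transform == "log10_floor":
            _check_positive("floor", self.floor)


@dataclass
class AnalysisConfig:
    """End-to-end pipeline options: metrics constants, model features,
    survival options and cross-validation settings."""

    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    dcb_window: float = 6.0
    minprop: float = 0.1
    tie_method: Literal["efron", "breslow"] = "efron"
    cv_folds: int = 5
    cv_repeats: int = 20
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.metrics.validate()
        self.feature_spec.validate()
        _check_positive("dcb_window", self.dcb_window)
        if not (0 < self.minprop < 0.5):
            raise ConfigError(f"minprop must lie in (0, 0.5), got {self.minprop}")
        if self.tie_method not in ("efron", "breslow"):
            raise ConfigError(f"unknown tie_method {self.tie_method!r}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ConfigError("cv_repeats must be >= 1")

    @classmethod
    def from_mapping(cls, m: Mapping) -> "AnalysisConfig":
        m = dict(m)
        metrics = MetricsConfig(**m.pop("metrics", {}))
        spec = FeatureSpec(**m.pop("feature_spec", {}))
        known = {f.name for f in fields(cls)} - {"metrics", "feature_spec"}
        unknown = set(m) - known
        if unknown:
            raise ConfigError(f"unknown AnalysisConfig fields: {sorted(unknown)}")
        return cls(metrics=metrics, feature_spec=spec, **m)
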