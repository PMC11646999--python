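"""End-to-end analysis: metrics → labels → cutpoints → models → CV →
optional external validation → score-stratified survival."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import metrics as mx
from . import survival as sv
from .config import AnalysisConfig, FeatureSpec
from .errors import ValidationError

__all__ = ["ReportBundle", "run_pipeline", "label_cohort"]

logger = logging.getLogger(__name__)

TWO_FEATURES = ("normalized_btmb", "delta_ctdna")
THREE_FEATURES = ("normalized_btmb", "delta_ctdna", "recist_responder")


def label_cohort(cohort: pd.DataFrame, window: float = 6.0) -> pd.Series:
    """DCB/NDB/indeterminate label for every row of a cohort table."""
    return pd.Series(
        [sv.dcb_label(t, bool(e), window)
         for t, e in zip(cohort["pfs_months"], cohort["progressed"])],
        index=cohort.index, name="dcb_label",
    )


@dataclass
class ReportBundle:
    """Everything the pipeline computed, plus a serializable summary."""

    metrics: pd.DataFrame
    labels: pd.Series
    cutpoints: dict
    model_2: clf.FittedModel
    model_3: clf.FittedModel | None
    cv_2: clf.CvReport
    cv_3: clf.CvReport | None
    strata: clf.ScoreStrata | None
    external: dict | None
    results: dict


def _op_dict(op: clf.OperatingPoint) -> dict:
    return {
        "threshold": op.threshold, "sensitivity": op.sensitivity,
        "specificity": op.specificity, "accuracy": op.accuracy,
        "youden_j": op.youden_j,
    }


def _model_summary(model: clf.FittedModel, cv: clf.CvReport | None) -> dict:
    d = {
        "features": list(model.feature_names),
        "coef": {"intercept": float(model.coef[0]),
                 **{n: float(c) for n, c in zip(model.feature_names, model.coef[1:])}},
        "auc": model.roc.auc if model.roc else None,
        "operating_point": _op_dict(model.operating_point) if model.operating_point else None,
    }
    if cv is not None:
        d["cv"] = {"mean_auc": cv.mean, "sd_auc": cv.sd, "k": cv.k, "repeats": cv.repeats}
    return d


def run_pipeline(
    config: AnalysisConfig,
    cohort: pd.DataFrame,
    variants: pd.DataFrame,
    external_cohort: pd.DataFrame | None = None,
    external_variants: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Run the full analysis on a validated cohort.

    Stages: liquid-biopsy metrics; 6-month benefit labeling; optimal
    survival cutpoints for bTMB and normalized bTMB; 2-feature and 3-feature
    logistic models with Youden operating points; repeated stratified CV;
    optional frozen-model external validation; survival stratified by the
    best model's score.  Every random step derives from ``config.seed``.
    """
    stage = "metrics"
    try:
        metrics = mx.compute_cohort_metrics(cohort, variants, config.metrics)
        stage = "labeling"
        labels = label_cohort(metrics, config.dcb_window)
        n_indet = int((labels == sv.INDETERMINATE).sum())
        if n_indet:
            logger.info("labeling: %d indeterminate patients excluded from classification", n_indet)
        if (labels == sv.INDETERMINATE).all():
            raise ValidationError("all patients are indeterminate (censored before the window)")

        stage = "cutpoints"
        t = metrics["pfs_months"].to_numpy(dtype=float)
        e = metrics["progressed"].to_numpy(dtype=bool)
        cutpoints = {}
        for feat in ("btmb", "normalized_btmb"):
            try:
                cp = sv.optimal_cutpoint(metrics[feat].to_numpy(dtype=float), t, e,
                                         minprop=config.minprop)
                cutpoints[feat] = {"cutpoint": cp.cutpoint, "statistic": cp.statistic,
                                   "n_low": cp.n_low, "n_high": cp.n_high}
            except ValidationError as err:
                logger.warning("cutpoint scan for %s failed: %s", feat, err)
                cutpoints[feat] = None

        stage = "model_2"
        spec2 = FeatureSpec(features=TWO_FEATURES,
                            transform=config.feature_spec.transform,
                            floor=config.feature_spec.floor,
                            standardize=config.feature_spec.standardize)
        X2, y2 = clf.build_features(metrics, labels, spec2)
        model_2 = clf.train_model(X2, y2, spec2)
        cv_2 = clf.repeated_cv(X2, y2, k=config.cv_folds, repeats=config.cv_repeats,
                               seed=config.seed, spec=spec2)

        stage = "model_3"
        spec3 = FeatureSpec(features=THREE_FEATURES,
                            transform=config.feature_spec.transform,
                            floor=config.feature_spec.floor,
                            standardize=config.feature_spec.standardize)
        model_3 = cv_3 = strata = None
        X3, y3 = clf.build_features(metrics, labels, spec3)
        if np.unique(y3).size == 2 and len(y3) > 4:
            model_3 = clf.train_model(X3, y3, spec3)
            cv_3 = clf.repeated_cv(X3, y3, k=config.cv_folds, repeats=config.cv_repeats,
                                   seed=config.seed + 1, spec=spec3)
            stage = "stratification"
            scores3 = clf.predict_scores(model_3, X3)
            sub = metrics.loc[X3.index]
            try:
                strata = clf.stratify_by_score(
                    scores3, model_3.operating_point.threshold,
                    sub["pfs_months"].to_numpy(dtype=float),
                    sub["progressed"].to_numpy(dtype=bool),
                )
            except ValidationError as err:
                logger.warning("score stratification skipped: %s", err)

        stage = "external_validation"
        external = None
        if external_cohort is not None:
            ext_metrics = mx.compute_cohort_metrics(
                external_cohort,
                external_variants if external_variants is not None
                else pd.DataFrame(columns=variants.columns),
                config.metrics,
            )
            ext_labels = label_cohort(ext_metrics, config.dcb_window)
            external = {}
            for name, model, spec in (("two_feature", model_2, spec2),
                                      ("three_feature", model_3, spec3)):
                if model is None:
                    continue
                Xe, ye = clf.build_features(ext_metrics, ext_labels, spec)
                op, roc = clf.external_validate(model, Xe, ye)
                external[name] = {"auc": roc.auc, "operating_point": _op_dict(op),
                                  "n": int(len(ye))}

        stage = "reporting"
        results = {
            "n_patients": int(len(cohort)),
            "n_indeterminate": n_indet,
            "n_dcb": int((labels == sv.DCB).sum()),
            "n_ndb": int((labels == sv.NDB).sum()),
            "lod_hge_per_ml": float(metrics.attrs["lod_hge_per_ml"]),
            "cutpoints": cutpoints,
            "two_feature_model": _model_summary(model_2, cv_2),
            "three_feature_model": _model_summary(model_3, cv_3) if model_3 else None,
            "score_strata": None if strata is None else {
                "n_high": strata.n_high, "n_low": strata.n_low,
                "logrank_p": strata.logrank.p_value,
                "hazard_ratio_high_vs_low": strata.hazard_ratio,
                "median_pfs_high": strata.km_high.median,
                "median_pfs_low": strata.km_low.median,
            },
            "external_validation": external,
            "seed": config.seed,
        }
    except ValidationError as err:
        raise ValidationError(f"[stage: {stage}] {err}") from err

    bundle = ReportBundle(metrics=metrics, labels=labels, cutpoints=cutpoints,
                          model_2=model_2, model_3=model_3, cv_2=cv_2, cv_3=cv_3,
                          strata=strata, external=external, results=results)
    if outdir is not None:
        _write_bundle(bundle, config, Path(outdir))
    return bundle


def _fmt(x) -> str:
    return "NA" if x is None else (f"{x:.3f}" if isinstance(x, float) else str(x))


def render_report(results: dict) -> str:
    """Human-readable markdown summary of a results dict."""
    lines = ["# ctDNA dynamics analysis report", ""]
    lines += [f"- patients: {results['n_patients']} "
              f"(DCB {results['n_dcb']}, NDB {results['n_ndb']}, "
              f"indeterminate {results['n_indeterminate']})",
              f"- cohort LOD: {results['lod_hge_per_ml']:.4g} hGE/mL", ""]
    lines += ["## Optimal survival cutpoints", ""]
    for feat, cp in results["cutpoints"].items():
        if cp is None:
            lines.append(f"- {feat}: no admissible cutpoint")
        else:
            lines.append(f"- {feat}: cutoff {cp['cutpoint']:.4g} "
                         f"(|z| = {cp['statistic']:.3f}, n {cp['n_low']}/{cp['n_high']})")
    for key, title in (("two_feature_model", "Two-feature model"),
                       ("three_feature_model", "Three-feature model")):
        m = results.get(key)
        if not m:
            continue
        op = m["operating_point"]
        lines += ["", f"## {title}", "",
                  f"- features: {', '.join(m['features'])}",
                  f"- training AUC: {_fmt(m['auc'])}",
                  f"- operating point: sensitivity {_fmt(op['sensitivity'])}, "
                  f"specificity {_fmt(op['specificity'])}, accuracy {_fmt(op['accuracy'])}"]
        if "cv" in m:
            lines.append(f"- repeated CV AUC: {m['cv']['mean_auc']:.3f} ± {m['cv']['sd_auc']:.3f} "
                         f"({m['cv']['repeats']}×{m['cv']['k']}-fold)")
    st = results.get("score_strata")
    if st:
        lines += ["", "## Score-stratified survival", "",
                  f"- median PFS high vs low score: {_fmt(st['median_pfs_high'])} vs "
                  f"{_fmt(st['median_pfs_low'])} months",
                  f"- log-rank p = {st['logrank_p']:.3g}; "
                  f"HR (high vs low) = {st['hazard_ratio_high_vs_low']:.3f}"]
    ext = results.get("external_validation")
    if ext:
        lines += ["", "## External validation", ""]
        for name, d in ext.items():
            op = d["operating_point"]
            lines.append(f"- {name}: AUC {_fmt(d['auc'])}, sensitivity {_fmt(op['sensitivity'])}, "
                         f"specificity {_fmt(op['specificity'])}, n = {d['n']}")
    return "\n".join(lines) + "\n"


def _write_bundle(bundle: ReportBundle, config: AnalysisConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    m = bundle.metrics.copy()
    m["dcb_label"] = bundle.labels
    m.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    (outdir / "model_two_feature.json").write_text(bundle.model_2.to_json())
    if bundle.model_3 is not None:
        (outdir / "model_three_feature.json").write_text(bundle.model_3.to_json())
    (outdir / "results.json").write_text(
        json.dumps(bundle.results, indent=2, sort_keys=True) + "\n")
    (outdir / "report.md").write_text(render_report(bundle.results))
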