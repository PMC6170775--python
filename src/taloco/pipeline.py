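"""End-to-end orchestration of the two analysis routes.

The biomechanical route runs stress fields through mesh-weighted
summaries, the Intervals' method and PERMANOVA, then a classifier
bench on the Box-Cox/centred/scaled interval features.  The
morphometric route runs landmarks through GPA, shape PCA with
broken-stick retention, the phylogenetic comparative tests (Kmult,
PGLS, PLS and phylogenetic PLS) and a classifier bench on the retained
PC scores.  Fossils are aligned jointly in the GPA but never enter any
model fit; their features are pushed through the training-time
transforms and scored by the best model of each route.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, fea, grouptests, intervals, phylo, shape
from .synthetic import Bundle

__all__ = ["RunConfig", "ExtantReport", "run_extant_analysis", "run_fossil_inference", "write_report"]

PERCENTILE_COLUMNS = ("M25", "M50", "M75", "M95")


@dataclass
class RunConfig:
    """Parameters for one pipeline run; the seed feeds every
    permutation test and resampling stream."""

    seed: int = 0
    route: str = "both"  # biomech | shape | both
    n_perm: int = 999
    qim_threshold_pct: float = 2.0
    n_intervals: int | None = 10  # None -> convergence procedure
    ft_upper: float | None = None  # None -> max-M95 rule
    interval_candidates: tuple[int, ...] = intervals.DEFAULT_CANDIDATE_NS
    cv: classify.CvSpec = field(default_factory=classify.CvSpec)
    model_families: tuple[str, ...] = classify.MODEL_FAMILIES

    def digest(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "route": self.route,
                "n_perm": self.n_perm,
                "qim_threshold_pct": self.qim_threshold_pct,
                "n_intervals": self.n_intervals,
                "ft_upper": self.ft_upper,
                "interval_candidates": list(self.interval_candidates),
                "cv": [self.cv.repeats, self.cv.train_fraction, self.cv.stratified, self.cv.seed],
                "model_families": list(self.model_families),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExtantReport:
    config: RunConfig
    stress_summaries: pd.DataFrame | None = None
    percentile_features: pd.DataFrame | None = None
    interval_features_raw: pd.DataFrame | None = None
    interval_features: intervals.FeatureMatrix | None = None
    ft_upper: float | None = None
    n_intervals: int | None = None
    permanova: grouptests.PermanovaResult | None = None
    pairwise_permanova: list[dict] | None = None
    normality: grouptests.MardiaResult | None = None
    aligned: shape.AlignedShapes | None = None
    pca: shape.ShapePCA | None = None
    extant_scores: np.ndarray | None = None
    fossil_scores: np.ndarray | None = None
    kmult_shape: phylo.KmultResult | None = None
    kmult_stress: phylo.KmultResult | None = None
    pgls_stress_volume: phylo.PglsResult | None = None
    pgls_shape_size: phylo.PglsResult | None = None
    pls: phylo.PlsResult | None = None
    phylo_pls: phylo.PlsResult | None = None
    classifier_reports: dict[str, dict[str, classify.ClassifierReport]] = field(default_factory=dict)
    best_models: dict[str, str] = field(default_factory=dict)
    extant_ids: list[str] = field(default_factory=list)
    fossil_ids: list[str] = field(default_factory=list)
    extant_labels: np.ndarray | None = None
    _biomech_fossil_features: np.ndarray | None = None


def _best_family(reports: dict[str, classify.ClassifierReport]) -> str:
    """Highest mean accuracy; ties broken by higher mean Kappa."""
    return max(
        reports, key=lambda name: (reports[name].accuracy_mean, reports[name].kappa_mean)
    )


def run_extant_analysis(bundle: Bundle, config: RunConfig | None = None) -> ExtantReport:
    config = config or RunConfig()
    report = ExtantReport(config=config)
    meta = bundle.metadata
    extant = meta[~meta["is_fossil"]]
    fossil = meta[meta["is_fossil"]]
    report.extant_ids = extant["specimen_id"].tolist()
    report.fossil_ids = fossil["specimen_id"].tolist()
    labels = extant.set_index("specimen_id")["locomotor_class"]
    report.extant_labels = labels.loc[report.extant_ids].to_numpy()
    taxa = [
        extant.set_index("specimen_id")["species"][sid] for sid in report.extant_ids
    ]

    do_biomech = config.route in ("biomech", "both")
    do_shape = config.route in ("shape", "both")

    if do_biomech:
        _run_biomech(bundle, config, report)
    if do_shape:
        _run_shape(bundle, config, report)
    if do_biomech and do_shape:
        _run_association(bundle, config, report, taxa)
    return report


def _run_biomech(bundle: Bundle, config: RunConfig, report: ExtantReport) -> None:
    extant_fields = [bundle.stress_fields[sid] for sid in report.extant_ids]
    summaries = [fea.stress_summary(f) for f in extant_fields]
    report.stress_summaries = pd.DataFrame([s.as_dict() for s in summaries]).set_index(
        "specimen_id"
    )
    report.percentile_features = report.stress_summaries[list(PERCENTILE_COLUMNS)]

    x = report.percentile_features.to_numpy()
    report.normality = grouptests.multivariate_normality(x)
    report.permanova = grouptests.permanova(
        x, report.extant_labels, n_perm=config.n_perm, seed=config.seed
    )
    report.pairwise_permanova = grouptests.pairwise_permanova(
        x, report.extant_labels, n_perm=config.n_perm, seed=config.seed + 1
    )

    ft_upper = config.ft_upper if config.ft_upper is not None else intervals.default_ft_upper(extant_fields)
    report.ft_upper = ft_upper
    if config.n_intervals is not None:
        n_int = config.n_intervals
    else:
        n_int = intervals.choose_intervals(
            extant_fields, ft_upper, config.interval_candidates
        )
    report.n_intervals = n_int

    profiles = [intervals.interval_profile(f, ft_upper, n_int) for f in extant_fields]
    raw = intervals.profiles_to_frame(profiles)
    fossil_fields = [bundle.stress_fields[sid] for sid in report.fossil_ids]
    fossil_profiles = [intervals.interval_profile(f, ft_upper, n_int) for f in fossil_fields]
    raw_fossil = intervals.profiles_to_frame(fossil_profiles) if fossil_profiles else None
    report.interval_features_raw = raw
    report.interval_features = intervals.boxcox_center_scale(raw)

    x_train = report.interval_features.values
    cv = classify.CvSpec(
        repeats=config.cv.repeats,
        train_fraction=config.cv.train_fraction,
        stratified=config.cv.stratified,
        seed=config.seed,
    )
    reports = {
        name: classify.lgocv_evaluate(x_train, report.extant_labels, name, cv=cv)
        for name in config.model_families
    }
    report.classifier_reports["biomech"] = reports
    report.best_models["biomech"] = _best_family(reports)
    report._biomech_fossil_features = (
        report.interval_features.transform_new(raw_fossil).to_numpy()
        if raw_fossil is not None
        else None
    )


def _run_shape(bundle: Bundle, config: RunConfig, report: ExtantReport) -> None:
    # joint GPA over extant + fossil, PCA fitted on extant only
    ids = report.extant_ids + report.fossil_ids
    by_id = {lm.specimen_id: lm for lm in bundle.landmarks}
    aligned = shape.gpa([by_id[sid] for sid in ids])
    report.aligned = aligned
    n_ext = len(report.extant_ids)
    extant_aligned = shape.AlignedShapes(
        procrustes_coords=aligned.procrustes_coords[:n_ext],
        centroid_sizes=aligned.centroid_sizes[:n_ext],
        mean_shape=aligned.procrustes_coords[:n_ext].mean(axis=0),
        specimen_ids=report.extant_ids,
        n_iterations=aligned.n_iterations,
    )
    pca = shape.shape_pca(extant_aligned)
    report.pca = pca
    r = pca.retained
    report.extant_scores = pca.scores[:, :r]
    if report.fossil_ids:
        fossil_aligned = shape.AlignedShapes(
            procrustes_coords=aligned.procrustes_coords[n_ext:],
            centroid_sizes=aligned.centroid_sizes[n_ext:],
            mean_shape=aligned.mean_shape,
            specimen_ids=report.fossil_ids,
            n_iterations=aligned.n_iterations,
        )
        report.fossil_scores = shape.project_shapes(pca, fossil_aligned)[:, :r]

    cv = classify.CvSpec(
        repeats=config.cv.repeats,
        train_fraction=config.cv.train_fraction,
        stratified=config.cv.stratified,
        seed=config.seed,
    )
    rf_mtry = [m for m in (2, 3) if m <= r] or [1]
    grids = dict(classify.DEFAULT_GRIDS)
    grids["RF"] = [{"n_estimators": 200, "max_features": m} for m in rf_mtry]
    reports = {
        name: classify.lgocv_evaluate(
            report.extant_scores, report.extant_labels, name, grids[name], cv=cv
        )
        for name in config.model_families
    }
    report.classifier_reports["shape"] = reports
    report.best_models["shape"] = _best_family(reports)


def _run_association(
    bundle: Bundle, config: RunConfig, report: ExtantReport, taxa: list[str]
) -> None:
    flat = report.aligned.flat()[: len(report.extant_ids)]
    percentiles = report.percentile_features.to_numpy()
    tree = bundle.tree
    report.kmult_shape = phylo.kmult(
        flat, tree, taxa, n_perm=config.n_perm, seed=config.seed + 2
    )
    report.kmult_stress = phylo.kmult(
        percentiles, tree, taxa, n_perm=config.n_perm, seed=config.seed + 3
    )
    volumes = report.stress_summaries["total_volume"].to_numpy()
    report.pgls_stress_volume = phylo.pgls(
        percentiles, volumes, tree, taxa, n_perm=config.n_perm, seed=config.seed + 4
    )
    sizes = report.aligned.centroid_sizes[: len(report.extant_ids)]
    report.pgls_shape_size = phylo.pgls(
        flat, sizes, tree, taxa, n_perm=config.n_perm, seed=config.seed + 5
    )
    report.pls = phylo.two_block_pls(
        flat, percentiles, n_perm=config.n_perm, seed=config.seed + 6
    )
    report.phylo_pls = phylo.phylo_pls(
        flat, percentiles, tree, taxa, n_perm=config.n_perm, seed=config.seed + 7
    )


def run_fossil_inference(bundle: Bundle, report: ExtantReport) -> pd.DataFrame:
    """Posterior locomotor-class probabilities per fossil under the
    best model of each available route; never reads fossil labels."""
    if not report.fossil_ids:
        warnings.warn("no fossil specimens in bundle", stacklevel=2)
        return pd.DataFrame()
    config = report.config
    rows = {sid: {"specimen_id": sid} for sid in report.fossil_ids}
    routes: list[tuple[str, np.ndarray, np.ndarray]] = []
    if "biomech" in report.classifier_reports:
        routes.append(
            (
                "biomech",
                report.interval_features.values,
                report._biomech_fossil_features,
            )
        )
    if "shape" in report.classifier_reports:
        routes.append(("shape", report.extant_scores, report.fossil_scores))
    for route, x_train, x_fossil in routes:
        if x_fossil is None:
            warnings.warn(f"route {route}: fossil features missing; skipped", stacklevel=2)
            continue
        best = report.best_models[route]
        best_report = report.classifier_reports[route][best]
        model = classify.fit_final_model(
            x_train, report.extant_labels, best, best_report.best_params, seed=config.seed
        )
        preds = classify.predict_fossils(model, x_fossil, report.fossil_ids)
        for p in preds:
            for cls, prob in p.posterior.items():
                rows[p.specimen_id][f"{route}_{cls}"] = prob
            rows[p.specimen_id][f"{route}_predicted"] = p.predicted_class
    return pd.DataFrame(list(rows.values())).set_index("specimen_id")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def write_report(report: ExtantReport, outdir: str | Path, fossil_table: pd.DataFrame | None = None) -> list[Path]:
    """Write every report artifact as CSV/JSON with provenance tags."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": report.config.seed, "config_hash": report.config.digest()}
    written = []

    def dump_json(name: str, payload: dict) -> None:
        path = outdir / name
        payload = {"provenance": provenance, **payload}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
        written.append(path)

    def dump_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path)
        written.append(path)

    if report.stress_summaries is not None:
        dump_csv("stress_summaries.csv", report.stress_summaries)
        dump_csv("interval_features_raw.csv", report.interval_features_raw)
        dump_csv("interval_features_transformed.csv", report.interval_features.data)
        pm = report.permanova
        dump_json(
            "permanova.json",
            {
                "normality": {
                    "skewness_p": report.normality.skewness_p,
                    "kurtosis_p": report.normality.kurtosis_p,
                    "normal": report.normality.normal,
                    "note": report.normality.note,
                },
                "overall": {
                    "F": pm.F,
                    "R2": pm.R2,
                    "p_value": pm.p_value,
                    "n_perm": pm.n_perm,
                },
                "pairwise": [
                    {
                        "pair": list(rec["pair"]),
                        "F": rec["result"].F,
                        "R2": rec["result"].R2,
                        "p_value": rec["result"].p_value,
                        "p_adjusted": rec["p_adjusted"],
                    }
                    for rec in report.pairwise_permanova
                ],
                "intervals": {"FT_upper": report.ft_upper, "N": report.n_intervals},
            },
        )
    if report.aligned is not None:
        coords = pd.DataFrame(
            report.aligned.flat(),
            index=report.extant_ids + report.fossil_ids,
        )
        dump_csv("aligned_coords.csv", coords)
        dump_csv(
            "pca_scores.csv",
            pd.DataFrame(report.extant_scores, index=report.extant_ids),
        )
        dump_json(
            "pca.json",
            {
                "eigenvalues": report.pca.eigenvalues,
                "retained": report.pca.retained,
                "variance_retained": float(
                    report.pca.proportions[: report.pca.retained].sum()
                ),
            },
        )
    if report.kmult_shape is not None:
        dump_json(
            "phylo_stats.json",
            {
                "kmult_shape": {"K": report.kmult_shape.statistic, "p": report.kmult_shape.p_value},
                "kmult_stress": {"K": report.kmult_stress.statistic, "p": report.kmult_stress.p_value},
                "pgls_stress_volume": {
                    "F": report.pgls_stress_volume.f_statistic,
                    "R2": report.pgls_stress_volume.r_squared,
                    "p": report.pgls_stress_volume.p_value,
                },
                "pgls_shape_size": {
                    "F": report.pgls_shape_size.f_statistic,
                    "R2": report.pgls_shape_size.r_squared,
                    "p": report.pgls_shape_size.p_value,
                },
                "pls": {"r_pls": report.pls.r_pls, "p": report.pls.p_value},
                "phylo_pls": {"r_pls": report.phylo_pls.r_pls, "p": report.phylo_pls.p_value},
            },
        )
    for route, reports in report.classifier_reports.items():
        dump_json(
            f"classifier_{route}.json",
            {
                "best_model": report.best_models[route],
                "models": {
                    name: {
                        "accuracy_mean": rep.accuracy_mean,
                        "accuracy_ci95": list(rep.accuracy_ci95),
                        "kappa_mean": rep.kappa_mean,
                        "kappa_ci95": list(rep.kappa_ci95),
                        "best_params": rep.best_params,
                    }
                    for name, rep in reports.items()
                },
            },
        )
    if fossil_table is not None and not fossil_table.empty:
        dump_csv("fossil_predictions.csv", fossil_table)
    return written
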