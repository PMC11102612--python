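"""End-to-end orchestration: simulate -> measure -> profile -> stats -> classify.

`measure_subject` is the per-subject measurement pipeline (anatomical frame,
ICV, smoothing, curvature, midline profile, CURV, IFA, CI, DIST, RATIO);
`run_pipeline` drives the whole analysis from a single validated config and
writes per-stage artifacts plus a JSON report with full provenance.
"""

from __future__ import annotations

import json
import logging
import pathlib
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .anthropometry import (MeasureRecord, anatomical_frame, cephalic_index,
                            interfrontal_angle, interorbital_distance,
                            orbital_ratio, to_frame)
from .cohort import DEFAULT_PRESETS, SyntheticSubject, sample_cohort
from .diagnostics import hcpc, knn_select_k, roc_with_cutoff
from .mesh import TriangleMesh, mesh_volume, principal_curvatures, taubin_smooth
from .profiles import (CurvatureProfile, compute_curv, midline_path,
                       profile_group_difference, section_profile)
from .stats import (generalized_procrustes, holm_adjust, icv_two_way_anova,
                    pairwise_perm, pca_with_threshold, perm_manova,
                    spearman_vs_age)

log = logging.getLogger(__name__)

KNN_FEATURES = ("age_days", "CURV", "IFA", "DIST", "RATIO", "CI")
HCPC_FEATURES = ("age_days", "CURV", "RATIO", "DIST", "IFA")
ROC_VARIABLES = ("CURV", "DIST", "IFA", "RATIO")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run (seed recorded in every output)."""

    output_dir: str = "results/pipeline"
    n_per_group: tuple = (90, 27, 90)           # TG, MR, C
    seed: int = 0
    smoothing_iterations: int = 10
    smoothing_shrink: float = 0.5
    smoothing_inflate: float = -0.53
    curvature_measure: str = "k1"               # k1 | mean
    curvature_ring: int = 2
    n_slices: int = 90
    half_width: float = 10.0
    section_range: tuple = (2, 31)
    n_perm: int = 999
    variance_threshold: float = 0.95
    confidence_level: float = 0.95
    n_boot: int = 2000
    cutoff_criterion: str = "youden"            # youden | closest-topleft
    k_grid: tuple = tuple(range(1, 16, 2))
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        lo, hi = self.section_range
        if lo > hi:
            raise ConfigError(f"inverted section range {self.section_range}")
        if not (0 <= lo and hi <= self.n_slices):
            raise ConfigError("section range outside slice numbering")
        if self.curvature_measure not in ("k1", "mean"):
            raise ConfigError("curvature_measure must be 'k1' or 'mean'")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.n_perm < 9 or self.n_boot < 9:
            raise ConfigError("n_perm/n_boot too small")
        if min(self.n_per_group) < 3:
            raise ConfigError("need n >= 3 per group")


def measure_subject(subject: SyntheticSubject, *,
                    smoothing_iterations: int = 10,
                    smoothing_shrink: float = 0.5,
                    smoothing_inflate: float = -0.53,
                    curvature_measure: str = "k1",
                    curvature_ring: int = 2,
                    n_slices: int = 90, half_width: float = 10.0,
                    section_range=(2, 31)) -> tuple[MeasureRecord, CurvatureProfile]:
    """All univariate descriptors plus the curvature profile for one subject.

    Every geometric quantity is computed in the Frankfurt-aligned anatomical
    frame derived from the subject's own landmarks, so the measures are
    invariant to how the input meshes happen to be positioned.
    """
    frame = anatomical_frame(subject.landmarks)
    vault = TriangleMesh(to_frame(subject.vault.vertices, frame), subject.vault.faces)
    lms = {k: to_frame(v[None], frame)[0] for k, v in subject.landmarks.points.items()}
    icv = mesh_volume(subject.intracranial)
    smoothed = taubin_smooth(vault, smoothing_iterations,
                             smoothing_shrink, smoothing_inflate)
    curv_field = principal_curvatures(smoothed, ring=curvature_ring)
    path = midline_path(smoothed, lms["glabella"], lms["anterior_fontanelle"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = section_profile(smoothed, curv_field, path, n_slices=n_slices,
                                  half_width=half_width, measure=curvature_measure,
                                  subject_id=subject.subject_id)
    curv = compute_curv(profile, section_range)
    record = MeasureRecord(
        subject_id=subject.subject_id, group=subject.group,
        age_days=subject.age_days, sex=subject.sex,
        CURV=curv,
        IFA=interfrontal_angle(subject.vault, subject.landmarks),
        CI=cephalic_index(vault),
        DIST=interorbital_distance(subject.orbits),
        RATIO=orbital_ratio(subject.orbits),
        ICV=icv,
    )
    return record, profile


def measure_cohort(subjects, **kwargs) -> tuple[pd.DataFrame, dict]:
    """Measure every subject; returns (measures table, subject_id -> profile)."""
    records, profiles = [], {}
    for s in subjects:
        rec, prof = measure_subject(s, **kwargs)
        records.append(rec.as_dict())
        profiles[s.subject_id] = prof
    return pd.DataFrame(records), profiles


def profiles_by_group(measures: pd.DataFrame, profiles: dict) -> dict:
    out: dict[str, list] = {}
    for sid, grp in zip(measures["subject_id"], measures["group"]):
        out.setdefault(grp, []).append(profiles[sid])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; any stage failure aborts with its name."""
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "seed": config.seed,
                    "version": __version__}
    rng_seed = config.seed

    stage = "simulate"
    try:
        subjects, meta = sample_cohort(config.n_per_group, seed=rng_seed)
        meta.to_csv(out / "metadata.csv", index=False)
        report["simulate"] = {"n_subjects": len(subjects),
                              "groups": meta["group"].value_counts().to_dict()}

        stage = "measure"
        measures, profiles = measure_cohort(
            subjects,
            smoothing_iterations=config.smoothing_iterations,
            smoothing_shrink=config.smoothing_shrink,
            smoothing_inflate=config.smoothing_inflate,
            curvature_measure=config.curvature_measure,
            curvature_ring=config.curvature_ring,
            n_slices=config.n_slices, half_width=config.half_width,
            section_range=config.section_range)
        measures.to_csv(out / "measures.csv", index=False)
        prof_tab = pd.DataFrame({sid: p.values for sid, p in profiles.items()}).T
        prof_tab.columns = [f"section_{i}" for i in range(prof_tab.shape[1])]
        prof_tab.to_csv(out / "profiles.csv")
        report["measure"] = {
            "group_means": measures.groupby("group")[
                ["CURV", "IFA", "CI", "DIST", "RATIO", "ICV"]].mean().round(4).to_dict()}

        stage = "profile"
        by_group = profiles_by_group(measures, profiles)
        comparisons = {}
        for a, b in (("TG", "C"), ("TG", "MR"), ("MR", "C")):
            cmp_ = profile_group_difference(by_group[a], by_group[b],
                                            level=config.confidence_level,
                                            n_boot=config.n_boot, seed=rng_seed)
            pd.DataFrame({"section": np.arange(len(cmp_.diff)), "diff": cmp_.diff,
                          "ci_low": cmp_.ci_low, "ci_high": cmp_.ci_high,
                          "significant": np.isin(np.arange(len(cmp_.diff)),
                                                 cmp_.significant_sections)}
                         ).to_csv(out / f"profile_{a}_vs_{b}.csv", index=False)
            comparisons[f"{a}_vs_{b}"] = cmp_.significant_sections.tolist()
        report["profile"] = {k: {"n_significant": len(v),
                                 "first": (v[0] if v else None),
                                 "last": (v[-1] if v else None)}
                             for k, v in comparisons.items()}

        stage = "stats"
        stats_report = {}
        age = measures["age_days"].to_numpy()
        group = measures["group"].to_numpy()
        for var in ("CI", "CURV", "DIST", "ICV", "IFA", "RATIO"):
            vals = measures[var].to_numpy()
            mres = perm_manova(vals, group, age, n_perm=config.n_perm, seed=rng_seed)
            pw = pairwise_perm(vals, group, age, n_perm=config.n_perm, seed=rng_seed)
            rho_by_group = {
                g: spearman_vs_age(measures.loc[group == g, var].to_numpy(),
                                   measures.loc[group == g, "age_days"].to_numpy())
                for g in np.unique(group)}
            stats_report[var] = {
                "perm": {k: vars(v) for k, v in mres.items()},
                "pairwise_p": {f"{a}_vs_{b}": p for (a, b), p in pw.items()},
                "spearman_vs_age": {g: {"S": s, "rho": r, "p": p}
                                    for g, (s, r, p) in rho_by_group.items()},
            }
        # orbital shape: GPA + PCA + permutation MANOVA on retained scores
        configs_ = [s.orbits.full_configuration() for s in subjects]
        aligned, _, _ = generalized_procrustes(configs_)
        flat = aligned.reshape(len(aligned), -1)
        pca = pca_with_threshold(flat, config.variance_threshold)
        shape_manova = perm_manova(pca.retained_scores, group, age,
                                   n_perm=config.n_perm, seed=rng_seed)
        stats_report["orbital_shape"] = {
            "n_pcs": pca.n_retained,
            "perm": {k: vars(v) for k, v in shape_manova.items()}}
        # ICV two-way ANOVA on age-residualised volumes
        from .stats import age_residualize
        icv_resid = age_residualize(measures["ICV"].to_numpy(), age)
        stats_report["icv_anova"] = icv_two_way_anova(
            icv_resid, measures["sex"].to_numpy(), group)
        report["stats"] = stats_report
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=1, default=str)

        stage = "classify"
        cls_report = {}
        roc_tab = []
        for var in ROC_VARIABLES:
            for a, b in (("MR", "TG"), ("MR", "C"), ("C", "TG")):
                m = measures["group"].isin([a, b])
                r = roc_with_cutoff(measures.loc[m, var].to_numpy(),
                                    measures.loc[m, "group"].to_numpy(),
                                    positive=b, criterion=config.cutoff_criterion)
                roc_tab.append({"variable": var, "pair": f"{a}_vs_{b}",
                                "auc": r.auc, "cutoff": r.cutoff,
                                "sensitivity": r.sensitivity_at_cutoff,
                                "specificity": r.specificity_at_cutoff,
                                "youden_j": r.youden_j, "flipped": r.flipped})
        roc_df = pd.DataFrame(roc_tab)
        roc_df.to_csv(out / "roc.csv", index=False)
        cls_report["roc"] = roc_tab
        features = measures[list(KNN_FEATURES)].to_numpy()
        knn = knn_select_k(features, group, train_fraction=config.train_fraction,
                           k_grid=list(config.k_grid), seed=rng_seed)
        cls_report["knn"] = {"k": knn.k, "accuracy": knn.accuracy,
                             "per_class_recall": knn.per_class_recall,
                             "confusion": knn.confusion.to_dict()}
        h = hcpc(measures[list(HCPC_FEATURES)].to_numpy(),
                 truth=group, feature_names=list(HCPC_FEATURES), seed=rng_seed)
        cls_report["hcpc"] = {
            "n_clusters": h.n_clusters,
            "per_class_agreement": h.confusion.per_class_agreement,
            "overall_agreement": h.confusion.overall_agreement,
            "confusion": h.confusion.counts.to_dict(),
            "axis_correlations": h.axis_correlations.round(3).to_dict()}
        report["classify"] = cls_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
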