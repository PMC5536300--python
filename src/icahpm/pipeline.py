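"""End-to-end orchestration: cohort -> preprocess -> ICA -> HPM ->
group statistics -> Granger causality -> classification.

A single YAML-backed :class:`PipelineConfig` carries every stage
parameter; the full-scale defaults follow the emulated acquisition and
analysis (discard 6 volumes; 8 mm FWHM; model orders 20..130 step 10;
voxel p 0.01 with a 20-voxel extent; Gaussian SVM width 0.5; 5-fold CV;
1000 repeated-LOO trials), while the desk-scale cohort runs a reduced
order grid. Every random draw derives from the master seed through named
per-stage seed spawns recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as clf
from . import gc as gcmod
from .cohort import CohortSpec, generate_cohort, write_cohort
from .group_stats import (
    GroupDiffMap,
    build_design,
    estimate_smoothness_fwhm,
    fit_voxelwise_glm,
    monte_carlo_extent_threshold,
    severity_correlation,
    threshold_clusters,
)
from .hpm import run_hpm
from .ica import decompose_subject, enumerate_model_orders
from .preprocess import preprocess_subject

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_RANGES = {
    "n_discard": (0, 50),
    "fwhm_mm": (0.0, 30.0),
    "motion_threshold_mm": (0.0, 10.0),
    "global_z_threshold": (0.1, 10.0),
    "voxel_p": (0.0, 1.0),
    "fwer": (0.0, 1.0),
    "alpha_threshold": (-1.0, 1.01),
    "min_subject_fraction": (0.0, 1.0),
    "min_orders_fraction": (0.0, 1.0),
    "kernel_width": (1e-6, 100.0),
    "svm_c": (1e-6, 1e6),
    "kfold_k": (2, 50),
    "n_trials": (1, 100000),
    "mc_iterations": (1, 1000000),
    "max_var_order": (1, 10),
}


@dataclass
class PipelineConfig:
    """Validated stage parameters for one pipeline run."""

    out_dir: str = "runs"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "cohort", "preprocess", "ica", "hpm", "group_stats", "gc", "classify",
        ]
    )
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    n_discard: int = 6
    motion_threshold_mm: float = 0.5
    global_z_threshold: float = 3.0
    fwhm_mm: float = 8.0
    # Full-scale order enumeration; desk-scale runs override (a 130-order
    # decomposition is degenerate on a toy grid).
    orders: str = "20:130:10"
    min_subject_fraction: float = 0.5
    alpha_threshold: float = 0.7
    min_orders_fraction: float = 0.5
    match_mode: str = "continuous"
    voxel_p: float = 0.01
    extent_voxels: int | None = None  # None -> Monte-Carlo calibrated
    fwer: float = 0.05
    mc_iterations: int = 1000
    max_var_order: int = 3
    kernel_width: float = 0.5
    svm_c: float = 1.0
    kfold_k: int = 5
    n_trials: int = 1000

    def model_orders(self) -> list[int]:
        lo, hi, step = (int(v) for v in self.orders.split(":"))
        return enumerate_model_orders(lo, hi, step)


def validate_config(raw) -> PipelineConfig:
    """Parse YAML text or a mapping into a validated PipelineConfig.

    Unknown keys are rejected; range violations name the key and the
    expected interval. An empty document gives the all-default config.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key, None)
        if v is None:
            continue
        if not (lo <= v <= hi) or (key in ("voxel_p", "fwer") and not (lo < v <= hi)):
            raise ValueError(f"config key {key!r} = {v} outside [{lo}, {hi}]")
    if cfg.match_mode not in ("continuous", "binary"):
        raise ValueError("match_mode must be 'continuous' or 'binary'")
    cfg.model_orders()  # validates the orders string
    bad_stages = set(cfg.stages) - {
        "cohort", "preprocess", "ica", "hpm", "group_stats", "gc", "classify",
    }
    if bad_stages:
        raise ValueError(f"unknown stages: {sorted(bad_stages)}")
    return cfg


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute the enabled stages in order and return the run report.

    The report carries, per stage, wall time, key parameters and content
    hashes of deterministic outputs; identical config + seed reproduce
    identical hashes. Intermediate Python objects are returned under
    ``report['objects']`` for library use (not serialized).
    """
    t_start = time.time()
    root = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(
        ["cohort", "ica", "mc", "kfold", "trials"], root.spawn(5)
    ))
    report: dict = {"config": dataclasses.asdict(config), "stages": {}, "objects": {}}
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    def record(stage, t0, **info):
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2), **info}

    series = truth = None
    if "cohort" in config.stages:
        t0 = time.time()
        spec = CohortSpec(**{**config.cohort, "seed": int(
            stage_seeds["cohort"].generate_state(1, dtype=np.uint32)[0] >> 1
        )}) if "seed" not in config.cohort else CohortSpec(**config.cohort)
        series, truth = generate_cohort(spec)
        if write_outputs:
            write_cohort(series, truth, out / "cohort")
        record("cohort", t0, n_subjects=len(series),
               data_hash=_hash_array(series[0].data))
        report["objects"]["truth"] = truth

    if series is None:
        raise ValueError("pipeline currently requires the cohort stage")

    if "preprocess" in config.stages:
        t0 = time.time()
        processed = []
        n_flagged = 0
        for s in series:
            ps, rep = preprocess_subject(
                s, config.n_discard, config.motion_threshold_mm,
                config.global_z_threshold, config.fwhm_mm,
            )
            processed.append(ps)
            n_flagged += len(rep.flagged_indices)
        series = processed
        record("preprocess", t0, flagged_volumes=n_flagged,
               n_volumes=series[0].n_volumes,
               data_hash=_hash_array(series[0].data))
    report["objects"]["series"] = series

    clusters = None
    if "ica" in config.stages and "hpm" in config.stages:
        t0 = time.time()
        orders = config.model_orders()
        subject_seeds = stage_seeds["ica"].spawn(len(series))
        by_order: dict[int, list] = {o: [] for o in orders}
        for s, ss in zip(series, subject_seeds):
            sets = decompose_subject(s, orders, ss)
            for o in orders:
                by_order[o].append(sets[o])
        record("ica", t0, orders=orders)
        t0 = time.time()
        clusters = run_hpm(
            by_order,
            min_subject_fraction=config.min_subject_fraction,
            alpha_threshold=config.alpha_threshold,
            min_orders_fraction=config.min_orders_fraction,
            mode=config.match_mode,
        )
        record("hpm", t0, n_clusters=len(clusters),
               alphas=[round(c.alpha, 4) for c in clusters])
        report["objects"]["clusters"] = clusters

    diff_maps: list[GroupDiffMap] = []
    severity_r = None
    if "group_stats" in config.stages and clusters:
        t0 = time.time()
        mask = series[0].mask
        labels = {s.subject_id: s.group for s in series}
        ages = {s.subject_id: s.age for s in series}
        sexes = {s.subject_id: s.sex for s in series}
        extent = config.extent_voxels
        for cl in clusters:
            sids = cl.subject_ids
            maps = np.stack([cl.subject_representatives[s] for s in sids])
            design, names, contrast = build_design(
                [labels[s] for s in sids],
                np.array([ages[s] for s in sids]),
                [sexes[s] for s in sids],
            )
            t_map, df = fit_voxelwise_glm(maps, design, contrast, names)
            if extent is None:
                beta = np.linalg.lstsq(design, maps, rcond=None)[0]
                resid = maps - design @ beta
                sm = estimate_smoothness_fwhm(resid, mask, series[0].voxel_size_mm)
                sm = min(sm, 2.0 * max(series[0].voxel_size_mm))
                extent = monte_carlo_extent_threshold(
                    mask, sm, series[0].voxel_size_mm, config.voxel_p,
                    config.fwer, config.mc_iterations, seed=stage_seeds["mc"],
                )
            t3 = np.zeros(mask.shape)
            t3[mask] = t_map
            survivors = threshold_clusters(t3, df, config.voxel_p, extent, mask)
            diff_maps.append(GroupDiffMap(
                cluster_id=cl.cluster_id, t_map=t3, df=df,
                voxel_p_threshold=config.voxel_p,
                extent_threshold_voxels=extent,
                surviving_clusters=survivors,
            ))
        # Severity correlation on the first cluster with survivors, using
        # patient subjects with a severity score.
        for dm, cl in zip(diff_maps, clusters):
            if not dm.surviving_clusters:
                continue
            vox = dm.surviving_clusters[0].voxels
            sel = np.zeros(mask.shape, dtype=bool)
            sel[tuple(vox.T)] = True
            sel_flat = sel[mask]
            pats = [s for s in series if s.group == "patient"
                    and s.severity is not None
                    and s.subject_id in cl.subject_representatives]
            if len(pats) >= 3:
                scal = np.array([
                    cl.subject_representatives[s.subject_id][sel_flat].mean()
                    for s in pats
                ])
                sev = np.array([s.severity for s in pats])
                if scal.std() > 0 and sev.std() > 0:
                    severity_r = severity_correlation(scal, sev)
                    break
        record("group_stats", t0, extent_threshold=extent,
               surviving=[len(d.surviving_clusters) for d in diff_maps],
               severity_r=None if severity_r is None else round(severity_r[0], 4))
        report["objects"]["diff_maps"] = diff_maps
        report["objects"]["severity_r"] = severity_r

    comparisons = []
    records = []
    if "gc" in config.stages and clusters and len(clusters) >= 2:
        t0 = time.time()
        records, order = gcmod.cohort_gci_records(
            clusters, series, max_p=config.max_var_order,
        )
        labels = {s.subject_id: s.group for s in series}
        by_edge: dict[tuple, dict[str, float]] = {}
        for r in records:
            key = (r.source_cluster, r.target_cluster, r.mediator_cluster)
            by_edge.setdefault(key, {})[r.subject_id] = r.gci
        for key, vals in sorted(by_edge.items(), key=str):
            try:
                comparisons.append(gcmod.group_compare(vals, labels, edge=key))
            except ValueError:
                continue
        record("gc", t0, var_order=order, n_edges=len(comparisons))
        report["objects"]["gci_records"] = records
        report["objects"]["gci_comparisons"] = comparisons

    if "classify" in config.stages and clusters:
        t0 = time.time()
        mask = series[0].mask
        regional: dict[str, dict[str, float]] = {}
        for dm, cl in zip(diff_maps, clusters):
            if not dm.surviving_clusters:
                continue
            sel = np.zeros(mask.shape, dtype=bool)
            for sc in dm.surviving_clusters:
                sel[tuple(sc.voxels.T)] = True
            sel_flat = sel[mask]
            regional[f"z:cluster{cl.cluster_id}"] = {
                sid: float(rep[sel_flat].mean())
                for sid, rep in cl.subject_representatives.items()
            }
        edge_feats: dict[str, dict[str, float]] = {}
        sig_edges = {c.edge for c in comparisons if c.rank_sum_p < 0.05}
        for r in records:
            key = (r.source_cluster, r.target_cluster, r.mediator_cluster)
            if key not in sig_edges:
                continue
            name = (f"gci:c{r.source_cluster}->c{r.target_cluster}"
                    + (f"|c{r.mediator_cluster}" if r.mediator_cluster is not None else ""))
            edge_feats.setdefault(name, {})[r.subject_id] = r.gci
        if regional or edge_feats:
            all_sids = [s.subject_id for s in series]
            fm = clf.build_features(all_sids, regional, edge_feats)
            labels_list = [
                next(s.group for s in series if s.subject_id == sid)
                for sid in fm.subjects
            ]
            rep_loo = clf.svm_crossval(
                fm, labels_list, scheme="loo",
                kernel_width=config.kernel_width, c=config.svm_c,
            )
            rep_kf = clf.svm_crossval(
                fm, labels_list, scheme="kfold", k=config.kfold_k,
                kernel_width=config.kernel_width, c=config.svm_c,
                seed=int(stage_seeds["kfold"].generate_state(1, dtype=np.uint32)[0] >> 1),
            )
            rep_mlda = clf.mlda_fit_loo(fm, labels_list)
            record("classify", t0,
                   loo_accuracy=rep_loo.accuracy,
                   kfold_accuracy=rep_kf.accuracy,
                   mlda_accuracy=rep_mlda.accuracy,
                   mlda_sensitivity=rep_mlda.sensitivity,
                   mlda_specificity=rep_mlda.specificity,
                   n_features=len(fm.feature_names))
            report["objects"]["features"] = fm
            report["objects"]["reports"] = {
                "svm_loo": rep_loo, "svm_kfold": rep_kf, "mlda_loo": rep_mlda,
            }
        else:
            warnings.warn("no significant features; classification skipped")
            record("classify", t0, skipped=True)

    report["total_seconds"] = round(time.time() - t_start, 2)
    if write_outputs:
        _write_stage_outputs(report, out)
        manifest = {k: v for k, v in report.items() if k != "objects"}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return report


def _write_stage_outputs(report: dict, out: Path) -> None:
    """Tabular and volumetric stage outputs: a cluster table (TSV), group
    t-maps (NIfTI), a causal-index group table (TSV) and the
    classification reports (JSON)."""
    import nibabel as nib
    import pandas as pd

    objects = report["objects"]
    series = objects.get("series")
    diff_maps = objects.get("diff_maps")
    if series and diff_maps:
        affine = np.diag(list(series[0].voxel_size_mm) + [1.0])
        rows = []
        for dm in diff_maps:
            nib.save(
                nib.Nifti1Image(dm.t_map.astype(np.float32), affine),
                out / f"cluster{dm.cluster_id}_tmap.nii",
            )
            for i, sc in enumerate(dm.surviving_clusters):
                rows.append({
                    "cluster_id": dm.cluster_id,
                    "blob": i,
                    "sign": sc.sign,
                    "peak_x": sc.peak_voxel[0],
                    "peak_y": sc.peak_voxel[1],
                    "peak_z": sc.peak_voxel[2],
                    "peak_t": round(sc.peak_t, 3),
                    "extent": sc.extent,
                })
        pd.DataFrame(rows).to_csv(out / "cluster_table.tsv", sep="\t", index=False)
    comparisons = objects.get("gci_comparisons")
    if comparisons:
        rows = []
        for c in comparisons:
            row = {"source": c.edge[0], "target": c.edge[1], "mediator": c.edge[2]}
            for g in c.group_medians:
                q1, q3 = c.group_iqrs[g]
                row[f"{g}_median"] = round(c.group_medians[g], 4)
                row[f"{g}_iqr"] = f"{q1:.4f}-{q3:.4f}"
                row[f"{g}_signed_rank_p"] = f"{c.signed_rank_p[g]:.3g}"
            row["rank_sum_z"] = round(c.rank_sum_z, 3)
            row["rank_sum_p"] = f"{c.rank_sum_p:.3g}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "gci_table.tsv", sep="\t", index=False)
    reports = objects.get("reports")
    if reports:
        payload = {}
        for name, rep in reports.items():
            payload[name] = {
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "contributions": rep.contributions,
            }
        with open(out / "classification.json", "w") as fh:
            json.dump(payload, fh, indent=2)
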