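"""End-to-end orchestration: cohort -> overlay -> VLSM -> membership ->
survival -> expression scoring, with deterministic, re-loadable outputs.

A run either simulates a cohort (``sim`` block in the config) or loads real
inputs (mask manifest, samples CSV, expression TSV, GMT gene sets). Every
stage writes its result to the output directory so each downstream number
is recomputable from the emitted intermediates, and a run manifest records
the config hash, seed and package versions.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lesion_io import (
    LesionCohort, LesionMask, build_overlay, read_manifest, subset_cohort,
    write_mask, write_overlay_nifti,
)
from .vlsm import ContingencyTable, VLSMConfig, run_vlsm
from .annotation import (
    chi2_test, classify_membership, cohen_kappa, contingency_report,
    kappa_grade, location_summary, read_samples, vasari_filter,
)
from .survival import km_estimate, logrank_test, plot_km
from .scoring import (
    ScoringConfig, celltype_scores, diff_by_group, differential_expression,
    purity_proxy, rank_diff_genes, read_gmt, ssgsea_score,
)
from .simulate import SimConfig, simulate_cohort, write_cohort

log = logging.getLogger("vlsmkit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "exclusion_flow", "load_pipeline_config"]

POSITIVE_SUBTYPE = "proneural"
NEGATIVE_SUBTYPE = "mesenchymal"


@dataclass
class PipelineConfig:
    """Either ``sim`` (a SimConfig) or all four input paths, never both."""

    out_dir: Path
    sim: SimConfig | None = None
    manifest_path: Path | None = None
    samples_path: Path | None = None
    expression_path: Path | None = None
    gene_sets_path: Path | None = None
    vlsm: VLSMConfig = field(default_factory=VLSMConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    membership_min_overlap: int = 1
    survival_filters: bool = True
    make_plots: bool = False
    seed: int = 0
    top_k_genes: int = 10

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        real = [self.manifest_path, self.samples_path, self.expression_path]
        if self.sim is not None and any(p is not None for p in real):
            raise ValueError("provide either a simulation config or input paths, not both")
        if self.sim is None and any(p is None for p in real):
            raise ValueError("real-input mode needs manifest, samples and expression paths")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimConfig(**{k: _as_tuple(v) for k, v in raw["sim"].items()}) if "sim" in raw else None
    kwargs = dict(
        out_dir=raw.get("out_dir", "vlsm_out"),
        sim=sim,
        vlsm=VLSMConfig(**raw.get("vlsm", {})),
        scoring=ScoringConfig(**raw.get("scoring", {})),
        membership_min_overlap=raw.get("membership_min_overlap", 1),
        survival_filters=raw.get("survival_filters", True),
        make_plots=raw.get("make_plots", False),
        seed=raw.get("seed", 0),
        top_k_genes=raw.get("top_k_genes", 10),
    )
    for key in ("manifest_path", "samples_path", "expression_path", "gene_sets_path"):
        if key in raw:
            kwargs[key] = Path(raw[key])
    return PipelineConfig(**kwargs)


def _as_tuple(v):
    return tuple(v) if isinstance(v, list) else v


def exclusion_flow(
    all_ids: set[str],
    has_image: set[str],
    has_clinical: set[str],
    has_subtype: set[str],
) -> dict:
    """Sequential inclusion report: image, then clinical, then subtype.

    Mirrors the usual cohort-selection flowchart; the counts excluded at
    each step are reported in order and the included set is the
    intersection of all requirements.
    """
    step1 = all_ids & has_image
    step2 = step1 & has_clinical
    step3 = step2 & has_subtype
    return {
        "initial": len(all_ids),
        "excluded_missing_image": len(all_ids) - len(step1),
        "excluded_missing_clinical": len(step1) - len(step2),
        "excluded_missing_subtype": len(step2) - len(step3),
        "included": len(step3),
        "included_ids": sorted(step3),
    }


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a bundle of results and output paths.

    Stage order: inputs -> overlays -> two VLSM maps (positive class =
    proneural, then mesenchymal) -> membership against the proneural map ->
    contingency/location/kappa reports -> survival (full subset and
    treatment+VASARI-filtered subset) -> enrichment scores, purity, cell
    types and differential expression. Identical config and seed give
    identical outputs.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"outputs": {}}

    def emit(name: str, path: Path):
        bundle["outputs"][name] = path

    # -- stage: inputs ------------------------------------------------------
    if config.sim is not None:
        sim_cfg = config.sim
        if config.seed is not None:
            sim_cfg.seed = config.seed
        log.info("simulating cohort (seed=%d)", sim_cfg.seed)
        syn = simulate_cohort(sim_cfg)
        cohort, samples, expr = syn.lesions, syn.samples, syn.expression
        gene_sets = syn.gene_sets
        bundle["truth"] = syn.truth
    else:
        log.info("loading cohort from %s", config.manifest_path)
        cohort = read_manifest(config.manifest_path)
        samples = read_samples(config.samples_path)
        expr = pd.read_csv(config.expression_path, sep=None, engine="python", index_col=0)
        gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else {}
    samples = samples.set_index("sample_id", drop=False)
    samples = samples.loc[cohort.sample_ids]
    log.info("cohort: %d samples on grid %s", len(cohort), cohort.grid.shape)

    flow = exclusion_flow(
        set(samples["sample_id"]),
        set(cohort.sample_ids),
        set(samples.dropna(subset=["os_days", "event"])["sample_id"])
        if {"os_days", "event"}.issubset(samples.columns) else set(samples["sample_id"]),
        set(samples.dropna(subset=["subtype"])["sample_id"]),
    )
    _write_json(flow, out / "inclusion_flow.json")
    emit("inclusion_flow", out / "inclusion_flow.json")

    # -- stage: overlays ----------------------------------------------------
    overlay = build_overlay(cohort)
    write_overlay_nifti(overlay, out / "overlay_all.nii.gz")
    emit("overlay_all", out / "overlay_all.nii.gz")
    for subtype in (POSITIVE_SUBTYPE, NEGATIVE_SUBTYPE):
        ids = set(samples.loc[samples["subtype"] == subtype, "sample_id"])
        if ids:
            sub = subset_cohort(cohort, ids)
            write_overlay_nifti(build_overlay(sub), out / f"overlay_{subtype}.nii.gz")
            emit(f"overlay_{subtype}", out / f"overlay_{subtype}.nii.gz")

    # -- stage: VLSM (one map per subtype polarity) -------------------------
    vlsm_sub = samples[samples["subtype"].isin([POSITIVE_SUBTYPE, NEGATIVE_SUBTYPE])]
    vlsm_cohort = subset_cohort(cohort, set(vlsm_sub["sample_id"]))
    vlsm_sub = vlsm_sub.loc[vlsm_cohort.sample_ids]
    results = {}
    for subtype in (POSITIVE_SUBTYPE, NEGATIVE_SUBTYPE):
        labels = (vlsm_sub["subtype"] == subtype).astype(int).to_numpy()
        log.info("VLSM map for %s (n=%d, positives=%d)", subtype, len(labels), labels.sum())
        res = run_vlsm(vlsm_cohort, labels, config.vlsm)
        results[subtype] = res
        _save_vlsm(res, out, subtype, emit)
        log.info(
            "  %d/%d analyzed voxels significant (FDR threshold %s)",
            res.n_significant, int(res.analyzed_mask.sum()), res.fdr_p_threshold,
        )
    bundle["vlsm"] = results

    # -- stage: membership + reports ---------------------------------------
    region = results[POSITIVE_SUBTYPE].sig_mask.astype(bool)
    bundle["region_voxels"] = int(region.sum())
    membership = classify_membership(vlsm_cohort, region, config.membership_min_overlap)
    membership.to_csv(out / "membership.csv", index=False)
    emit("membership", out / "membership.csv")
    labels_pos = (
        (vlsm_sub["subtype"] == POSITIVE_SUBTYPE).astype(int)
    )
    report = contingency_report(membership, labels_pos)
    if region.any():
        cells = report["cells"]
        tbl = ContingencyTable(
            a=cells["in_pos"], b=cells["in_neg"],
            c=cells["out_pos"], d=cells["out_neg"],
        )
        try:
            chi2, chi2_p = chi2_test(tbl)
            report["chi2"] = chi2
            report["chi2_p"] = chi2_p
        except ValueError as exc:
            report["chi2_error"] = str(exc)
    _write_json(report, out / "contingency_report.json")
    emit("contingency_report", out / "contingency_report.json")

    _write_json(location_summary(samples), out / "location_summary.json")
    emit("location_summary", out / "location_summary.json")

    kappa_report = {}
    for feat in ("f1", "f5"):
        c1, c2 = f"vasari_{feat}", f"rater2_{feat}"
        if {c1, c2}.issubset(samples.columns):
            k = cohen_kappa(samples[c1], samples[c2])
            kappa_report[feat.upper()] = {"kappa": k, "grade": kappa_grade(k)}
    _write_json(kappa_report, out / "kappa_report.json")
    emit("kappa_report", out / "kappa_report.json")

    # -- stage: survival ----------------------------------------------------
    surv_report: dict[str, Any] = {}
    if {"os_days", "event"}.issubset(samples.columns):
        member = membership.set_index("sample_id")["in_area"]
        surv = vlsm_sub.assign(
            time_days=vlsm_sub["os_days"], in_area=member.reindex(vlsm_sub.index)
        ).dropna(subset=["time_days", "event"])
        subsets = {"all_vlsm_samples": surv}
        if config.survival_filters:
            treated = surv
            for flag in ("resection", "radiation", "pharmaceutical"):
                if flag in treated.columns:
                    treated = treated[treated[flag].astype(bool)]
            keep = vasari_filter(treated)
            subsets["treated_vasari_filtered"] = treated[
                treated["sample_id"].isin(keep)
            ]
        for name, df in subsets.items():
            surv_report[name] = _survival_compare(df, out, name, config, emit)
    _write_json(surv_report, out / "survival_report.json")
    emit("survival_report", out / "survival_report.json")
    bundle["survival"] = surv_report

    # -- stage: expression scoring -----------------------------------------
    scoring_report: dict[str, Any] = {}
    if expr is not None and len(expr) and gene_sets:
        member = membership.set_index("sample_id")["in_area"]
        member = member.reindex(expr.columns).dropna().astype(bool)
        expr_m = expr[member.index]
        scores = pd.DataFrame(index=expr_m.columns)
        core = {}
        for name in ("EMT", "immune_signature", "stromal_signature"):
            if name in gene_sets:
                scores[name] = ssgsea_score(expr_m, gene_sets[name], config.scoring)
        if {"immune_signature", "stromal_signature"}.issubset(gene_sets):
            scores["purity"] = purity_proxy(
                expr_m, gene_sets["immune_signature"],
                gene_sets["stromal_signature"], config.scoring,
            )
        marker_sets = [
            gs for name, gs in gene_sets.items()
            if name not in ("EMT", "immune_signature", "stromal_signature")
        ]
        if marker_sets:
            ct_scores, ct_errors = celltype_scores(expr_m, marker_sets, config.scoring)
            scores = pd.concat([scores, ct_scores], axis=1)
            if ct_errors:
                scoring_report["celltype_errors"] = ct_errors
        scores.to_csv(out / "signature_scores.csv")
        emit("signature_scores", out / "signature_scores.csv")

        if member.nunique() == 2 and member.value_counts().min() >= 2:
            comparisons = {}
            for col in scores.columns:
                cmp = diff_by_group(scores[col], member)
                comparisons[col] = {
                    "t": cmp.t, "p": cmp.p, "mean_in": cmp.mean_a,
                    "mean_out": cmp.mean_b, "stars": cmp.stars,
                }
            scoring_report["group_comparisons"] = comparisons
            if "EMT" in gene_sets:
                diff = differential_expression(
                    expr_m, member, genes=sorted(gene_sets["EMT"].genes)
                )
                diff.to_csv(out / "diffexp_emt.csv")
                emit("diffexp_emt", out / "diffexp_emt.csv")
                top = rank_diff_genes(diff, config.top_k_genes)
                scoring_report["top_emt_genes"] = top.reset_index().to_dict("records")
        else:
            scoring_report["note"] = "membership groups too small for comparison"
    _write_json(scoring_report, out / "scoring_report.json")
    emit("scoring_report", out / "scoring_report.json")
    bundle["scoring"] = scoring_report

    # -- run manifest -------------------------------------------------------
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "vlsmkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_samples": len(cohort),
        "grid_shape": list(cohort.grid.shape),
        "outputs": {k: str(v) for k, v in bundle["outputs"].items()},
    }
    _write_json(manifest, out / "run_manifest.json")
    bundle["manifest"] = manifest
    bundle["contingency"] = report
    bundle["kappa"] = kappa_report
    bundle["membership"] = membership
    return bundle


def _save_vlsm(res, out: Path, tag: str, emit) -> None:
    import nibabel as nib

    for name, arr, dtype in (
        ("z", np.nan_to_num(res.z_map), np.float32),
        ("p", np.where(np.isnan(res.p_map), 1.0, res.p_map), np.float32),
        ("sig", res.sig_mask, np.uint8),
    ):
        path = out / f"vlsm_{tag}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(dtype), res.grid.affine), str(path))
        emit(f"vlsm_{tag}_{name}", path)
    rows = []
    for c in res.clusters:
        world = res.grid.affine @ np.array([*c.peak_index, 1.0])
        rows.append(
            {
                "label": c.label, "n_voxels": c.n_voxels, "peak_z": c.peak_z,
                "peak_i": c.peak_index[0], "peak_j": c.peak_index[1],
                "peak_k": c.peak_index[2],
                "peak_x_mm": world[0], "peak_y_mm": world[1], "peak_z_mm": world[2],
            }
        )
    path = out / f"vlsm_{tag}_clusters.csv"
    pd.DataFrame(
        rows, columns=["label", "n_voxels", "peak_z", "peak_i", "peak_j",
                       "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm"]
    ).to_csv(path, index=False)
    emit(f"vlsm_{tag}_clusters", path)


def _survival_compare(df: pd.DataFrame, out: Path, name: str, config, emit) -> dict:
    rep: dict[str, Any] = {"n": int(len(df))}
    groups = {
        "in_area": df[df["in_area"] == True],  # noqa: E712
        "out_area": df[df["in_area"] == False],  # noqa: E712
    }
    rep["n_in"] = int(len(groups["in_area"]))
    rep["n_out"] = int(len(groups["out_area"]))
    if min(rep["n_in"], rep["n_out"]) == 0 or df["event"].sum() == 0:
        rep["note"] = "one group empty or no events; log-rank skipped"
        return rep
    curves = []
    for gname, g in groups.items():
        curve = km_estimate(g[["time_days", "event"]], label=gname)
        curve.to_frame().to_csv(out / f"km_{name}_{gname}.csv", index=False)
        emit(f"km_{name}_{gname}", out / f"km_{name}_{gname}.csv")
        curves.append(curve)
        rep[f"median_survival_{gname}"] = _median_survival(curve)
    try:
        chi2, p = logrank_test(
            groups["in_area"][["time_days", "event"]],
            groups["out_area"][["time_days", "event"]],
        )
        rep["logrank_chi2"] = chi2
        rep["logrank_p"] = p
    except ValueError as exc:
        rep["note"] = str(exc)
    if config.make_plots:
        plot_km(curves, out / f"km_{name}.png", title=name)
        emit(f"km_plot_{name}", out / f"km_{name}.png")
    return rep


def _median_survival(curve) -> float | None:
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if below.size else None
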