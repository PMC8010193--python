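"""Synthetic radiogenomic cohorts with known ground truth.

The generator produces the coupled data the analysis assumes, at desk
scale: (1) binary ellipsoidal lesion masks inside a brain-shaped ellipsoid
on a shared grid, where lesions of the positive subtype class are drawn
toward a planted spherical hotspot with probability ``hotspot_attraction``;
(2) a clinical table with subtype labels, exponential survival times whose
hazard doubles (by default) for tumors that miss the hotspot, independent
censoring, and VASARI-style annotations with duplicate-rater columns;
(3) a gene x sample expression matrix of standard-normal log-scale values
in which designated EMT, immune, stromal and cell-type marker genes are
shifted in the out-of-region samples. Ground truth (hotspot mask, true
membership, planted gene ids) is returned alongside, so every pipeline
stage can be scored against what was planted.

Default cohort structure mirrors the study conditions the pipeline is
meant for: 52 + 73 samples of the two subtype classes, a 141-gene EMT set
with 16 planted up-regulated genes, hazard ratio 2 for out-of-region
tumors, hotspot attraction 0.7 and a 1-SD expression shift.

All randomness flows from a single seed through named child streams, so a
stage can be re-simulated without disturbing the others.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lesion_io import LesionCohort, LesionMask, VolumeGrid, write_mask
from .scoring import GeneSet, write_gmt

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "simulate_survival", "write_cohort"]

_STREAMS = ("lesions", "clinical", "survival", "expression")


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_mm: float = 3.0
    n_pos: int = 52          # positive class (e.g. proneural)
    n_neg: int = 73          # negative class (e.g. mesenchymal)
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)  # voxels, per semi-axis
    hotspot_center: tuple[int, int, int] | None = None  # default: left-posterior-inferior
    hotspot_radius: float = 6.0
    hotspot_attraction: float = 0.7  # P(positive-class lesion centers in hotspot)
    hazard_baseline: float = 1.0 / 400.0  # per day; in-region hazard
    hazard_out_ratio: float = 2.0
    censor_rate: float = 0.25  # censoring hazard as a fraction of baseline
    max_followup_days: float = 1730.0
    n_genes: int = 2000
    emt_set_size: int = 141
    n_planted_up: int = 16
    n_planted_down: int = 4
    effect_sd: float = 1.0   # delta: expression shift in out-of-region samples (SD units)
    immune_set_size: int = 50
    stromal_set_size: int = 50
    immune_shift: float = 1.0
    stromal_shift: float = 1.0
    n_celltype_sets: int = 22
    celltype_set_size: int = 15
    depleted_celltypes: tuple[str, ...] = ("T_cells_CD8", "T_cells_follicular_helper")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg < 4:
            raise ValueError("need at least 4 samples in total")
        if not 0.0 <= self.hotspot_attraction <= 1.0:
            raise ValueError("hotspot_attraction must be in [0,1]")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.n_planted_up + self.n_planted_down > self.emt_set_size:
            raise ValueError("planted genes exceed the EMT set size")
        needed = (
            self.emt_set_size + self.immune_set_size + self.stromal_set_size
            + self.n_celltype_sets * self.celltype_set_size
        )
        if needed > self.n_genes:
            raise ValueError("n_genes too small for the requested gene sets")
        center = self.hotspot_center or tuple(
            int(round(s * f)) for s, f in zip(self.grid_shape, (0.32, 0.35, 0.35))
        )
        shape = np.array(self.grid_shape)
        if np.any(np.array(center) - self.hotspot_radius < 0) or np.any(
            np.array(center) + self.hotspot_radius >= shape
        ):
            raise ValueError("hotspot does not fit inside the grid")
        self.hotspot_center = center


@dataclass
class SyntheticCohort:
    lesions: LesionCohort
    samples: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: dict[str, GeneSet]
    truth: dict
    config: SimConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _sphere_mask(shape: Sequence[int], center: Sequence[float], radius: float) -> np.ndarray:
    grids = np.indices(tuple(shape))
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _ellipsoid_mask(
    shape: Sequence[int], center: Sequence[float], semi_axes: Sequence[float]
) -> np.ndarray:
    grids = np.indices(tuple(shape))
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, semi_axes))
    return q <= 1.0


def _brain_ellipsoid(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) * 0.45
    return center, semi


def _draw_center_in_brain(rng: np.random.Generator, shape, center, semi) -> np.ndarray:
    while True:  # rejection sampling inside the brain ellipsoid
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) <= 1.0:
            return center + u * semi


def _draw_center_in_sphere(rng, center, radius) -> np.ndarray:
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) <= 1.0:
            return np.asarray(center) + u * radius


def _simulate_lesions(cfg: SimConfig, rng: np.random.Generator):
    grid = VolumeGrid.isotropic(cfg.grid_shape, cfg.voxel_mm, "synthetic-template")
    bc, bs = _brain_ellipsoid(cfg.grid_shape)
    hotspot = _sphere_mask(cfg.grid_shape, cfg.hotspot_center, cfg.hotspot_radius)
    masks = []
    n_total = cfg.n_pos + cfg.n_neg
    labels = np.array([1] * cfg.n_pos + [0] * cfg.n_neg)
    for i in range(n_total):
        positive = labels[i] == 1
        if positive and rng.uniform() < cfg.hotspot_attraction:
            center = _draw_center_in_sphere(rng, cfg.hotspot_center, cfg.hotspot_radius)
        else:
            center = _draw_center_in_brain(rng, cfg.grid_shape, bc, bs)
        semi = rng.uniform(*cfg.lesion_radius_range, size=3)
        vox = _ellipsoid_mask(cfg.grid_shape, center, semi)
        if not vox.any():  # degenerate draw at the brain edge: keep the center voxel
            vox = np.zeros(cfg.grid_shape, dtype=bool)
            idx = np.clip(np.round(center).astype(int), 0, np.array(cfg.grid_shape) - 1)
            vox[tuple(idx)] = True
        masks.append(LesionMask(f"S{i:04d}", grid, vox.astype(np.uint8)))
    cohort = LesionCohort(masks)
    overlap = cohort.stacked()[:, hotspot].sum(axis=1)
    true_in = overlap >= 1
    return cohort, labels, hotspot, true_in


def simulate_survival(
    in_region: np.ndarray,
    rng: np.random.Generator,
    hazard_baseline: float = 1.0 / 400.0,
    hazard_out_ratio: float = 2.0,
    censor_rate: float = 0.25,
    max_followup_days: float = 1730.0,
) -> pd.DataFrame:
    """Exponential survival with region-dependent hazard, independent censoring.

    ``in_region`` is a boolean vector; tumors outside the region carry
    ``hazard_baseline * hazard_out_ratio``. Censoring is exponential with
    hazard ``censor_rate * hazard_baseline``, capped administratively at
    ``max_followup_days``. Returns columns time_days (>= 1), event.
    """
    in_region = np.asarray(in_region, dtype=bool)
    n = in_region.size
    hazard = np.where(in_region, hazard_baseline, hazard_baseline * hazard_out_ratio)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = (
        rng.exponential(1.0 / (censor_rate * hazard_baseline), size=n)
        if censor_rate > 0
        else np.full(n, np.inf)
    )
    t_censor = np.minimum(t_censor, max_followup_days)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({"time_days": np.maximum(time, 1.0), "event": event})


def _simulate_clinical(
    cfg: SimConfig, ids, labels, true_in, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(ids)
    subtype = np.where(labels == 1, "proneural", "mesenchymal")
    age = np.clip(rng.normal(58, 11, n), 20, 88).round(1)
    sex = rng.choice(["female", "male"], n, p=[0.4, 0.6])
    kps = rng.choice([60, 70, 80, 90, 100], n, p=[0.08, 0.18, 0.49, 0.18, 0.07])
    mgmt = rng.choice(["methylated", "unmethylated"], n)
    resection = rng.uniform(size=n) < 0.91
    radiation = rng.uniform(size=n) < 0.84
    pharmaceutical = rng.uniform(size=n) < 0.81
    loc = rng.choice(
        ["single_temporal", "multi_temporal", "other"], n, p=[0.17, 0.58, 0.25]
    )
    side = rng.choice(["left", "right", "bilateral"], n, p=[0.46, 0.47, 0.07])
    f1 = np.where(loc == "single_temporal", 2, np.where(loc == "multi_temporal", 2, 1))
    f5 = rng.choice([4, 5, 6, 7, 8], n, p=[0.08, 0.12, 0.25, 0.40, 0.15])
    # duplicate raters: mostly identical, occasional one-category disagreement
    flip1 = rng.uniform(size=n) < 0.05
    flip5 = rng.uniform(size=n) < 0.08
    r2_f1 = np.where(flip1, rng.integers(1, 8, n), f1)
    r2_f5 = np.where(flip5, np.clip(f5 + rng.choice([-1, 1], n), 2, 8), f5)
    return pd.DataFrame(
        {
            "sample_id": ids,
            "subtype": subtype,
            "age": age,
            "sex": sex,
            "kps": kps,
            "mgmt": mgmt,
            "resection": resection.astype(int),
            "radiation": radiation.astype(int),
            "pharmaceutical": pharmaceutical.astype(int),
            "location_category": loc,
            "side": side,
            "vasari_f1": f1,
            "vasari_f5": f5,
            "rater2_f1": r2_f1,
            "rater2_f5": r2_f5,
        }
    )


def _simulate_expression(cfg: SimConfig, ids, true_in, rng: np.random.Generator):
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    perm = rng.permutation(cfg.n_genes)
    pos = 0

    def take(k):
        nonlocal pos
        out = genes[perm[pos : pos + k]]
        pos += k
        return list(out)

    emt_genes = take(cfg.emt_set_size)
    planted_up = emt_genes[: cfg.n_planted_up]
    planted_down = emt_genes[cfg.n_planted_up : cfg.n_planted_up + cfg.n_planted_down]
    immune_genes = take(cfg.immune_set_size)
    stromal_genes = take(cfg.stromal_set_size)
    celltype = {}
    for i in range(cfg.n_celltype_sets):
        name = (
            cfg.depleted_celltypes[i]
            if i < len(cfg.depleted_celltypes)
            else f"celltype_{i:02d}"
        )
        celltype[name] = take(cfg.celltype_set_size)

    values = rng.normal(0.0, 1.0, size=(cfg.n_genes, len(ids)))
    expr = pd.DataFrame(values, index=genes, columns=ids)
    out_mask = ~np.asarray(true_in, dtype=bool)
    d = cfg.effect_sd
    expr.loc[planted_up, expr.columns[out_mask]] += d
    expr.loc[planted_down, expr.columns[out_mask]] -= d
    expr.loc[immune_genes, expr.columns[out_mask]] += cfg.immune_shift
    expr.loc[stromal_genes, expr.columns[out_mask]] += cfg.stromal_shift
    for name in cfg.depleted_celltypes:
        if name in celltype:
            expr.loc[celltype[name], expr.columns[out_mask]] -= d

    gene_sets = {"EMT": GeneSet("EMT", frozenset(emt_genes)),
                 "immune_signature": GeneSet("immune_signature", frozenset(immune_genes)),
                 "stromal_signature": GeneSet("stromal_signature", frozenset(stromal_genes))}
    for name, gl in celltype.items():
        gene_sets[name] = GeneSet(name, frozenset(gl))
    truth_genes = {
        "planted_up": planted_up,
        "planted_down": planted_down,
        "immune_genes": immune_genes,
        "stromal_genes": stromal_genes,
    }
    return expr, gene_sets, truth_genes


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Draw a full coupled cohort (lesions + clinical + expression + truth)."""
    cfg = config or SimConfig()
    streams = _streams(cfg.seed)
    lesions, labels, hotspot, true_in = _simulate_lesions(cfg, streams["lesions"])
    ids = lesions.sample_ids
    samples = _simulate_clinical(cfg, ids, labels, true_in, streams["clinical"])
    surv = simulate_survival(
        true_in,
        streams["survival"],
        cfg.hazard_baseline,
        cfg.hazard_out_ratio,
        cfg.censor_rate,
        cfg.max_followup_days,
    )
    samples["os_days"] = surv["time_days"].to_numpy()
    samples["event"] = surv["event"].to_numpy()
    expr, gene_sets, truth_genes = _simulate_expression(
        cfg, ids, true_in, streams["expression"]
    )
    truth = {
        "hotspot_mask": hotspot,
        "true_membership": pd.Series(true_in, index=ids, name="true_in_area"),
        "labels": pd.Series(labels, index=ids, name="label"),
        "hazard_ratio": cfg.hazard_out_ratio,
        **truth_genes,
    }
    return SyntheticCohort(lesions, samples, expr, gene_sets, truth, cfg)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write masks (NIfTI), manifest, samples, expression, GMT and truth JSON."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for mask in cohort.lesions:
        p = out / "masks" / f"{mask.sample_id}.nii.gz"
        write_mask(mask, p)
        rows.append({"sample_id": mask.sample_id, "mask_path": str(p.relative_to(out))})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    samples = out / "samples.csv"
    cohort.samples.to_csv(samples, index=False)
    expr = out / "expression.tsv"
    cohort.expression.to_csv(expr, sep="\t")
    gmt = out / "gene_sets.gmt"
    write_gmt(cohort.gene_sets.values(), gmt)
    hotspot_nii = out / "hotspot.nii.gz"
    write_mask(
        LesionMask("hotspot", cohort.lesions.grid,
                   cohort.truth["hotspot_mask"].astype(np.uint8)),
        hotspot_nii,
    )
    truth_json = out / "truth.json"
    truth_json.write_text(
        json.dumps(
            {
                "true_membership": {
                    k: bool(v) for k, v in cohort.truth["true_membership"].items()
                },
                "labels": {k: int(v) for k, v in cohort.truth["labels"].items()},
                "planted_up": cohort.truth["planted_up"],
                "planted_down": cohort.truth["planted_down"],
                "hazard_ratio": cohort.truth["hazard_ratio"],
                "hotspot_nifti": hotspot_nii.name,
            },
            indent=2,
        )
    )
    return {
        "manifest": manifest,
        "samples": samples,
        "expression": expr,
        "gene_sets": gmt,
        "truth": truth_json,
        "hotspot": hotspot_nii,
    }
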