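"""Per-sample clinical and radiological bookkeeping.

Sample tables are plain pandas DataFrames with documented columns
(``sample_id``, ``subtype``, ``os_days``, ``event``, ``age``, ``sex``,
``kps``, ``mgmt``, ``vasari_f1``, ``vasari_f5``, ``rater2_f1``,
``rater2_f5``, ``location_category``, ``side`` and treatment flags). This
module covers inter-rater agreement (Cohen's kappa with the conventional
excellent/good/poor grading), the VOI volume-discrepancy recheck rule,
VASARI-based sample filtering, classification of tumors as in or outside a
reference region, and the 2x2 contingency / location-distribution reports.

VASARI F1 codes tumor location (2 = temporal); F5 codes the enhancing
proportion of the tumor, where code 7 means "> 95%".
"""
from __future__ import annotations

import warnings
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lesion_io import LesionCohort
from .vlsm import ContingencyTable

__all__ = [
    "SAMPLE_COLUMNS",
    "read_samples",
    "cohen_kappa",
    "kappa_grade",
    "voi_discrepancy",
    "vasari_filter",
    "classify_membership",
    "contingency_report",
    "chi2_test",
    "location_summary",
]

SAMPLE_COLUMNS = [
    "sample_id", "subtype", "os_days", "event", "age", "sex", "kps", "mgmt",
    "vasari_f1", "vasari_f5", "rater2_f1", "rater2_f5",
    "location_category", "side", "resection", "radiation", "pharmaceutical",
]

#: VASARI F5 code for "> 95%" enhancing proportion, the striking-enhancement cutoff.
F5_OVER_95 = 7
#: F5 code meaning "indeterminate"; never satisfies an enhancement cutoff.
F5_INDETERMINATE = 9
#: VASARI F1 code for a temporal-lobe epicenter.
F1_TEMPORAL = 2

TEMPORAL_CATEGORIES = ("single_temporal", "multi_temporal")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("samples table needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return df


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa for two raters over the same items.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement implied by the raters' marginal frequencies.
    When both raters are constant and identical, p_e = 1 and kappa is
    undefined; reported as 1.0 with a warning (agreement is perfect).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length rating vectors of length >= 2")
    cats = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        warnings.warn("both raters constant and identical; kappa undefined, reporting 1.0")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_grade(kappa: float) -> str:
    """Agreement grade: > 0.8 excellent, 0.6-0.8 good, < 0.6 poor."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa > 0.8:
        return "excellent"
    if kappa >= 0.6:
        return "good"
    return "poor"


def voi_discrepancy(volume_a: float, volume_b: float, tol: float = 0.05) -> str:
    """Two-observer VOI volume check: 'recheck' when the relative difference
    over the smaller volume exceeds ``tol``, else 'accept'."""
    if volume_a <= 0 or volume_b <= 0:
        raise ValueError("VOI volumes must be positive")
    ratio = abs(volume_a - volume_b) / min(volume_a, volume_b)
    return "recheck" if ratio > tol else "accept"


def vasari_filter(
    samples: pd.DataFrame,
    require_temporal: bool = True,
    min_f5_code: int = F5_OVER_95,
) -> set[str]:
    """Sample ids passing the enhancement / location screen.

    Keeps samples whose F5 enhancing-proportion code is >= ``min_f5_code``
    (default 7, "> 95%"); code 9 ("indeterminate") never qualifies. With
    ``require_temporal``, the tumor must involve the temporal lobe (F1 = 2
    or a multi-lobe location category that includes temporal). Samples with
    missing codes are excluded and counted in a warning.
    """
    df = samples
    f5 = pd.to_numeric(df.get("vasari_f5"), errors="coerce")
    keep = (f5 >= min_f5_code) & (f5 != F5_INDETERMINATE)
    if require_temporal:
        f1 = pd.to_numeric(df.get("vasari_f1"), errors="coerce")
        temporal = f1 == F1_TEMPORAL
        if "location_category" in df.columns:
            temporal |= df["location_category"].isin(TEMPORAL_CATEGORIES)
        keep &= temporal
    n_missing = int(f5.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} samples with missing VASARI codes excluded")
    return set(df.loc[keep.fillna(False), "sample_id"])


def classify_membership(
    cohort: LesionCohort, region: np.ndarray, min_overlap_voxels: int = 1
) -> pd.DataFrame:
    """Classify each tumor as in or outside a reference region.

    A sample is "in the area" when its mask overlaps the region by at least
    ``min_overlap_voxels`` voxels (default 1, the most permissive reading).
    ``overlap_fraction`` (overlap / tumor volume) is recorded so stricter
    rules can be applied downstream as a sensitivity analysis.
    """
    region = np.asarray(region).astype(bool)
    if region.shape != cohort.grid.shape:
        raise ValueError("region is not on the cohort grid")
    if min_overlap_voxels < 1:
        raise ValueError("min_overlap_voxels must be >= 1")
    stacked = cohort.stacked()
    overlap = stacked[:, region].sum(axis=1)
    volume = stacked.reshape(len(cohort), -1).sum(axis=1)
    return pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "in_area": overlap >= min_overlap_voxels,
            "overlap_voxels": overlap.astype(int),
            "overlap_fraction": overlap / volume,
        }
    )


def contingency_report(
    membership: pd.DataFrame | None = None,
    labels: Mapping[str, int] | pd.Series | None = None,
    table: ContingencyTable | None = None,
) -> dict:
    """2x2 in/out-of-area x label report with margins and percentages.

    Either pass ``membership`` (from :func:`classify_membership`) plus
    per-sample binary ``labels`` (1 = positive subtype), or a prebuilt
    ``table``. Cell layout: rows in/out of area, columns positive/negative
    label. Percentages are each cell over its row total and over its column
    total, rounded to the nearest integer as in a clinical report.
    """
    if table is None:
        if membership is None or labels is None:
            raise ValueError("need membership + labels, or a prebuilt table")
        lab = pd.Series(labels)
        lab = lab.reindex(membership["sample_id"]).astype(bool).to_numpy()
        in_area = membership["in_area"].to_numpy(dtype=bool)
        table = ContingencyTable(
            a=int(np.sum(in_area & lab)),
            b=int(np.sum(in_area & ~lab)),
            c=int(np.sum(~in_area & lab)),
            d=int(np.sum(~in_area & ~lab)),
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    in_total, out_total = a + b, c + d
    pos_total, neg_total = a + c, b + d

    def pct(x, tot):
        return int(round(100.0 * x / tot)) if tot else 0

    report = {
        "cells": {"in_pos": a, "in_neg": b, "out_pos": c, "out_neg": d},
        "in_area_total": in_total,
        "out_area_total": out_total,
        "positive_total": pos_total,
        "negative_total": neg_total,
        "grand_total": table.n,
        "row_pct": {
            "in_pos": pct(a, in_total), "in_neg": pct(b, in_total),
            "out_pos": pct(c, out_total), "out_neg": pct(d, out_total),
        },
        "col_pct": {
            "in_pos": pct(a, pos_total), "out_pos": pct(c, pos_total),
            "in_neg": pct(b, neg_total), "out_neg": pct(d, neg_total),
        },
    }
    if b * c > 0:
        report["odds_ratio"] = (a * d) / (b * c)
    elif a * d > 0:
        report["odds_ratio"] = float("inf")
    return report


def chi2_test(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction (df = 1 for 2x2)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def location_summary(samples: pd.DataFrame) -> dict:
    """Lobe-level tumor-location distribution, overall and per subtype.

    Uses ``location_category`` (single_temporal / multi_temporal / other)
    and ``side`` (left / right / bilateral). Percentages carry two decimals;
    temporal involvement = (single + multi temporal) / total.
    """
    def one_group(df: pd.DataFrame) -> dict:
        n = len(df)
        out: dict = {"n": n}
        for col, cats in (
            ("location_category", ("single_temporal", "multi_temporal", "other")),
            ("side", ("left", "right", "bilateral")),
        ):
            series = df[col] if col in df.columns else pd.Series(dtype=object)
            for cat in cats:
                cnt = int((series == cat).sum())
                out[cat] = {"n": cnt, "pct": round(100.0 * cnt / n, 2) if n else 0.0}
        temporal = out["single_temporal"]["n"] + out["multi_temporal"]["n"]
        out["temporal_involvement_pct"] = round(100.0 * temporal / n, 2) if n else 0.0
        return out

    report = {"total": one_group(samples)}
    if "subtype" in samples.columns:
        for subtype, grp in samples.groupby("subtype"):
            report[str(subtype)] = one_group(grp)
    return report
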