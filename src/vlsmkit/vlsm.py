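"""Voxel-wise lesion-symptom mapping with the Liebermeister quasi-exact test.

The analysis asks, voxel by voxel, whether lesion presence is associated
with a binary per-patient label (here: transcriptomic subtype). At each
voxel the cohort splits into a 2x2 table of lesion status x label; the
Liebermeister test scores the association, one-sided p-values are mapped to
signed z-scores, and voxel-level multiplicity is handled by a
Benjamini-Hochberg false-discovery-rate threshold computed over the
analyzed voxels only. Voxels lesioned in too small a fraction of the cohort
carry no information and are excluded before testing (coverage filter).

Liebermeister's measure for a table ``(a, b; c, d)`` is the hypergeometric
tail of the table augmented in the concordant cells: for a positive
(lesion-and-label-positive) association the table becomes
``(a+1, b; c, d+1)`` on ``n + 2`` subjects and the p-value is
``P(X >= a+1)`` where ``X`` is hypergeometric with population ``n + 2``,
``a+c+1`` successes and ``a+b+1`` draws. It is quasi-exact and uniformly
less conservative than the one-sided Fisher exact test on the raw table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats
from skimage import measure

from .lesion_io import LesionCohort, VolumeGrid, build_overlay

__all__ = [
    "ContingencyTable",
    "VLSMConfig",
    "Cluster",
    "VLSMResult",
    "voxel_coverage_mask",
    "voxel_table",
    "liebermeister_p",
    "p_to_z",
    "bh_fdr_threshold",
    "extract_clusters",
    "run_vlsm",
]

#: |z| ceiling used when p underflows to 0 or rounds to 1; keeps stored maps finite.
Z_CLAMP = 8.0

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of lesion status x binary label at one voxel.

    a: lesioned & label-positive;  b: lesioned & label-negative;
    c: intact   & label-positive;  d: intact   & label-negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class VLSMConfig:
    """Settings for a VLSM run; the defaults are the conventional ones.

    min_lesion_fraction: voxels lesioned in a strictly greater fraction of
        the cohort than this are analyzed (default: damaged in > 5%).
    fdr_q: false-discovery-rate level for the voxel-wise threshold.
    direction: which one-sided association to map ("positive" = lesion
        co-occurs with the positive label). Separate subtype maps are
        separate runs, not a two-sided test.
    connectivity: 3-D neighbourhood for cluster extraction (6, 18 or 26).
    """

    min_lesion_fraction: float = 0.05
    fdr_q: float = 0.05
    direction: Literal["positive", "negative", "two-sided"] = "positive"
    connectivity: int = 26
    fdr_method: Literal["bh", "by"] = "bh"

    def __post_init__(self) -> None:
        if not 0 < self.min_lesion_fraction < 1:
            raise ValueError("min_lesion_fraction must be in (0,1)")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0,1)")
        if self.connectivity not in _CONNECTIVITY_TO_SKIMAGE:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.direction not in ("positive", "negative", "two-sided"):
            raise ValueError(f"unknown direction {self.direction!r}")


class Cluster(NamedTuple):
    label: int
    n_voxels: int
    peak_z: float
    peak_index: tuple[int, int, int]


@dataclass
class VLSMResult:
    grid: VolumeGrid
    analyzed_mask: np.ndarray
    p_map: np.ndarray
    z_map: np.ndarray
    fdr_p_threshold: float | None
    sig_mask: np.ndarray
    clusters: list[Cluster]
    config: VLSMConfig

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


def voxel_coverage_mask(
    cohort: LesionCohort, min_lesion_fraction: float = 0.05
) -> np.ndarray:
    """Voxels damaged in strictly more than ``min_lesion_fraction`` of the cohort."""
    if not 0 < min_lesion_fraction < 1:
        raise ValueError("min_lesion_fraction must be in (0,1)")
    overlay = build_overlay(cohort)
    frac = overlay.counts / overlay.n_samples
    return (frac > min_lesion_fraction).astype(bool)


def voxel_table(
    cohort: LesionCohort, labels: Sequence[int], voxel: tuple[int, int, int]
) -> ContingencyTable:
    """The lesion-status x label 2x2 table at one voxel."""
    lab = _check_labels(labels, len(cohort))
    lesioned = cohort.stacked()[(slice(None), *voxel)]
    a = int(np.sum(lesioned & lab))
    b = int(np.sum(lesioned & ~lab))
    c = int(np.sum(~lesioned & lab))
    d = int(np.sum(~lesioned & ~lab))
    return ContingencyTable(a, b, c, d)


def liebermeister_p(
    table: ContingencyTable, direction: Literal["positive", "negative"] = "positive"
) -> float:
    """Liebermeister quasi-exact one-sided p for a 2x2 table.

    positive: augment (a+1, b; c, d+1), return P(X >= a+1);
    negative: augment (a, b+1; c+1, d), return P(X <= a).
    X ~ Hypergeometric(N = n+2, K = a+c+1, m = a+b+1) in both cases.
    """
    a, n = table.a, table.n
    N = n + 2
    K = table.a + table.c + 1
    m = table.a + table.b + 1
    if direction == "positive":
        p = float(stats.hypergeom.sf(a, N, K, m))  # P(X > a) = P(X >= a+1)
    elif direction == "negative":
        p = float(stats.hypergeom.cdf(a, N, K, m))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def _liebermeister_p_vec(
    a: np.ndarray, lesioned: np.ndarray, n_pos: int, n: int, direction: str
) -> np.ndarray:
    """Vectorized Liebermeister p over voxels.

    a: lesioned & positive count per voxel; lesioned: total lesioned count
    per voxel; n_pos: label-positive samples; n: cohort size.
    """
    N = n + 2
    K = a + n_pos - a + 1  # a + c + 1
    m = lesioned + 1  # a + b + 1
    if direction == "positive":
        p = stats.hypergeom.sf(a, N, K, m)
    else:
        p = stats.hypergeom.cdf(a, N, K, m)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def p_to_z(p: float | np.ndarray, direction_sign: int = 1) -> float | np.ndarray:
    """Map a one-sided p-value to a signed standard-normal z-score.

    z = Phi^-1(1 - p) * sign. p outside (0, 1) maps to +/-inf and is clamped
    at |z| = 8 with a warning, so the value survives storage in finite maps.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        warnings.warn("p-values at 0 or 1 clamped to |z| = 8")
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p_arr) * direction_sign
    z = np.clip(z, -Z_CLAMP, Z_CLAMP)
    return float(z) if np.isscalar(p) else z


def bh_fdr_threshold(
    pvals: Sequence[float], q: float = 0.05, method: Literal["bh", "by"] = "bh"
) -> float | None:
    """Benjamini-Hochberg step-up p-value threshold.

    Sort p ascending, find the largest k with p(k) <= k*q/m and return p(k);
    None when no rank qualifies. method="by" applies the Benjamini-Yekutieli
    correction factor (divide q by sum 1/i) for arbitrary dependence.
    """
    p = np.sort(np.asarray(list(pvals), dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    if method == "by":
        q = q / np.sum(1.0 / np.arange(1, m + 1))
    crit = np.arange(1, m + 1) * q / m
    ok = np.nonzero(p <= crit)[0]
    if ok.size == 0:
        return None
    return float(p[ok.max()])


def extract_clusters(
    sig_mask: np.ndarray, z_map: np.ndarray, connectivity: int = 26
) -> list[Cluster]:
    """Connected components of the significant mask, largest first.

    Ties on size break by higher peak z, then by lowest linear index of the
    peak voxel, so ordering is deterministic.
    """
    sig = np.asarray(sig_mask).astype(bool)
    if not sig.any():
        return []
    lab = measure.label(sig, connectivity=_CONNECTIVITY_TO_SKIMAGE[connectivity])
    clusters = []
    for lid in range(1, lab.max() + 1):
        idx = np.nonzero(lab == lid)
        zvals = z_map[idx]
        k = int(np.argmax(zvals))
        # among equal-z peaks prefer the lowest linear index (argmax already
        # returns the first in C order)
        peak = (int(idx[0][k]), int(idx[1][k]), int(idx[2][k]))
        clusters.append(Cluster(lid, int(len(idx[0])), float(zvals[k]), peak))
    lin = lambda c: int(np.ravel_multi_index(c.peak_index, sig.shape))
    clusters.sort(key=lambda c: (-c.n_voxels, -c.peak_z, lin(c)))
    return clusters


def run_vlsm(
    cohort: LesionCohort, labels: Sequence[int], config: VLSMConfig | None = None
) -> VLSMResult:
    """Full voxel-wise map: coverage filter, Liebermeister test, FDR, clusters.

    ``labels`` is the per-sample binary outcome aligned with cohort order
    (1 = positive class). Both classes need at least two samples. The result
    is deterministic in the input and invariant to sample reordering.
    """
    config = config or VLSMConfig()
    lab = _check_labels(labels, len(cohort))
    n_pos = int(lab.sum())
    n = len(cohort)
    if n_pos < 2 or n - n_pos < 2:
        raise ValueError("each label class needs at least 2 samples")

    stacked = cohort.stacked().reshape(n, -1)
    counts = stacked.sum(axis=0)
    analyzed_flat = counts / n > config.min_lesion_fraction
    if not analyzed_flat.any():
        raise ValueError("no voxel passes the lesion-coverage filter")
    idx = np.nonzero(analyzed_flat)[0]

    a = lab.astype(np.int64) @ stacked[:, idx]
    lesioned = counts[idx].astype(np.int64)

    direction = config.direction
    if direction == "two-sided":
        p_pos = _dedup_p(a, lesioned, n_pos, n, "positive")
        p_neg = _dedup_p(a, lesioned, n_pos, n, "negative")
        p = np.minimum(1.0, 2.0 * np.minimum(p_pos, p_neg))
        sign = np.where(p_pos <= p_neg, 1.0, -1.0)
        one_sided = np.minimum(p_pos, p_neg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = p_to_z(one_sided) * sign
    else:
        p = _dedup_p(a, lesioned, n_pos, n, direction)
        sign = 1 if direction == "positive" else -1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = p_to_z(p, sign)

    thr = bh_fdr_threshold(p, config.fdr_q, method=config.fdr_method)

    shape = cohort.grid.shape
    p_map = np.full(int(np.prod(shape)), np.nan)
    z_map = np.full(int(np.prod(shape)), np.nan)
    p_map[idx] = p
    z_map[idx] = z
    p_map = p_map.reshape(shape)
    z_map = z_map.reshape(shape)
    analyzed = analyzed_flat.reshape(shape)

    sig = np.zeros(shape, dtype=bool)
    if thr is not None:
        with np.errstate(invalid="ignore"):
            sig = np.where(np.isnan(p_map), False, p_map <= thr)
    clusters = extract_clusters(sig, np.nan_to_num(z_map), config.connectivity)
    return VLSMResult(
        cohort.grid, analyzed, p_map, z_map, thr, sig.astype(np.uint8), clusters, config
    )


def _dedup_p(
    a: np.ndarray, lesioned: np.ndarray, n_pos: int, n: int, direction: str
) -> np.ndarray:
    """Evaluate the voxel-wise p on unique (a, lesioned) pairs only."""
    pair = a * (n + 1) + lesioned
    uniq, inv = np.unique(pair, return_inverse=True)
    ua = uniq // (n + 1)
    ul = uniq % (n + 1)
    up = _liebermeister_p_vec(ua, ul, n_pos, n, direction)
    return up[inv]


def _check_labels(labels: Sequence[int], n: int) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.shape != (n,):
        raise ValueError(f"labels must have length {n}, got shape {lab.shape}")
    if not np.isin(np.unique(lab), (0, 1, True, False)).all():
        raise ValueError("labels must be binary")
    return lab.astype(bool)
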